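"""Synthetic field experiment: design table, layered nitrogen values, spectra.

The generator emulates a two-year factorial trial: 4 nitrogen rates
(0/60/120/180 kg/ha) x 2 seed-dressing treatments (rhizobium inoculated
or not) x 3 replicates x 2 years = 48 samples.  Each sample carries a
leaf nitrogen concentration (LNC) for three vertical leaf layers -- root
(RL), lateral (LL) and canopy (CL) -- ordered RL < LL < CL, and a canopy
reflectance spectrum on the 350-1830 nm grid whose chlorophyll wells,
red-edge amplitude and NIR plateau are driven by the canopy-layer LNC.

Lower layers are noisy, attenuated companions of the canopy value: a
shared half-normal "decay" draw pulls LL and RL down together (with a
larger gain for RL), which keeps the per-sample layer ordering while
weakening the layer-to-spectrum coupling from canopy to root.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import FULL_GRID, LAYERS, SpectrumSet
from .parameters import dual_band_value

N_LEVELS = ("N0", "N1", "N2", "N3")
N_RATES = {"N0": 0, "N1": 60, "N2": 120, "N3": 180}
YEARS = (2021, 2022)
REPLICATES = (1, 2, 3)

#: Default canopy-layer target means per (n_level, inoculated), on a
#: dimensionless concentration scale (~3-6); strictly increasing in
#: nitrogen rate and in inoculation at every rate.
DEFAULT_TREATMENT_MEANS: dict[tuple[str, bool], float] = {
    ("N0", False): 3.13,
    ("N1", False): 4.69,
    ("N2", False): 5.13,
    ("N3", False): 5.44,
    ("N0", True): 3.48,
    ("N1", True): 4.97,
    ("N2", True): 5.33,
    ("N3", True): 5.70,
}

# Internal RNG stream tags (mixed with the master seed).
_STREAM_LNC = 1
_STREAM_SPECTRUM = 2
_STREAM_PLANT = 3


@dataclass
class SpectralCoupling:
    """Parameters linking canopy LNC to reflectance features."""

    base_visible: float = 0.10
    green_peak_height: float = 0.06
    green_peak_center: float = 550.0
    green_peak_width: float = 18.0
    well_depth_base: float = 0.010
    well_depth_per_lnc: float = 0.012
    blue_well_center: float = 450.0
    blue_well_width: float = 30.0
    red_well_center: float = 670.0
    red_well_width: float = 28.0
    rededge_center: float = 718.0
    rededge_width: float = 14.0
    nir_base: float = 0.22
    nir_per_lnc: float = 0.035
    swir_drop: float = 0.12
    swir_center: float = 1350.0
    swir_width: float = 80.0
    water_depth: float = 0.10
    water_center: float = 1450.0
    water_width: float = 35.0


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic experiment generator.

    All noise scales are standard deviations and must be non-negative;
    ``treatment_means`` must increase with nitrogen level and with
    inoculation at fixed level.
    """

    seed: int = 0
    treatment_means: dict[tuple[str, bool], float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_MEANS)
    )
    year_effects: dict[int, float] = field(
        default_factory=lambda: {2021: 0.0, 2022: 0.0}
    )
    layer_offsets: dict[str, float] = field(
        default_factory=lambda: {"LL": 0.18, "RL": 0.42}
    )
    plot_noise_sd: float = 0.10
    layer_noise_sd: float = 0.03
    layer_decay_sd: float = 0.45
    layer_decay_gain: dict[str, float] = field(
        default_factory=lambda: {"LL": 1.0, "RL": 1.4}
    )
    spectral_noise_sd: float = 0.005
    coupling: SpectralCoupling = field(default_factory=SpectralCoupling)

    def validate(self) -> None:
        for name in ("plot_noise_sd", "layer_noise_sd", "layer_decay_sd",
                     "spectral_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for inoc in (False, True):
            means = [self.treatment_means[(lv, inoc)] for lv in N_LEVELS]
            if np.any(np.diff(means) <= 0):
                raise ValueError(
                    "treatment means must increase with nitrogen level"
                )
        for lv in N_LEVELS:
            if self.treatment_means[(lv, True)] <= self.treatment_means[(lv, False)]:
                raise ValueError(
                    "inoculated mean must exceed uninoculated at each level"
                )
        min_mean = min(self.treatment_means.values()) + min(
            self.year_effects.values()
        )
        for layer, off in self.layer_offsets.items():
            if off <= 0:
                raise ValueError("layer offsets must be positive")
            if min_mean - off <= 0:
                raise ValueError(
                    f"layer offset for {layer} drives the mean non-positive"
                )

    def noiseless(self) -> "GeneratorConfig":
        """Copy with every noise source switched off (same structure)."""
        return replace(
            self,
            plot_noise_sd=0.0,
            layer_noise_sd=0.0,
            layer_decay_sd=0.0,
            spectral_noise_sd=0.0,
        )


def make_design(config: GeneratorConfig) -> pd.DataFrame:
    """Full-factorial design table: 2 years x 4 N levels x 2 dressings x 3 reps."""
    config.validate()
    rows = []
    k = 0
    for year in YEARS:
        for n_level in N_LEVELS:
            for inoculated in (False, True):
                for rep in REPLICATES:
                    k += 1
                    rows.append(
                        {
                            "sample_id": f"S{k:02d}",
                            "year": year,
                            "n_level": n_level,
                            "inoculated": inoculated,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


def sample_lnc(design: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Draw per-sample, per-layer nitrogen concentrations (144 rows).

    The canopy value is drawn around its treatment mean; LL and RL
    subtract positive layer offsets plus a shared half-normal decay draw
    (gain increasing toward the root) and small independent noise.
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_LNC, config.seed])
    rows = []
    for rec in design.to_dict("records"):
        mean = config.treatment_means[(rec["n_level"], rec["inoculated"])]
        mean += config.year_effects.get(rec["year"], 0.0)
        cl = mean + rng.normal(0.0, config.plot_noise_sd)
        eta = abs(rng.normal(0.0, config.layer_decay_sd))
        values = {"CL": cl}
        for layer in ("LL", "RL"):
            values[layer] = (
                cl
                - config.layer_offsets[layer]
                - config.layer_decay_gain[layer] * eta
                + rng.normal(0.0, config.layer_noise_sd)
            )
        for layer in LAYERS:
            rows.append({**rec, "layer": layer, "lnc": max(values[layer], 1e-6)})
    return pd.DataFrame(rows)


def _spectrum_mean(lnc_cl: float, c: SpectralCoupling) -> np.ndarray:
    lam = FULL_GRID.astype(float)
    depth = c.well_depth_base + c.well_depth_per_lnc * lnc_cl
    nir = c.nir_base + c.nir_per_lnc * lnc_cl
    r = np.full(lam.shape, c.base_visible)
    r += c.green_peak_height * np.exp(
        -0.5 * ((lam - c.green_peak_center) / c.green_peak_width) ** 2
    )
    r -= depth * np.exp(-0.5 * ((lam - c.blue_well_center) / c.blue_well_width) ** 2)
    r -= depth * np.exp(-0.5 * ((lam - c.red_well_center) / c.red_well_width) ** 2)
    r += nir / (1.0 + np.exp(-(lam - c.rededge_center) / c.rededge_width))
    r -= c.swir_drop / (1.0 + np.exp(-(lam - c.swir_center) / c.swir_width))
    r -= c.water_depth * np.exp(-0.5 * ((lam - c.water_center) / c.water_width) ** 2)
    return r


def generate_spectrum(
    lnc_cl: float, config: GeneratorConfig, sample_seed: int
) -> np.ndarray:
    """Reflectance on the 1481-point grid, driven by the canopy LNC.

    Additive components: visible baseline, green peak near 550 nm,
    chlorophyll wells near 450/670 nm deepening with LNC, a logistic red
    edge whose NIR amplitude grows with LNC, an SWIR roll-off and a
    water dip near 1450 nm, plus seeded Gaussian noise.  Values are
    clipped into (0, 1).
    """
    if lnc_cl <= 0:
        raise ValueError("lnc_cl must be positive")
    mean = _spectrum_mean(lnc_cl, config.coupling)
    if mean.min() <= 0.0 or mean.max() >= 1.0:
        raise ValueError(
            "coupling configuration produces reflectance outside (0, 1)"
        )
    rng = np.random.default_rng([_STREAM_SPECTRUM, config.seed, int(sample_seed)])
    r = mean + rng.normal(0.0, config.spectral_noise_sd, size=mean.shape)
    return np.clip(r, 1e-6, 1.0 - 1e-6)


def generate_spectra(lnc: pd.DataFrame, config: GeneratorConfig) -> SpectrumSet:
    """One spectrum per sample, driven by that sample's canopy-layer LNC."""
    cl = lnc[lnc["layer"] == "CL"].set_index("sample_id")["lnc"]
    sample_ids = list(cl.index)
    rows = [
        generate_spectrum(float(cl[sid]), config, k)
        for k, sid in enumerate(sample_ids)
    ]
    return SpectrumSet(FULL_GRID.copy(), np.vstack(rows), sample_ids)


def generate_dataset(config: GeneratorConfig) -> tuple[SpectrumSet, pd.DataFrame]:
    """Design -> layered LNC -> spectra, fully determined by ``config.seed``."""
    design = make_design(config)
    lnc = sample_lnc(design, config)
    spectra = generate_spectra(lnc, config)
    return spectra, lnc


def plant_signal(
    spectra: SpectrumSet,
    lnc: pd.DataFrame,
    pair: tuple[int, int],
    formula_id: str,
    slope: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Replace LNC values with ``slope * index(i, j) + noise`` per layer.

    Ground-truth construction for band-search recovery tests: every
    layer of the returned table is an affine function of the planted
    dual-band index (independent noise per layer), so the search should
    rediscover ``pair``.  The planted pair is recorded in
    ``table.attrs['planted_pair']``.
    """
    i, j = int(pair[0]), int(pair[1])
    values = dual_band_value(
        formula_id, spectra.band(i), spectra.band(j),
        spectra.band(550), spectra.band(455),
    )
    if not np.all(np.isfinite(values)) or np.ptp(values) == 0:
        raise ValueError("planted index is degenerate on these spectra")
    idx = pd.Series(values, index=pd.Index(spectra.sample_ids, name="sample_id"))
    rng = np.random.default_rng([_STREAM_PLANT, seed])
    out = lnc.copy()
    for layer in LAYERS:
        mask = out["layer"] == layer
        base = slope * idx.loc[out.loc[mask, "sample_id"]].to_numpy()
        out.loc[mask, "lnc"] = base + rng.normal(0.0, noise_sd, size=base.size)
    out.attrs["planted_pair"] = (i, j)
    out.attrs["planted_formula"] = formula_id
    return out
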