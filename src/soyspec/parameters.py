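"""Spectral parameters: empirical indices, three-edge parameters, dual-band formulas.

Three parameter classes are computed per spectrum:

* 10 empirical indices at fixed wavelengths (IPVI, OSAVI, NDNI, AVI,
  D678/500, D800/550, D800/680, D833/658, DVI_MSS, DD);
* 10 three-edge ("trilateral") parameters from the first-derivative
  spectrum (D_b, D_y, D_r, R_g, R_r, S_b, S_y, S_r, NDD_rb, NDSD_rb);
* 10 dual-band formulas (RI, DI, SAVI, NDVI, TVI, mSR, mNDI, PI, SI,
  VI6) evaluated at a caller-supplied wavelength pair per formula.

Undefined values (division by zero, non-positive operand of a log,
zero-sum normalizers) become NaN sentinels and are counted, never
silently replaced.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import (
    CLASS_DUALBAND,
    CLASS_EMPIRICAL,
    CLASS_TRILATERAL,
    DerivativeSet,
    ParameterMatrix,
    SpectrumSet,
)
from .preprocess import first_derivative

logger = logging.getLogger(__name__)

EMPIRICAL_NAMES = [
    "IPVI",
    "OSAVI",
    "NDNI",
    "AVI",
    "D678/500",
    "D800/550",
    "D800/680",
    "D833/658",
    "DVI_MSS",
    "DD",
]

TRILATERAL_NAMES = [
    "D_b",
    "D_y",
    "D_r",
    "R_g",
    "R_r",
    "S_b",
    "S_y",
    "S_r",
    "NDD_rb",
    "NDSD_rb",
]

#: Edge windows in nm (inclusive endpoints).
EDGE_WINDOWS = {"blue": (490, 530), "yellow": (462, 642), "red": (670, 760)}
GREEN_PEAK_WINDOW = (510, 560)
RED_VALLEY_WINDOW = (650, 690)

DUAL_BAND_NAMES = ["RI", "DI", "SAVI", "NDVI", "TVI", "mSR", "mNDI", "PI", "SI", "VI6"]

#: Formulas that are degenerate (constant or undefined) on the i = j diagonal.
DEGENERATE_AT_EQUAL = frozenset({"RI", "DI", "NDVI", "VI6", "mSR", "mNDI"})


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


def _safe_log_inv(r):
    """log(1/r) with NaN where r <= 0."""
    r = np.asarray(r, dtype=float)
    out = np.full(r.shape, np.nan)
    ok = r > 0
    np.log(r, out=out, where=ok)
    return -out


def empirical_indices(
    spectra: SpectrumSet,
    ipvi_literature: bool = False,
    ratio_reading: bool = True,
) -> pd.DataFrame:
    """Evaluate the ten fixed-wavelength empirical indices per sample.

    Parameters
    ----------
    ipvi_literature
        If True, use the common literature form R800/(R800+R670) instead
        of the default product form R800*(R800+R670).
    ratio_reading
        AVI / DVI_MSS juxtaposition read as band ratios,
        ``2*(R800/R1100) - R600/R700`` (default); if False, the literal
        product reading ``2*R800*R1100 - R600*R700`` is used.
    """
    R = spectra.band
    r800, r670 = R(800), R(670)
    if ipvi_literature:
        ipvi = _safe_div(r800, r800 + r670)
    else:
        ipvi = r800 * (r800 + r670)
    osavi = _safe_div(1.16 * (r800 - r670), r800 + r670 + 0.16)
    la, lb = _safe_log_inv(R(1510)), _safe_log_inv(R(1680))
    ndni = _safe_div(la - lb, la + lb)
    if ratio_reading:
        avi = 2.0 * _safe_div(r800, R(1100)) - _safe_div(R(600), R(700))
        dvi_mss = 2.4 * _safe_div(r800, R(1100)) - _safe_div(R(600), R(700))
    else:
        avi = 2.0 * r800 * R(1100) - R(600) * R(700)
        dvi_mss = 2.4 * r800 * R(1100) - R(600) * R(700)
    dd = (R(749) - R(720)) - (R(701) - R(672))
    values = {
        "IPVI": ipvi,
        "OSAVI": osavi,
        "NDNI": ndni,
        "AVI": avi,
        "D678/500": _safe_div(R(678), R(500)),
        "D800/550": _safe_div(r800, R(550)),
        "D800/680": _safe_div(r800, R(680)),
        "D833/658": _safe_div(R(833), R(658)),
        "DVI_MSS": dvi_mss,
        "DD": dd,
    }
    return pd.DataFrame(values, index=pd.Index(spectra.sample_ids, name="sample_id"))


def _window_slice(wavelengths: np.ndarray, lo: int, hi: int) -> slice:
    a = int(np.searchsorted(wavelengths, lo, side="left"))
    b = int(np.searchsorted(wavelengths, hi, side="right"))
    if a >= b:
        raise ValueError(f"window {lo}-{hi} nm not covered by the grid")
    return slice(a, b)


def trilateral_parameters(
    spectra: SpectrumSet, deriv: DerivativeSet | None = None
) -> pd.DataFrame:
    """Three-edge parameters from a smoothed spectrum and its derivative.

    Edge maxima (D_b, D_y, D_r) and areas (S_b, S_y, S_r) use derivative
    entries whose left endpoint lies in ``[a, b)`` for a window
    ``[a, b]``, so each area telescopes exactly to ``R(b) - R(a)``.
    Reflectance extrema (R_g, R_r) use the closed windows; ties resolve
    toward the shorter wavelength.
    """
    if deriv is None:
        deriv = first_derivative(spectra)
    out: dict[str, np.ndarray] = {}
    for key, short in (("blue", "b"), ("yellow", "y"), ("red", "r")):
        lo, hi = EDGE_WINDOWS[key]
        sl = _window_slice(deriv.wavelengths, lo, hi - 1)  # left endpoints in [lo, hi)
        win = deriv.values[:, sl]
        out[f"D_{short}"] = win.max(axis=1)
        out[f"S_{short}"] = win.sum(axis=1)
    gsl = _window_slice(spectra.wavelengths, *GREEN_PEAK_WINDOW)
    rsl = _window_slice(spectra.wavelengths, *RED_VALLEY_WINDOW)
    out["R_g"] = spectra.reflectance[:, gsl].max(axis=1)
    out["R_r"] = spectra.reflectance[:, rsl].min(axis=1)
    out["NDD_rb"] = _safe_div(out["D_r"] - out["D_b"], out["D_r"] + out["D_b"])
    out["NDSD_rb"] = _safe_div(out["S_r"] - out["S_b"], out["S_r"] + out["S_b"])
    frame = pd.DataFrame(out, index=pd.Index(spectra.sample_ids, name="sample_id"))
    return frame[TRILATERAL_NAMES]


def dual_band_value(formula_id: str, r_i, r_j, r_550=None, r_455=None):
    """Evaluate one dual-band formula (vectorized, NaN at singularities).

    ``r_550`` is required for TVI; ``r_455`` for mSR and mNDI.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    if formula_id == "RI":
        return _safe_div(r_i, r_j)
    if formula_id == "DI":
        return r_i - r_j
    if formula_id == "SAVI":
        return _safe_div(1.16 * (r_i - r_j), r_i + r_j + 0.16)
    if formula_id == "NDVI":
        return _safe_div(r_i - r_j, r_i + r_j)
    if formula_id == "TVI":
        if r_550 is None:
            raise ValueError("TVI requires r_550")
        r_550 = np.asarray(r_550, dtype=float)
        return 0.5 * (120.0 * (r_i - r_550) - 200.0 * (r_j - r_550))
    if formula_id == "mSR":
        if r_455 is None:
            raise ValueError("mSR requires r_455")
        r_455 = np.asarray(r_455, dtype=float)
        return _safe_div(r_i - r_455, r_j - r_455)
    if formula_id == "mNDI":
        if r_455 is None:
            raise ValueError("mNDI requires r_455")
        r_455 = np.asarray(r_455, dtype=float)
        return _safe_div(r_i - r_j, r_i + r_j - 2.0 * r_455)
    if formula_id == "PI":
        return r_i * r_j
    if formula_id == "SI":
        return r_i + r_j
    if formula_id == "VI6":
        return _safe_div(1.0, r_i) - _safe_div(1.0, r_j)
    raise KeyError(f"unknown dual-band formula {formula_id!r}")


def dual_band_columns(
    spectra: SpectrumSet, pairs: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """Evaluate every dual-band formula at its assigned wavelength pair."""
    missing = [f for f in DUAL_BAND_NAMES if f not in pairs]
    if missing:
        raise ValueError(f"missing wavelength pairs for: {missing}")
    r550 = spectra.band(550)
    r455 = spectra.band(455)
    cols = {}
    for fid in DUAL_BAND_NAMES:
        i, j = pairs[fid]
        cols[fid] = dual_band_value(
            fid, spectra.band(int(i)), spectra.band(int(j)), r550, r455
        )
    return pd.DataFrame(cols, index=pd.Index(spectra.sample_ids, name="sample_id"))


def parameter_matrix(
    spectra: SpectrumSet,
    pairs: dict[str, tuple[int, int]],
    ipvi_literature: bool = False,
    ratio_reading: bool = True,
) -> ParameterMatrix:
    """Assemble the full 30-column parameter matrix for a spectrum set."""
    emp = empirical_indices(spectra, ipvi_literature, ratio_reading)
    tri = trilateral_parameters(spectra)
    dual = dual_band_columns(spectra, pairs)
    values = pd.concat([emp, tri, dual], axis=1)
    tags = {c: CLASS_EMPIRICAL for c in EMPIRICAL_NAMES}
    tags.update({c: CLASS_TRILATERAL for c in TRILATERAL_NAMES})
    tags.update({c: CLASS_DUALBAND for c in DUAL_BAND_NAMES})
    matrix = ParameterMatrix(values, tags)
    bad = matrix.undefined_counts()
    bad = bad[bad > 0]
    if len(bad):
        logger.warning("undefined parameter values per column: %s", bad.to_dict())
    return matrix
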