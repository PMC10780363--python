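"""CSV schemas, figure rendering, and the run manifest.

Spectra are wide CSV (first column ``wavelength_nm``, one column per
sample).  Nitrogen tables are tidy CSV with header
``sample_id,year,n_level,inoculated,replicate,layer,lnc``.  All writes
round-trip losslessly through :func:`read_spectra` / :func:`read_lnc`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LAYERS, SchemaError, SpectrumSet

LNC_COLUMNS = ["sample_id", "year", "n_level", "inoculated", "replicate", "layer", "lnc"]


def write_spectra(spectra: SpectrumSet, path) -> None:
    frame = pd.DataFrame(
        spectra.reflectance.T,
        columns=spectra.sample_ids,
        index=pd.Index(spectra.wavelengths, name="wavelength_nm"),
    )
    frame.to_csv(path, float_format="%.12g")


def read_spectra(path) -> SpectrumSet:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"spectra file not found: {path}")
    frame = pd.read_csv(path)
    if frame.columns[0] != "wavelength_nm":
        raise SchemaError("first column must be 'wavelength_nm'")
    wl = frame["wavelength_nm"].to_numpy()
    if not np.all(wl == wl.astype(int)):
        raise SchemaError("wavelengths must be integers (nm)")
    wl = wl.astype(int)
    steps = np.diff(wl)
    if np.any(steps != 1):
        bad = int(wl[:-1][steps != 1][0])
        raise SchemaError(
            f"wavelength grid has a gap after {bad} nm; expected 1 nm steps"
        )
    sample_ids = [str(c) for c in frame.columns[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise SchemaError("duplicate sample columns in spectra file")
    refl = frame.iloc[:, 1:].to_numpy(dtype=float).T
    if not np.all(np.isfinite(refl)):
        raise SchemaError("spectra contain missing or non-finite values")
    if refl.min() < -0.02 or refl.max() > 1.02:
        raise SchemaError("reflectance outside the [0, 1] range")
    return SpectrumSet(wl, refl, sample_ids)


def write_lnc(lnc: pd.DataFrame, path) -> None:
    lnc[LNC_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_lnc(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"lnc file not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in LNC_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"lnc file missing columns: {missing}")
    frame["sample_id"] = frame["sample_id"].astype(str)
    frame["inoculated"] = frame["inoculated"].astype(bool)
    by_sample = frame.groupby("sample_id")["layer"].apply(set)
    for sid, layers in by_sample.items():
        if layers != set(LAYERS):
            raise SchemaError(
                f"sample {sid} has layers {sorted(layers)}; expected {sorted(LAYERS)}"
            )
    dup = frame.duplicated(subset=["sample_id", "layer"])
    if dup.any():
        raise SchemaError("duplicate (sample_id, layer) rows in lnc file")
    if (frame["lnc"] <= 0).any():
        raise SchemaError("lnc values must be positive")
    return frame


def write_surface(result, path) -> None:
    """Persist one correlation surface as CSV (grid header row/column)."""
    frame = pd.DataFrame(result.r_surface, index=result.grid, columns=result.grid)
    frame.to_csv(path, index_label="i_nm", float_format="%.10g")


def render_heatmap(result, path) -> None:
    """Correlation-matrix heatmap for one dual-band formula."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    extent = [result.grid[0], result.grid[-1], result.grid[0], result.grid[-1]]
    im = ax.imshow(
        result.r_surface,
        origin="lower",
        extent=extent,
        cmap="RdBu_r",
        vmin=-1,
        vmax=1,
        aspect="auto",
    )
    ax.set_xlabel("wavelength j (nm)")
    ax.set_ylabel("wavelength i (nm)")
    ax.set_title(f"{result.formula_id}: best |r|={abs(result.best_r):.3f} "
                 f"at {result.best_pair}")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_scatter(predictions: pd.DataFrame, path, title: str = "") -> None:
    """Observed-vs-predicted scatter with a 1:1 line for one grid cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    colors = {"modeling": "tab:red", "validation": "tab:blue"}
    for split_name, sub in predictions.groupby("split"):
        ax.scatter(
            sub["y"], sub["yhat"], s=18, label=split_name,
            color=colors.get(split_name, "gray"), alpha=0.8,
        )
    lims = [
        min(predictions["y"].min(), predictions["yhat"].min()),
        max(predictions["y"].max(), predictions["yhat"].max()),
    ]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("observed LNC")
    ax.set_ylabel("predicted LNC")
    if title:
        ax.set_title(title, fontsize=9)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, seed: int, config_dict: dict, files: list[Path]) -> Path:
    """Record config hash, seed, and a content hash per output file."""
    outdir = Path(outdir)
    config_json = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": json.loads(config_json),
        "files": {
            str(Path(f).relative_to(outdir)): file_sha256(f) for f in sorted(files)
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
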