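"""Exhaustive two-band index optimization against a trait vector.

For each dual-band formula the full wavelength-pair Pearson-correlation
surface is computed row-blockwise (one fixed band i at a time, all j
vectorized), and the optimal pair is the argmax of |r| over defined
entries with ties broken toward the smallest i, then smallest j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SpectrumSet
from .parameters import DEGENERATE_AT_EQUAL, DUAL_BAND_NAMES, dual_band_value


def critical_r(n: int, alpha: float = 0.05) -> float:
    """|r| threshold for two-sided significance at level alpha, n samples."""
    if n < 3:
        raise ValueError("n must be >= 3")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


def pearson_r_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p from the t distribution.

    NaN entries are deleted pairwise; returns ``(nan, nan)`` for zero
    variance or fewer than 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return (float("nan"), float("nan"))
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return (float("nan"), float("nan"))
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return (r, p)


@dataclass
class PairSearchResult:
    """Correlation surface of one dual-band formula against a target."""

    formula_id: str
    grid: np.ndarray  # wavelengths searched
    r_surface: np.ndarray  # (len(grid), len(grid)), NaN where undefined
    best_pair: tuple[int, int]
    best_r: float
    n: int


def _column_correlations(values: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``values`` with ``target`` (NaN-aware)."""
    n, m = values.shape
    r = np.full(m, np.nan)
    finite = np.isfinite(values)
    clean = finite.all(axis=0)
    if clean.any():
        v = values[:, clean]
        vc = v - v.mean(axis=0)
        tc = target - target.mean()
        denom = np.sqrt((vc * vc).sum(axis=0) * (tc @ tc))
        num = tc @ vc
        out = np.full(denom.shape, np.nan)
        np.divide(num, denom, out=out, where=denom != 0)
        r[clean] = np.clip(out, -1.0, 1.0)
    # Columns with undefined entries: pairwise deletion, one at a time.
    for k in np.nonzero(~clean)[0]:
        r[k] = pearson_r_with_p(values[:, k], target)[0]
    return r


def correlation_surface(
    spectra: SpectrumSet,
    target: np.ndarray,
    formula_id: str,
    grid: np.ndarray | None = None,
    stride: int | None = None,
) -> PairSearchResult:
    """Correlation of index(i, j) with the target for all ordered pairs.

    Parameters
    ----------
    grid
        Wavelength subset to search; defaults to the full instrument
        grid (optionally thinned with ``stride``).  Auxiliary fixed
        bands (550 nm for TVI, 455 nm for mSR/mNDI) always come from
        the full spectra, independent of the search grid.
    """
    if formula_id not in DUAL_BAND_NAMES:
        raise KeyError(f"unknown dual-band formula {formula_id!r}")
    target = np.asarray(target, dtype=float)
    if target.size != spectra.n_samples:
        raise ValueError("target must align with samples")
    if grid is None:
        grid = spectra.wavelengths
        if stride is not None and stride > 1:
            grid = grid[::stride]
    grid = np.asarray(grid, dtype=int)
    if not np.all(np.isin(grid, spectra.wavelengths)):
        raise ValueError("search grid must be a subset of the instrument grid")
    cols = np.searchsorted(spectra.wavelengths, grid)
    refl = spectra.reflectance[:, cols]  # (n, m)
    r550 = spectra.band(550)[:, None]
    r455 = spectra.band(455)[:, None]
    m = grid.size
    surface = np.empty((m, m))
    with np.errstate(divide="ignore", invalid="ignore"):
        for a in range(m):
            values = dual_band_value(
                formula_id, refl[:, a][:, None], refl, r550, r455
            )
            surface[a] = _column_correlations(values, target)
    if formula_id in DEGENERATE_AT_EQUAL:
        np.fill_diagonal(surface, np.nan)
    if np.all(np.isnan(surface)):
        raise ValueError(f"{formula_id}: correlation surface is entirely undefined")
    result = PairSearchResult(
        formula_id=formula_id,
        grid=grid,
        r_surface=surface,
        best_pair=(0, 0),
        best_r=float("nan"),
        n=int(np.isfinite(target).sum()),
    )
    i, j, r = best_pair(result)
    result.best_pair = (i, j)
    result.best_r = r
    return result


def best_pair(result: PairSearchResult) -> tuple[int, int, float]:
    """Argmax of |r| over defined entries; ties go to smallest i, then j.

    Row-major scanning realizes the tie rule exactly, because equal |r|
    values compare equal bit-for-bit for algebraically mirrored pairs.
    """
    absr = np.abs(result.r_surface)
    if np.all(np.isnan(absr)):
        raise ValueError("no defined entries in the surface")
    flat = np.nanargmax(absr)  # first occurrence in row-major order
    a, b = np.unravel_index(flat, absr.shape)
    return (
        int(result.grid[a]),
        int(result.grid[b]),
        float(result.r_surface[a, b]),
    )


def search_all_formulas(
    spectra: SpectrumSet,
    target: np.ndarray,
    grid: np.ndarray | None = None,
    stride: int | None = None,
    formulas: list[str] | None = None,
) -> dict[str, PairSearchResult]:
    """Run the pair search for every dual-band formula."""
    out = {}
    for fid in formulas or DUAL_BAND_NAMES:
        out[fid] = correlation_surface(spectra, target, fid, grid=grid, stride=stride)
    return out


def _p_from_r(r: float, n: int) -> float:
    if np.isnan(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


def best_pairs_table(results: dict[str, PairSearchResult]) -> "pd.DataFrame":
    """Per-formula best-pair summary (formula, i, j, r, p, n)."""
    import pandas as pd

    rows = []
    for fid, res in results.items():
        i, j = res.best_pair
        rows.append(
            {
                "formula": fid,
                "i": i,
                "j": j,
                "r": res.best_r,
                "p": _p_from_r(res.best_r, res.n),
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
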