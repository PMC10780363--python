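"""Spectral preprocessing: grid validation, smoothing, first derivatives.

Smoothing is Savitzky-Golay with a 9-point window and a 4th-order
polynomial by default, applied with mirror padding so the output grid
equals the input grid.  The derivative is a plain forward first
difference per nm, so windowed derivative sums telescope exactly to
endpoint reflectance differences.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .core import FULL_GRID, DerivativeSet, SchemaError, SpectrumSet


def validate_full_grid(spectra: SpectrumSet) -> None:
    """Require the full 1 nm instrument grid (350-1830 nm, 1481 bands)."""
    if spectra.wavelengths.size != FULL_GRID.size or np.any(
        spectra.wavelengths != FULL_GRID
    ):
        steps = np.diff(spectra.wavelengths)
        gaps = spectra.wavelengths[:-1][steps != 1]
        if gaps.size:
            raise SchemaError(
                f"wavelength grid has a gap after {int(gaps[0])} nm; "
                "expected contiguous 1 nm steps 350-1830"
            )
        raise SchemaError(
            f"wavelength grid spans {spectra.wavelengths[0]}-"
            f"{spectra.wavelengths[-1]} nm; expected 350-1830"
        )


def savitzky_golay_smooth(
    spectra: SpectrumSet,
    window: int = 9,
    order: int = 4,
    iterations: int = 1,
) -> SpectrumSet:
    """Smooth every spectrum with a Savitzky-Golay filter.

    Parameters
    ----------
    window
        Odd window length in grid points.
    order
        Polynomial order of the local fits; must be < ``window``.
    iterations
        Number of repeated smoothing passes (the convention where the
        smoothing count, rather than the polynomial order, is iterated);
        default is a single pass.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than window")
    if window >= spectra.n_bands:
        raise ValueError("window must be shorter than the spectrum")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    out = spectra.reflectance
    for _ in range(iterations):
        out = savgol_filter(out, window, order, axis=-1, mode="mirror")
    return SpectrumSet(spectra.wavelengths.copy(), out, list(spectra.sample_ids))


def first_derivative(spectra: SpectrumSet) -> DerivativeSet:
    """Forward first difference (R[lambda+1] - R[lambda]) / 1 nm.

    The result has one fewer band than the input; entry ``k`` is indexed
    at the left endpoint ``wavelengths[k]``.
    """
    steps = np.diff(spectra.wavelengths).astype(float)
    values = np.diff(spectra.reflectance, axis=-1) / steps
    return DerivativeSet(
        spectra.wavelengths[:-1].copy(), values, list(spectra.sample_ids)
    )
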