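"""Shared data containers and constants for the spectral pipeline.

Everything downstream works on a fixed 1 nm instrument grid from 350 to
1830 nm (1481 bands).  A :class:`SpectrumSet` holds one reflectance vector
per sample on that grid; a :class:`ParameterMatrix` holds one row of named
spectral parameters per sample, each column tagged with its parameter
class (``empirical``, ``trilateral`` or ``dualband``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRID_START = 350
GRID_STOP = 1830
FULL_GRID = np.arange(GRID_START, GRID_STOP + 1)
N_BANDS = FULL_GRID.size  # 1481

#: Parameter class tags used throughout screening and reporting.
CLASS_EMPIRICAL = "empirical"
CLASS_TRILATERAL = "trilateral"
CLASS_DUALBAND = "dualband"
PARAMETER_CLASSES = (CLASS_EMPIRICAL, CLASS_TRILATERAL, CLASS_DUALBAND)

LAYERS = ("RL", "LL", "CL")


class SchemaError(ValueError):
    """Raised when an input table violates the expected file schema."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message is stage-tagged."""


@dataclass
class SpectrumSet:
    """Reflectance spectra for a set of samples on a common wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing integer wavelengths in nm, shape ``(n_bands,)``.
    reflectance
        Array of shape ``(n_samples, n_bands)``.
    sample_ids
        Unique sample identifiers, one per row of ``reflectance``.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=int)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths.ndim != 1:
            raise SchemaError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SchemaError("wavelengths must be strictly increasing")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise SchemaError(
                f"reflectance has {self.reflectance.shape[1]} bands, "
                f"grid has {self.wavelengths.size}"
            )
        if len(self.sample_ids) != self.reflectance.shape[0]:
            raise SchemaError("one sample_id required per reflectance row")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError("duplicate sample ids")
        if not np.all(np.isfinite(self.reflectance)):
            raise SchemaError("reflectance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def band_index(self, nm: int) -> int:
        idx = np.searchsorted(self.wavelengths, nm)
        if idx >= self.wavelengths.size or self.wavelengths[idx] != nm:
            raise KeyError(f"wavelength {nm} nm not on the grid")
        return int(idx)

    def band(self, nm: int) -> np.ndarray:
        """Reflectance column at wavelength ``nm`` (shape ``(n_samples,)``)."""
        return self.reflectance[:, self.band_index(nm)]

    def select_samples(self, ids: list[str]) -> "SpectrumSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[s] for s in ids]
        return SpectrumSet(self.wavelengths, self.reflectance[rows], list(ids))


@dataclass
class DerivativeSet:
    """First-difference spectra; wavelengths index the left endpoints."""

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)


@dataclass
class ParameterMatrix:
    """Samples x named spectral parameters, with a class tag per column."""

    values: pd.DataFrame  # index: sample_id; columns: parameter names
    class_tags: dict[str, str]

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            raise SchemaError("duplicate parameter columns")
        missing = [c for c in cols if c not in self.class_tags]
        if missing:
            raise SchemaError(f"columns without class tag: {missing}")
        bad = {c: t for c, t in self.class_tags.items() if t not in PARAMETER_CLASSES}
        if bad:
            raise SchemaError(f"unknown class tags: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    def columns_of(self, class_tag: str) -> list[str]:
        return [c for c in self.values.columns if self.class_tags[c] == class_tag]

    def undefined_counts(self) -> pd.Series:
        """Number of undefined (NaN) entries per column."""
        return self.values.isna().sum()

    def to_csv(self, path) -> None:
        # Two header rows: class tags on top, parameter names below.
        frame = self.values.copy()
        frame.columns = pd.MultiIndex.from_tuples(
            [(self.class_tags[c], c) for c in frame.columns],
            names=["class", "parameter"],
        )
        frame.to_csv(path, index_label="sample_id")

    @classmethod
    def read_csv(cls, path) -> "ParameterMatrix":
        frame = pd.read_csv(path, header=[0, 1], index_col=0)
        tags = {name: tag for tag, name in frame.columns}
        frame.columns = [name for _, name in frame.columns]
        frame.index = frame.index.astype(str)
        return cls(frame, tags)

    @staticmethod
    def concat(parts: list["ParameterMatrix"]) -> "ParameterMatrix":
        values = pd.concat([p.values for p in parts], axis=1)
        tags: dict[str, str] = {}
        for p in parts:
            tags.update(p.class_tags)
        return ParameterMatrix(values, tags)
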