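"""Spectral domain types and I/O.

A spectral table is a wide CSV: first column is the sample id, the remaining
column headers are wavelengths in nm. Values are dimensionless reflectance
or absorbance, tracked by :attr:`SpectraSet.mode`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraSet",
    "read_spectra_table",
    "write_spectra_table",
    "average_scans",
    "to_absorbance",
]

#: Instrument limits for the default profile (nm).
DEFAULT_BOUNDS = (200.0, 1100.0)


class SpectraFormatError(ValueError):
    """Malformed spectral table (headers, duplicates, non-numeric cells)."""


class SpectraStateError(ValueError):
    """Operation applied to a SpectraSet in the wrong mode."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm."""

    values: np.ndarray
    bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        lo, hi = self.bounds
        if values[0] < lo or values[-1] > hi:
            raise ValueError(
                f"wavelengths outside instrument bounds [{lo}, {hi}] nm"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def index_of(self, wavelength: float) -> int:
        """Index of the grid point nearest to ``wavelength``."""
        return int(np.argmin(np.abs(self.values - wavelength)))

    @classmethod
    def default(cls, start: float = 200.0, stop: float = 1100.0,
                step: float = 2.0) -> "WavelengthGrid":
        """Uniform instrument grid (200-1100 nm at 2 nm by default)."""
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))


@dataclass
class SpectraSet:
    """Per-sample spectra on a shared wavelength grid.

    Parameters
    ----------
    grid : WavelengthGrid
        Shared wavelength axis.
    intensities : ndarray, shape (n_samples, n_wavelengths)
        Reflectance or absorbance values.
    sample_ids : sequence of str
        Row identifiers. For scan-level sets these are scan ids.
    mode : {"reflectance", "absorbance"}
    scan_of : mapping, optional
        Maps a scan id to its parent sample id for pre-averaging sets.
    """

    grid: WavelengthGrid
    intensities: np.ndarray
    sample_ids: list[str]
    mode: str
    scan_of: Mapping[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.mode not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (samples x wavelengths)")
        if self.intensities.shape[1] != len(self.grid):
            raise ValueError(
                f"intensity columns ({self.intensities.shape[1]}) do not "
                f"match grid length ({len(self.grid)})"
            )
        if self.intensities.shape[0] != len(self.sample_ids):
            raise ValueError("one sample id per row required")
        if self.mode == "reflectance" and np.any(self.intensities <= 0):
            r, c = np.argwhere(self.intensities <= 0)[0]
            raise ValueError(
                f"non-positive reflectance at sample {self.sample_ids[r]!r}, "
                f"wavelength {self.grid.values[c]:g} nm"
            )

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def select_wavelengths(self, indices: Sequence[int]) -> "SpectraSet":
        """Restrict to a subset of wavelength columns (indices into grid)."""
        idx = np.asarray(sorted(indices), dtype=int)
        sub = WavelengthGrid(self.grid.values[idx], bounds=self.grid.bounds)
        return SpectraSet(sub, self.intensities[:, idx],
                          list(self.sample_ids), self.mode, self.scan_of)


def read_spectra_table(path: str | Path, mode: str) -> SpectraSet:
    """Read a wide spectral CSV into a :class:`SpectraSet`.

    The first column holds sample ids; every other header must parse as a
    wavelength in nm. Columns are sorted by wavelength; row order preserved.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    if len(header) < 2:
        raise SpectraFormatError(f"{path}: need an id column plus wavelengths")
    try:
        wavelengths = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-wavelength header: {exc}") from exc
    if np.unique(wavelengths).size != wavelengths.size:
        raise SpectraFormatError(f"{path}: duplicate wavelength headers")
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    id_col = df.columns[0]
    order = np.argsort(wavelengths)
    data = df.iloc[:, 1:].to_numpy()
    for (r, c), v in np.ndenumerate(data):
        if not isinstance(v, (int, float, np.integer, np.floating)):
            try:
                float(v)
            except (TypeError, ValueError):
                raise SpectraFormatError(
                    f"{path}: non-numeric value {v!r} at row "
                    f"{df.iloc[r, 0]!r}, column {df.columns[1 + c]}"
                ) from None
    values = data.astype(float)[:, order]
    grid = WavelengthGrid(wavelengths[order])
    return SpectraSet(grid, values, list(df[id_col]), mode)


def write_spectra_table(s: SpectraSet, path: str | Path) -> None:
    """Write a :class:`SpectraSet` as a wide CSV (id + wavelength columns)."""
    cols = {"id": s.sample_ids}
    for j, w in enumerate(s.grid.values):
        cols[f"{w:g}"] = s.intensities[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def average_scans(scans: SpectraSet, scans_per_sample: int | None = None) -> SpectraSet:
    """Average consecutive scan groups (or groups from ``scan_of``) per sample.

    Each output row is the arithmetic mean of its scans; mode is unchanged.
    """
    if scans.scan_of is not None:
        groups: dict[str, list[int]] = {}
        for i, sid in enumerate(scans.sample_ids):
            groups.setdefault(scans.scan_of[sid], []).append(i)
        ids = list(groups)
        means = np.stack([scans.intensities[groups[g]].mean(axis=0) for g in ids])
        return SpectraSet(scans.grid, means, ids, scans.mode)
    if scans_per_sample is None or scans_per_sample < 1:
        raise ValueError("scans_per_sample required when scan_of is absent")
    n = scans.n_samples
    if n % scans_per_sample:
        raise ValueError(
            f"{n} scans not divisible by scans_per_sample={scans_per_sample} "
            "and no scan_of map provided"
        )
    k = n // scans_per_sample
    means = scans.intensities.reshape(k, scans_per_sample, -1).mean(axis=1)
    ids = [scans.sample_ids[i * scans_per_sample] for i in range(k)]
    # strip a trailing scan suffix like "_s0" if present so ids stay sample-level
    ids = [sid.rsplit("_s", 1)[0] if "_s" in sid else sid for sid in ids]
    if len(set(ids)) != len(ids):
        ids = [f"sample{i}" for i in range(k)]
    return SpectraSet(scans.grid, means, ids, scans.mode)


def to_absorbance(s: SpectraSet) -> SpectraSet:
    """Convert reflectance to absorbance, A = log10(1/R), element-wise."""
    if s.mode != "reflectance":
        raise SpectraStateError("SpectraSet is already in absorbance mode")
    # the reflectance invariant guarantees R > 0
    values = np.log10(1.0 / s.intensities)
    return SpectraSet(s.grid, values, list(s.sample_ids), "absorbance", s.scan_of)
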