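"""Labeled spectral datasets: container, delimited-text I/O, region selection.

A dataset is the N x p intensity matrix ``X`` of N spectra sampled on a
common, strictly increasing wavenumber axis (cm^-1), together with a binary
label vector ``W`` (1 = first sample, 0 = second sample).

The on-disk format is "wide": one row per spectrum, a reserved ``label``
column first, and one column per wavenumber with the wavenumber itself as
the column header.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError, EmptyRegionError, ShapeError

__all__ = [
    "SpectralDataset",
    "SpectralRegion",
    "LW_REGION",
    "HW_REGION",
    "read_dataset",
    "write_dataset",
    "select_region",
    "resolve_region",
]


@dataclass
class SpectralDataset:
    """N spectra on a shared wavenumber axis with binary labels.

    Parameters
    ----------
    wavenumbers : (p,) float array, strictly increasing, cm^-1.
    intensities : (N, p) float array of intensities (arbitrary counts).
    labels : (N,) int array with values in {0, 1}; 1 marks the first sample.
    sample_names : pair of identifiers, ``(name_of_label_1, name_of_label_0)``.
    metadata : free-form provenance dict (seeds, injected-outlier rows, ...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray
    sample_names: tuple[str, str] = ("first", "second")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.intensities.shape[0] != self.labels.shape[0]:
            raise ShapeError(
                f"{self.intensities.shape[0]} spectra but {self.labels.shape[0]} labels"
            )
        if self.intensities.shape[1] != self.wavenumbers.shape[0]:
            raise ShapeError(
                f"{self.intensities.shape[1]} intensity columns but "
                f"{self.wavenumbers.shape[0]} wavenumbers"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise DataFormatError("wavenumber axis must be strictly increasing")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise DataFormatError(f"labels must be 0/1, found {sorted(bad)}")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    def subset_rows(self, rows) -> "SpectralDataset":
        """Dataset restricted to the given row indices / boolean mask."""
        rows = np.asarray(rows)
        return replace(
            self,
            intensities=self.intensities[rows],
            labels=self.labels[rows],
            metadata=dict(self.metadata),
        )

    def with_intensities(self, intensities: np.ndarray) -> "SpectralDataset":
        """Same axis/labels with a replaced intensity matrix."""
        return replace(self, intensities=intensities, metadata=dict(self.metadata))


@dataclass(frozen=True)
class SpectralRegion:
    """Closed wavenumber interval [lo, hi] in cm^-1."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise EmptyRegionError(f"region bounds must satisfy lo < hi, got [{self.lo}, {self.hi}]")


#: Low-wavenumber window: DNA-nanowire interaction bands (Ag-N ~234 cm^-1,
#: Si ~514 cm^-1). On the default acquisition grid it contains 221 points.
LW_REGION = SpectralRegion(125.25, 549.27, "LW")

#: High-wavenumber window: CH/CH3 stretching (~2934 cm^-1), sensitive to
#: methylation. On the default acquisition grid it contains 570 points.
HW_REGION = SpectralRegion(2303.16, 3399.83, "HW")


def resolve_region(spec: str | SpectralRegion) -> SpectralRegion:
    """Parse ``"LW"``, ``"HW"`` or ``"lo:hi"`` into a :class:`SpectralRegion`."""
    if isinstance(spec, SpectralRegion):
        return spec
    s = str(spec).strip()
    if s.upper() == "LW":
        return LW_REGION
    if s.upper() == "HW":
        return HW_REGION
    if ":" in s:
        lo, hi = s.split(":", 1)
        try:
            return SpectralRegion(float(lo), float(hi), s)
        except ValueError as exc:
            raise EmptyRegionError(f"cannot parse region {spec!r}") from exc
    raise EmptyRegionError(f"cannot parse region {spec!r}: expected LW, HW or lo:hi")


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path,
    label_column: str = "label",
    sep: str | None = None,
    sample_names: tuple[str, str] = ("first", "second"),
) -> SpectralDataset:
    """Read a wide delimited-text spectra file.

    The header row carries the wavenumbers; ``label_column`` (default the
    reserved first column ``"label"``) carries the 0/1 labels. Separator is
    inferred from the extension (TSV for ``.tsv``/``.tab``, else CSV) unless
    given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, sep))
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    if label_column not in df.columns:
        raise DataFormatError(f"{path}: missing label column {label_column!r}")
    labels_raw = df.pop(label_column)
    try:
        wavenumbers = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-numeric wavenumber header: {exc}") from exc
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise DataFormatError(
                    f"{path}: non-numeric cell at row {row}, column {col!r}"
                )
        values = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise DataFormatError(f"{path}: missing value at row {i}, column {df.columns[j]!r}")
    try:
        labels = labels_raw.astype(int).to_numpy()
    except (ValueError, TypeError) as exc:
        raise DataFormatError(f"{path}: non-integer label: {exc}") from exc
    return SpectralDataset(
        wavenumbers=wavenumbers,
        intensities=values.astype(float),
        labels=labels,
        sample_names=sample_names,
    )


def write_dataset(ds: SpectralDataset, path, label_column: str = "label", sep: str | None = None) -> None:
    """Write a dataset in the wide delimited-text format read_dataset parses."""
    path = Path(path)
    df = pd.DataFrame(ds.intensities, columns=[repr(float(w)) for w in ds.wavenumbers])
    df.insert(0, label_column, ds.labels)
    df.to_csv(path, sep=_sep_for(path, sep), index=False)


def select_region(ds: SpectralDataset, region: SpectralRegion | str) -> SpectralDataset:
    """Restrict a dataset to the columns with lo <= wavenumber <= hi.

    Both interval ends are inclusive; labels are unchanged. Raises
    :class:`EmptyRegionError` when no axis point falls inside the region.
    """
    region = resolve_region(region)
    mask = (ds.wavenumbers >= region.lo) & (ds.wavenumbers <= region.hi)
    if not mask.any():
        raise EmptyRegionError(
            f"region [{region.lo}, {region.hi}] contains no axis point "
            f"(axis spans [{ds.wavenumbers[0]}, {ds.wavenumbers[-1]}])"
        )
    return replace(
        ds,
        wavenumbers=ds.wavenumbers[mask],
        intensities=ds.intensities[:, mask],
        metadata=dict(ds.metadata),
    )
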