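"""Preprocessing: baseline correction, outlier rejection, smoothing.

The canonical stage order is background correction (iterative polynomial
fit, order 3) -> decision-surface outlier removal (pointwise mean +/- 3 SD
per sample group) -> Savitzky-Golay smoothing. :func:`preprocess` applies
the stages in that order and records it in the dataset metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectralDataset
from .errors import InsufficientDataError, InvalidConfigError

__all__ = [
    "PreprocessConfig",
    "background_correct",
    "remove_outliers",
    "smooth",
    "smooth_array",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Stage parameters.

    sg_window defaults to 91 points: a symmetric Savitzky-Golay filter
    needs an odd width, so the conventional 90-point window is widened to
    the nearest odd value.
    """

    background_order: int = 3
    sd_multiplier: float = 3.0
    sg_window: int = 91
    sg_polyorder: int = 3
    apply_background: bool = True
    iterative_background: bool = True
    pooled_outlier_groups: bool = False

    def __post_init__(self) -> None:
        if self.background_order < 0:
            raise InvalidConfigError("background_order must be >= 0")
        if self.sd_multiplier <= 0:
            raise InvalidConfigError("sd_multiplier must be > 0")
        if self.sg_window % 2 == 0:
            raise InvalidConfigError(
                f"sg_window must be odd; use {self.sg_window + 1} or {self.sg_window - 1}"
            )
        if self.sg_window <= self.sg_polyorder:
            raise InvalidConfigError("sg_window must exceed sg_polyorder")


def background_correct(
    x: np.ndarray,
    order: int = 3,
    iterative: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Subtract a polynomial fluorescence baseline from one spectrum.

    The baseline is an order-``order`` polynomial estimated by iterated
    clipped least squares: after each fit, points above the current
    baseline (the peaks) are replaced by the baseline value, so they stop
    dragging the fit upward. With ``iterative=False`` a single plain
    least-squares fit is used.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InvalidConfigError("background_correct expects a single spectrum")
    if order >= x.size:
        raise InvalidConfigError(f"order {order} needs more than {order} points, got {x.size}")
    u = np.linspace(-1.0, 1.0, x.size)
    work = x.copy()
    scale = np.ptp(x) or 1.0
    baseline = np.polynomial.Polynomial.fit(u, work, order)(u)
    if iterative:
        for _ in range(max_iter):
            clipped = np.minimum(work, baseline)
            new_baseline = np.polynomial.Polynomial.fit(u, clipped, order)(u)
            delta = np.max(np.abs(new_baseline - baseline))
            work, baseline = clipped, new_baseline
            if delta < tol * scale:
                break
    return x - baseline


def remove_outliers(
    ds: SpectralDataset,
    k: float = 3.0,
    per_group: bool = True,
) -> tuple[SpectralDataset, np.ndarray]:
    """Discard spectra leaving the pointwise mean +/- k*SD decision surface.

    For each label group separately (or pooled with ``per_group=False``),
    the pointwise mean and population SD define the surface; a spectrum
    with at least one point strictly outside is discarded. Points exactly
    on the surface count as inside. Returns the surviving dataset and the
    removed row indices.
    """
    if per_group:
        groups = [np.flatnonzero(ds.labels == v) for v in (0, 1) if np.any(ds.labels == v)]
    else:
        groups = [np.arange(ds.n_spectra)]
    keep = np.ones(ds.n_spectra, dtype=bool)
    for idx in groups:
        if idx.size < 2:
            raise InsufficientDataError(
                f"decision surface needs >= 2 spectra per group, got {idx.size}"
            )
        block = ds.intensities[idx]
        mean = block.mean(axis=0)
        sd = block.std(axis=0)
        with np.errstate(invalid="ignore"):
            outside = (block > mean + k * sd) | (block < mean - k * sd)
        keep[idx[outside.any(axis=1)]] = False
    removed = np.flatnonzero(~keep)
    out = ds.subset_rows(keep)
    out.metadata["removed_outliers"] = removed.tolist()
    return out, removed


def smooth_array(X: np.ndarray, window: int = 91, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing along the wavenumber axis.

    Interior points use the convolution form of the filter; near the edges
    the filter falls back to least-squares polynomial fits on the
    truncated windows (``mode="interp"``).
    """
    X = np.asarray(X, dtype=float)
    if window % 2 == 0:
        raise InvalidConfigError(
            f"Savitzky-Golay window must be odd; got {window}, use {window + 1} or {window - 1}"
        )
    if window <= polyorder:
        raise InvalidConfigError(f"window {window} must exceed polyorder {polyorder}")
    if window > X.shape[-1]:
        raise InvalidConfigError(
            f"window {window} exceeds the {X.shape[-1]}-point spectrum"
        )
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=-1, mode="interp")


def smooth(ds: SpectralDataset, window: int = 91, polyorder: int = 3) -> SpectralDataset:
    """Dataset-level Savitzky-Golay smoothing (see :func:`smooth_array`)."""
    return ds.with_intensities(smooth_array(ds.intensities, window, polyorder))


def preprocess(
    ds: SpectralDataset, config: PreprocessConfig | None = None
) -> tuple[SpectralDataset, dict]:
    """Run the full pipeline: background -> outlier removal -> smoothing.

    Returns the cleaned dataset and a stage log with the order executed and
    the removed-outlier rows; the log is also merged into the dataset
    metadata.
    """
    config = config or PreprocessConfig()
    stages: list[str] = []
    if config.apply_background:
        corrected = np.vstack(
            [
                background_correct(
                    row, config.background_order, iterative=config.iterative_background
                )
                for row in ds.intensities
            ]
        )
        ds = ds.with_intensities(corrected)
        stages.append("background")
    ds, removed = remove_outliers(ds, config.sd_multiplier, per_group=not config.pooled_outlier_groups)
    stages.append("outliers")
    ds = smooth(ds, config.sg_window, config.sg_polyorder)
    stages.append("smooth")
    log = {"stage_order": stages, "removed_outliers": removed.tolist()}
    ds.metadata.update(log)
    return ds, log
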