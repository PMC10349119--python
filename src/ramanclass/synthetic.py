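"""Two-class synthetic SERS-like DNA spectra.

The generator emulates the statistical structure of Raman maps of genomic
DNA dried onto Ag-coated silicon nanowires: a smooth fluorescence baseline,
Lorentzian (or Gaussian) bands at the characteristic positions — the Ag-N
stretch near 234 cm^-1, the Si line near 514 cm^-1, in-plane base/phosphate
bands between 600 and 1200 cm^-1, and the broad CH/CH3 stretch near
2934 cm^-1 — plus i.i.d. Gaussian noise and a small fraction of single-point
gross outliers. A class effect is a multiplicative change of a band
amplitude in class 1 relative to class 0 (``class_delta``), mimicking the
intensity differences that separate tumor subtypes.

Intensities are in arbitrary counts; the default scale is O(1-10) so that
downstream models can consume the spectra untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import SpectralDataset
from .errors import InvalidConfigError

__all__ = [
    "PeakSpec",
    "SyntheticConfig",
    "generate_axis",
    "generate_spectrum",
    "generate_dataset",
    "default_peaks",
    "default_config",
    "two_class_config",
]

#: Default acquisition grid matching the study design: 1700 uniformly
#: spaced points from 125.25 to 3399.83 cm^-1. With this grid the LW window
#: [125.25, 549.27] holds 221 points and the HW window [2303.16, 3399.83]
#: holds 570.
DEFAULT_AXIS = (125.25, 3399.83, 1700)


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band.

    center/width in cm^-1 (width is the half-width at half-maximum of a
    Lorentzian, or the Gaussian sigma), amplitude in intensity counts, and
    ``class_delta`` the multiplicative amplitude factor applied in class 1.
    """

    center: float
    width: float
    amplitude: float
    class_delta: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidConfigError(f"peak width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise InvalidConfigError(f"peak amplitude must be >= 0, got {self.amplitude}")
        if self.class_delta < 0:
            raise InvalidConfigError(f"class_delta must be >= 0, got {self.class_delta}")

    def profile(self, wavenumbers: np.ndarray, kind: str = "lorentzian") -> np.ndarray:
        """Unit-amplitude line shape evaluated on the axis."""
        u = (wavenumbers - self.center) / self.width
        if kind == "lorentzian":
            return 1.0 / (1.0 + u * u)
        if kind == "gaussian":
            return np.exp(-0.5 * u * u)
        raise InvalidConfigError(f"unknown peak profile {kind!r}")


def default_peaks(
    lw_delta: float = 1.0,
    hw_delta: float = 1.0,
    dna_delta: float = 1.0,
) -> tuple[PeakSpec, ...]:
    """The default band set.

    ``lw_delta`` scales the class effect on the Si band (514 cm^-1),
    ``hw_delta`` on the CH/CH3 band (2934 cm^-1), ``dna_delta`` on the
    600-1200 cm^-1 DNA backbone/base bands.
    """
    return (
        PeakSpec(234.0, 40.0, 1.2),                       # Ag-N stretch
        PeakSpec(514.0, 12.0, 2.0, class_delta=lw_delta),  # Si line
        PeakSpec(730.0, 18.0, 0.6, class_delta=dna_delta),  # adenine ring
        PeakSpec(785.0, 16.0, 0.9, class_delta=dna_delta),  # backbone / pyrimidine
        PeakSpec(1090.0, 22.0, 0.8, class_delta=dna_delta),  # PO2- stretch
        PeakSpec(2934.0, 55.0, 3.0, class_delta=hw_delta),  # CH2/CH3 stretch
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a two-class synthetic acquisition.

    ``baseline_coeffs`` are polynomial coefficients (ascending order,
    intensity counts) evaluated in the normalized coordinate
    u = (w - axis_start)/(axis_stop - axis_start) in [0, 1]; this keeps the
    coefficients O(1) regardless of the axis units. Outliers are
    single-point spikes of ``outlier_magnitude * noise_sd`` counts injected
    at one random position of a random ``outlier_rate`` fraction of rows.
    """

    axis_start: float = DEFAULT_AXIS[0]
    axis_stop: float = DEFAULT_AXIS[1]
    axis_points: int = DEFAULT_AXIS[2]
    peaks: tuple[PeakSpec, ...] = field(default_factory=default_peaks)
    baseline_coeffs: tuple[float, ...] = (3.0, -2.6, 1.4, 0.5)
    noise_sd: float = 0.08
    noise_dist: str = "uniform"
    noise_clip: float = 2.8
    outlier_rate: float = 0.005
    outlier_magnitude: float = 30.0
    n_per_class: int = 2000
    seed: int = 0
    peak_profile: str = "lorentzian"
    sample_names: tuple[str, str] = ("first", "second")

    def __post_init__(self) -> None:
        if self.axis_points < 2:
            raise InvalidConfigError("axis_points must be >= 2")
        if not self.axis_stop > self.axis_start:
            raise InvalidConfigError("axis_stop must exceed axis_start")
        if not 0 <= self.outlier_rate < 1:
            raise InvalidConfigError("outlier_rate must be in [0, 1)")
        if self.n_per_class < 1:
            raise InvalidConfigError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.noise_dist not in ("gaussian", "truncated_gaussian", "uniform"):
            raise InvalidConfigError(f"unknown noise_dist {self.noise_dist!r}")
        if self.noise_clip <= 0:
            raise InvalidConfigError("noise_clip must be > 0")

    @property
    def wavenumbers(self) -> np.ndarray:
        return generate_axis(self.axis_start, self.axis_stop, self.axis_points)


def generate_axis(start: float, stop: float, n: int) -> np.ndarray:
    """Uniform, strictly increasing wavenumber grid with both endpoints."""
    if n < 2:
        raise InvalidConfigError(f"axis needs at least 2 points, got {n}")
    if not stop > start:
        raise InvalidConfigError(f"axis span must be positive, got [{start}, {stop}]")
    return np.linspace(start, stop, n)


def _baseline(config: SyntheticConfig, wavenumbers: np.ndarray) -> np.ndarray:
    u = (wavenumbers - config.axis_start) / (config.axis_stop - config.axis_start)
    return np.polynomial.polynomial.polyval(u, np.asarray(config.baseline_coeffs, dtype=float))


def clean_spectrum(config: SyntheticConfig, class_label: int, wavenumbers: np.ndarray | None = None) -> np.ndarray:
    """Noise-free expected spectrum for one class (baseline + bands)."""
    w = config.wavenumbers if wavenumbers is None else wavenumbers
    y = _baseline(config, w)
    for pk in config.peaks:
        amp = pk.amplitude * (pk.class_delta if class_label == 1 else 1.0)
        y = y + amp * pk.profile(w, config.peak_profile)
    return y


def _noise(config: SyntheticConfig, rng: np.random.Generator, shape) -> np.ndarray:
    """Additive mean-zero noise field with SD ``noise_sd``.

    The default is uniform (bounded at sqrt(3) SDs): with ~1700 points per
    spectrum, unbounded Gaussian noise would put several points of almost
    every spectrum beyond the pointwise 3-SD decision surface, so the
    outlier filter would discard essentially all spectra instead of the
    few gross outliers it is meant to catch. Bounded noise keeps ordinary
    spectra strictly inside the surface even when the pointwise SD is
    estimated from few spectra. ``noise_dist`` also accepts ``"gaussian"``
    and ``"truncated_gaussian"`` (clipped at ``noise_clip`` SDs).
    """
    if config.noise_dist == "uniform":
        half = np.sqrt(3.0) * config.noise_sd
        return rng.uniform(-half, half, size=shape)
    noise = rng.normal(0.0, config.noise_sd, size=shape)
    if config.noise_dist == "truncated_gaussian":
        bound = config.noise_clip * config.noise_sd
        noise = np.clip(noise, -bound, bound)
    return noise


def generate_spectrum(config: SyntheticConfig, class_label: int, rng: np.random.Generator) -> np.ndarray:
    """One spectrum: class-conditional clean signal plus noise."""
    if class_label not in (0, 1):
        raise InvalidConfigError(f"class_label must be 0 or 1, got {class_label}")
    y = clean_spectrum(config, class_label)
    if config.noise_sd > 0:
        y = y + _noise(config, rng, y.shape)
    return y


def generate_dataset(config: SyntheticConfig) -> SpectralDataset:
    """Balanced two-class dataset, fully reproducible from ``config.seed``.

    Rows 0..n-1 are class 1 (first sample), rows n..2n-1 class 0. The
    injected-outlier row indices are recorded in ``metadata["outlier_rows"]``.
    """
    rng = np.random.default_rng(config.seed)
    w = config.wavenumbers
    n = config.n_per_class
    clean1 = clean_spectrum(config, 1, w)
    clean0 = clean_spectrum(config, 0, w)
    X = np.empty((2 * n, w.size))
    X[:n] = clean1
    X[n:] = clean0
    if config.noise_sd > 0:
        X += _noise(config, rng, X.shape)
    labels = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    outlier_rows = np.flatnonzero(rng.random(2 * n) < config.outlier_rate)
    for i in outlier_rows:
        j = rng.integers(0, w.size)
        X[i, j] += config.outlier_magnitude * (config.noise_sd if config.noise_sd > 0 else 1.0)
    return SpectralDataset(
        wavenumbers=w,
        intensities=X,
        labels=labels,
        sample_names=config.sample_names,
        metadata={
            "generator_seed": config.seed,
            "outlier_rows": outlier_rows.tolist(),
        },
    )


def default_config(**overrides) -> SyntheticConfig:
    """Study-scale configuration: 2000 spectra per class on the default grid."""
    return SyntheticConfig(**overrides)


def two_class_config(
    effect: str | None = None,
    delta: float = 1.5,
    n_per_class: int = 2000,
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """Convenience scenarios for the pairwise comparisons.

    ``effect``:
      * ``None`` — null: both classes identically distributed.
      * ``"hw"`` — class effect only on the CH/CH3 band at 2934 cm^-1
        (the tumor-subtype-like pattern: separable in HW, not in LW).
      * ``"lw"`` — class effect only on the Si band at 514 cm^-1
        (the reversed pattern).
      * ``"both"`` — effects in both windows (healthy-vs-tumor-like).
    """
    deltas = {
        None: dict(),
        "null": dict(),
        "hw": dict(hw_delta=delta),
        "lw": dict(lw_delta=delta),
        "both": dict(lw_delta=delta, hw_delta=delta, dna_delta=delta),
    }
    if effect not in deltas:
        raise InvalidConfigError(f"unknown effect scenario {effect!r}")
    peaks = default_peaks(**deltas[effect])
    return SyntheticConfig(peaks=peaks, n_per_class=n_per_class, seed=seed, **overrides)


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a plain (e.g. YAML-loaded) mapping.

    Recognized keys mirror :class:`SyntheticConfig`; ``peaks`` is a list of
    ``{center, width, amplitude, class_delta}`` mappings, and the shortcut
    keys ``effect``/``delta`` select a :func:`two_class_config` scenario.
    """
    d = dict(d)
    if "effect" in d:
        effect = d.pop("effect")
        delta = float(d.pop("delta", 1.5))
        return two_class_config(effect=effect, delta=delta, **_coerce(d))
    if "peaks" in d:
        d["peaks"] = tuple(PeakSpec(**p) for p in d["peaks"])
    return SyntheticConfig(**_coerce(d))


def _coerce(d: dict) -> dict:
    out = dict(d)
    for key in ("baseline_coeffs", "sample_names"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def with_effect(config: SyntheticConfig, center: float, delta: float) -> SyntheticConfig:
    """Copy of ``config`` with the class effect of the band at ``center`` set."""
    peaks = tuple(
        replace(pk, class_delta=delta) if pk.center == center else pk for pk in config.peaks
    )
    if peaks == config.peaks and not any(pk.center == center for pk in config.peaks):
        raise InvalidConfigError(f"no band at {center} cm^-1 in this config")
    return replace(config, peaks=peaks)
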