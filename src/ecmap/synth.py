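"""Synthetic masked 4D series with planted hub/module structure.

Each module carries one latent band-limited Gaussian signal; module voxels
are that latent plus white noise, hub voxels load on the average of all
module latents.  Ground-truth labels (module id, or -1 for hubs) are
returned alongside the data so every downstream stage can be tested on
known structure.  Fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nifti_io import MaskGeometry, MaskedSeries

__all__ = ["SynthConfig", "module_layout", "generate", "two_condition_cohort",
           "HUB_LABEL"]

#: label value marking hub voxels in the ground-truth vector
HUB_LABEL = -1


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for the synthetic generator.

    ``module_bands_hz`` optionally assigns each module its own frequency
    band (overriding ``signal_band_hz``), which plants spectrally disjoint
    communities for coherence-based tests.
    """

    grid_shape: tuple = (10, 10, 5)
    n_modules: int = 4
    hub_fraction: float = 0.05
    signal_amplitude: float = 1.0
    noise_sd: float = 1.0
    signal_band_hz: tuple = (0.01, 0.1)
    module_bands_hz: tuple | None = None
    n_timepoints: int = 180
    tr_seconds: float = 2.3
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if not 0 < self.hub_fraction < 1:
            raise ValueError("hub_fraction must lie in (0, 1)")
        if self.signal_amplitude <= 0 or self.noise_sd <= 0:
            raise ValueError("signal_amplitude and noise_sd must be positive")
        if self.n_timepoints < 8:
            raise ValueError("n_timepoints must be >= 8")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        for band in self._bands():
            lo, hi = band
            if not 0 <= lo < hi:
                raise ValueError(f"invalid band {band}")
            if hi > nyquist + 1e-12:
                raise ValueError(
                    f"band {band} exceeds the Nyquist frequency "
                    f"{nyquist:.6g} Hz for TR={self.tr_seconds} s")
        if (self.module_bands_hz is not None
                and len(self.module_bands_hz) != self.n_modules):
            raise ValueError("module_bands_hz needs one band per module")

    def _bands(self):
        if self.module_bands_hz is not None:
            return [tuple(b) for b in self.module_bands_hz]
        return [tuple(self.signal_band_hz)] * self.n_modules

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


def _geometry(cfg: SynthConfig) -> MaskGeometry:
    affine = np.diag(list(cfg.voxel_size_mm) + [1.0])
    inside = np.ones(cfg.grid_shape, dtype=bool)
    return MaskGeometry.from_mask(inside, affine)


def module_layout(cfg: SynthConfig) -> np.ndarray:
    """Ground-truth labels: module id per voxel, HUB_LABEL for hubs.

    Hubs are spread evenly through the canonical voxel order; the remaining
    voxels form spatially contiguous blocks, one per module.  Deterministic
    (no RNG involved).
    """
    n = cfg.n_voxels
    n_hubs = max(1, int(round(cfg.hub_fraction * n)))
    hub_idx = np.unique(np.round(np.linspace(0, n - 1, n_hubs)).astype(int))
    labels = np.empty(n, dtype=int)
    labels[hub_idx] = HUB_LABEL
    rest = np.setdiff1d(np.arange(n), hub_idx)
    for m, chunk in enumerate(np.array_split(rest, cfg.n_modules)):
        labels[chunk] = m
    return labels


def band_limited_signal(rng: np.random.Generator, n_timepoints: int,
                        tr_seconds: float, band_hz) -> np.ndarray:
    """Unit-variance Gaussian signal restricted to a frequency band.

    White noise is filtered with a boxcar mask in the frequency domain and
    inverse-transformed; at least one frequency bin must fall in the band.
    """
    lo, hi = band_hz
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    keep = (freqs >= lo) & (freqs <= hi)
    keep[0] = False  # never keep DC
    if not keep.any():
        raise ValueError(
            f"band {band_hz} Hz contains no frequency bin for T="
            f"{n_timepoints}, TR={tr_seconds}")
    spectrum = np.fft.rfft(rng.standard_normal(n_timepoints))
    spectrum[~keep] = 0.0
    signal = np.fft.irfft(spectrum, n=n_timepoints)
    sd = signal.std()
    if sd == 0:
        raise ValueError("degenerate band-limited signal")
    return signal / sd


def _synthesize(cfg: SynthConfig, labels: np.ndarray,
                rng: np.random.Generator,
                coupling: np.ndarray | None = None) -> np.ndarray:
    """One subject's n x T data matrix.  ``coupling`` scales per-voxel
    signal amplitude (defaults to 1 everywhere)."""
    n, t = labels.size, cfg.n_timepoints
    bands = cfg._bands()
    latents = np.stack([
        band_limited_signal(rng, t, cfg.tr_seconds, bands[m])
        for m in range(cfg.n_modules)
    ])
    hub_signal = latents.mean(axis=0)
    if coupling is None:
        coupling = np.ones(n)
    data = cfg.noise_sd * rng.standard_normal((n, t))
    amp = cfg.signal_amplitude * coupling
    is_hub = labels == HUB_LABEL
    data[is_hub] += amp[is_hub, None] * hub_signal
    for m in range(cfg.n_modules):
        sel = labels == m
        data[sel] += amp[sel, None] * latents[m]
    return data


def generate(cfg: SynthConfig, seed: int | None = None):
    """Generate one subject: (MaskedSeries, ground-truth labels)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    geometry = _geometry(cfg)
    labels = module_layout(cfg)
    data = _synthesize(cfg, labels, rng)
    series = MaskedSeries(geometry=geometry, data=data,
                          tr_seconds=cfg.tr_seconds)
    return series, labels


def two_condition_cohort(cfg: SynthConfig, n_subjects: int,
                         effect_region: np.ndarray, effect_size: float,
                         seed: int | None = None):
    """Paired cohort: per subject, one series per condition.

    Condition B multiplies the signal coupling of ``effect_region`` voxels
    by ``1 + effect_size`` (effect_size 0 gives a null cohort where A and B
    are exchangeable).  Subjects are i.i.d. given the seed.

    Returns
    -------
    (series_a, series_b, labels)
        Two lists of MaskedSeries (matched subject order) and the
        ground-truth label vector.
    """
    effect_region = np.asarray(effect_region, dtype=int)
    if effect_size != 0 and effect_region.size == 0:
        raise ValueError("effect_region is empty")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    labels = module_layout(cfg)
    n = labels.size
    if effect_region.size and (effect_region.min() < 0
                               or effect_region.max() >= n):
        raise ValueError("effect_region indices outside the mask")
    geometry = _geometry(cfg)
    coupling_b = np.ones(n)
    coupling_b[effect_region] *= 1.0 + effect_size
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    series_a, series_b = [], []
    for _ in range(n_subjects):
        data_a = _synthesize(cfg, labels, rng)
        data_b = _synthesize(cfg, labels, rng, coupling=coupling_b)
        series_a.append(MaskedSeries(geometry=geometry, data=data_a,
                                     tr_seconds=cfg.tr_seconds))
        series_b.append(MaskedSeries(geometry=geometry, data=data_b,
                                     tr_seconds=cfg.tr_seconds))
    return series_a, series_b, labels
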