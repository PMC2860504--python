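"""Voxel-pair similarity metrics.

Two families are provided:

* time-domain: Pearson correlation, re-scaled to [0, 1] via ``(r + 1) / 2``
  or made non-negative via the absolute value;
* frequency-domain: lag-window spectral coherence (magnitude-squared) and
  phase coherence at a single frequency of interest.

Coherence here is the magnitude-squared form
``(c^2 + q^2) / (f_xx * f_yy)`` built from the cospectrum ``c`` and the
quadrature spectrum ``q`` of the lag-windowed cross-spectral density; it is
guaranteed to lie in [0, 1] up to estimator leakage, and is clipped there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nifti_io import MaskedSeries

__all__ = [
    "SimilarityMatrix", "SpectralConfig", "SpectralEstimate",
    "pearson", "scale_correlation", "abs_correlation",
    "correlation_similarity", "lag_window", "default_n_lags",
    "cross_spectral_estimate", "coherence", "phase_coherence",
    "coherence_similarity",
]

_COH_CLIP_TOL = 1e-6


class DegenerateSeriesError(ValueError):
    """A series has zero variance / zero auto-spectrum."""


# ---------------------------------------------------------------------------
# similarity matrix container
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Symmetric non-negative n x n voxel-pair similarity.

    ``form="dense"`` stores the full matrix in ``dense_values``.
    ``form="factored"`` stores an n x k factor ``Z`` representing
    ``A = (Z Z^T + 1 1^T) / 2`` (the scaled-correlation matrix) without
    ever materializing A.
    """

    n: int
    form: str
    metric_tag: str = ""
    dense_values: np.ndarray | None = field(default=None, repr=False)
    factor: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.form not in ("dense", "factored"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "dense":
            a = np.asarray(self.dense_values, dtype=float)
            if a.shape != (self.n, self.n):
                raise ValueError("dense_values must be n x n")
            if not np.allclose(a, a.T, atol=1e-10):
                raise ValueError("similarity matrix must be symmetric")
            if a.min() < -1e-10:
                raise ValueError("similarity entries must be non-negative")
            self.dense_values = np.clip(a, 0.0, None)
        else:
            z = np.asarray(self.factor, dtype=float)
            if z.ndim != 2 or z.shape[0] != self.n:
                raise ValueError("factor must be n x k")
            self.factor = z

    def materialize(self) -> np.ndarray:
        """Dense n x n array (builds it for the factored form)."""
        if self.form == "dense":
            return self.dense_values
        z = self.factor
        return (z @ z.T + 1.0) / 2.0

    def matvec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"expected vector of length {self.n}")
        if self.form == "dense":
            return self.dense_values @ x
        return factored_matvec(self.factor, x)

    def diagonal(self) -> np.ndarray:
        if self.form == "dense":
            return np.diag(self.dense_values).copy()
        return ((self.factor ** 2).sum(axis=1) + 1.0) / 2.0

    def has_offdiagonal_support(self) -> bool:
        """True iff every row has at least one non-zero off-diagonal entry."""
        if self.form == "factored":
            # entries are (r_ij + 1)/2 >= 0, zero only for exact r = -1;
            # a whole row of exact -1 correlations cannot occur for n >= 3
            # rows of unit-norm factors, so support is assumed.
            return True
        a = self.dense_values.copy()
        np.fill_diagonal(a, 0.0)
        return bool((a.max(axis=1) > 0).all())


def factored_matvec(factor: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Compute ``A @ x`` for ``A = (Z Z^T + 1 1^T)/2`` without forming A.

    Cost is O(n k) per call.
    """
    z = np.asarray(factor, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != (z.shape[0],):
        raise ValueError(
            f"vector length {x.shape} does not match factor rows {z.shape[0]}")
    return (z @ (z.T @ x) + x.sum()) / 2.0


# ---------------------------------------------------------------------------
# time-domain similarity
# ---------------------------------------------------------------------------

def pearson(x, y) -> float:
    """Sample linear correlation between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1D and of equal length")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd ** 2).mean())
    sy = np.sqrt((yd ** 2).mean())
    if sx == 0 or sy == 0:
        raise DegenerateSeriesError("correlation undefined for zero variance")
    r = float((xd * yd).mean() / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def scale_correlation(r: float) -> float:
    """Affine map [-1, 1] -> [0, 1]: ``(r + 1) / 2``."""
    r = float(r)
    if abs(r) > 1 + 1e-9:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    return (np.clip(r, -1.0, 1.0) + 1.0) / 2.0


def abs_correlation(r: float) -> float:
    """Alternative non-negative map: ``|r|``."""
    r = float(r)
    if abs(r) > 1 + 1e-9:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    return abs(np.clip(r, -1.0, 1.0))


def _correlation_factor(data: np.ndarray) -> np.ndarray:
    """Rows z_i = (x_i - mean) / (sd_pop * sqrt(T)) so that Z Z^T = R."""
    xd = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt((xd ** 2).sum(axis=1, keepdims=True))
    if (norms == 0).any():
        raise DegenerateSeriesError(
            "zero-variance voxel encountered; filter the mask first")
    return xd / norms


def correlation_similarity(series: MaskedSeries, mode: str = "scaled",
                           form: str = "dense") -> SimilarityMatrix:
    """Pairwise correlation similarity matrix for all in-mask voxels.

    Parameters
    ----------
    mode : {"scaled", "absolute"}
        ``scaled`` uses (r+1)/2; ``absolute`` uses |r|.
    form : {"dense", "factored"}
        The factored form holds the correlation factor Z only; it is
        available for ``mode="scaled"`` (|r| is not low-rank-representable).
    """
    if series.n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    if mode not in ("scaled", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    if form == "factored":
        if mode != "scaled":
            raise ValueError(
                "factored form is only supported for mode='scaled'")
        z = _correlation_factor(series.data)
        return SimilarityMatrix(n=series.n_voxels, form="factored", factor=z,
                                metric_tag="scaled-corr")
    z = _correlation_factor(series.data)
    r = np.clip(z @ z.T, -1.0, 1.0)
    if mode == "scaled":
        a = (r + 1.0) / 2.0
        tag = "scaled-corr"
    else:
        a = np.abs(r)
        tag = "abs-corr"
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0  # enforce exact symmetry
    return SimilarityMatrix(n=series.n_voxels, form="dense", dense_values=a,
                            metric_tag=tag)


# ---------------------------------------------------------------------------
# frequency-domain similarity
# ---------------------------------------------------------------------------

def default_n_lags(n_timepoints: int) -> int:
    """Rule-of-thumb lag count: round(2 sqrt(T)), clamped to [T/10, T/3]."""
    m = int(round(2.0 * np.sqrt(n_timepoints)))
    lo = max(1, n_timepoints // 10)
    hi = max(lo, n_timepoints // 3)
    return int(np.clip(m, lo, hi))


def lag_window(window: str, n_lags: int) -> np.ndarray:
    """Lag-window weights w_0..w_M.

    Tukey (Tukey-Hanning): ``w_k = (1 + cos(pi k / M)) / 2``.
    Parzen: the standard piecewise-cubic taper.
    Both satisfy w_0 = 1, w_M = 0 (Parzen: ~0) and decrease monotonically.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    k = np.arange(n_lags + 1, dtype=float)
    if window == "tukey":
        return 0.5 * (1.0 + np.cos(np.pi * k / n_lags))
    if window == "parzen":
        u = k / n_lags
        w = np.where(u <= 0.5,
                     1.0 - 6.0 * u ** 2 + 6.0 * u ** 3,
                     2.0 * (1.0 - u) ** 3)
        return w
    raise ValueError(f"unknown window {window!r}")


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the lag-window cross-spectral estimator.

    The frequency of interest is physical (Hz); internally it becomes
    ``omega = 2 pi f TR`` radians per sample.
    """

    frequency_hz: float
    tr_seconds: float
    n_lags: int
    window: str = "tukey"

    def __post_init__(self):
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if self.frequency_hz > nyquist + 1e-12:
            raise ValueError(
                f"frequency {self.frequency_hz} Hz exceeds the Nyquist "
                f"frequency {nyquist:.6g} Hz for TR={self.tr_seconds} s")
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")
        if self.window not in ("tukey", "parzen"):
            raise ValueError(f"unknown window {self.window!r}")

    @property
    def omega(self) -> float:
        """Angular frequency in radians per sample."""
        return 2.0 * np.pi * self.frequency_hz * self.tr_seconds

    @classmethod
    def for_series(cls, frequency_hz: float, series: MaskedSeries,
                   n_lags: int | None = None, window: str = "tukey"):
        if n_lags is None:
            n_lags = default_n_lags(series.n_timepoints)
        return cls(frequency_hz=frequency_hz, tr_seconds=series.tr_seconds,
                   n_lags=n_lags, window=window)


@dataclass(frozen=True)
class SpectralEstimate:
    """Cross- and auto-spectral quantities for one voxel pair at one frequency."""

    cospectrum: float
    quadrature: float
    auto_x: float
    auto_y: float


def _crosscov(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    """Biased sample cross-covariance (1/T) sum_t x_t y_{t+lag}."""
    t = x.size
    if lag >= 0:
        return float(x[:t - lag] @ y[lag:]) / t
    return float(x[-lag:] @ y[:t + lag]) / t


def cross_spectral_estimate(x, y, cfg: SpectralConfig) -> SpectralEstimate:
    """Lag-window cross-spectral estimate for one pair of series.

    Series are mean-centered here; the cross-covariance sequence over lags
    -M..M is tapered with the configured lag window and transformed at the
    single angular frequency ``cfg.omega``.  The constant 1/(2 pi) density
    factor is omitted: it cancels in coherence and phase.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1D and of equal length")
    t = x.size
    m = cfg.n_lags
    if m >= t:
        raise ValueError(f"n_lags={m} must be smaller than series length {t}")
    x = x - x.mean()
    y = y - y.mean()
    if not (x @ x) or not (y @ y):
        raise DegenerateSeriesError("zero-variance series in spectral estimate")
    w = lag_window(cfg.window, m)
    omega = cfg.omega
    ks = np.arange(-m, m + 1)
    wk = w[np.abs(ks)]
    cxy = np.array([_crosscov(x, y, int(k)) for k in ks])
    cxx = np.array([_crosscov(x, x, int(k)) for k in ks])
    cyy = np.array([_crosscov(y, y, int(k)) for k in ks])
    phase = np.exp(-1j * omega * ks)
    f_xy = np.sum(wk * cxy * phase)
    auto_x = float(np.real(np.sum(wk * cxx * phase)))
    auto_y = float(np.real(np.sum(wk * cyy * phase)))
    if auto_x <= 0 or auto_y <= 0:
        raise DegenerateSeriesError(
            f"non-positive auto-spectrum (auto_x={auto_x:.3g}, "
            f"auto_y={auto_y:.3g}); input degenerate at this frequency")
    return SpectralEstimate(cospectrum=float(np.real(f_xy)),
                            quadrature=float(-np.imag(f_xy)),
                            auto_x=auto_x, auto_y=auto_y)


def coherence(est: SpectralEstimate) -> float:
    """Magnitude-squared coherence ``(c^2 + q^2) / (auto_x auto_y)`` in [0, 1]."""
    if est.auto_x <= 0 or est.auto_y <= 0:
        raise DegenerateSeriesError("auto-spectra must be strictly positive")
    value = (est.cospectrum ** 2 + est.quadrature ** 2) / (est.auto_x * est.auto_y)
    if value > 1.0 + _COH_CLIP_TOL:
        raise ValueError(f"coherence {value} exceeds 1 beyond tolerance")
    return float(np.clip(value, 0.0, 1.0))


def phase_coherence(est: SpectralEstimate) -> float:
    """Phase angle of the cross-spectrum, in (-pi, pi].

    Antisymmetric under swapping the two series.
    """
    if est.cospectrum == 0 and est.quadrature == 0:
        raise ValueError("phase undefined: cross-spectrum is zero")
    phi = float(np.arctan2(est.quadrature, est.cospectrum))
    if phi <= -np.pi:
        phi = np.pi
    return phi


def coherence_similarity(series: MaskedSeries, cfg: SpectralConfig,
                         block_size: int = 256) -> SimilarityMatrix:
    """Dense matrix of pairwise magnitude-squared coherences at one frequency.

    Works block-wise over voxel rows so peak memory stays bounded by
    ``block_size * n`` per lag; the result is independent of ``block_size``.
    """
    n, t = series.data.shape
    if n < 2:
        raise ValueError("need at least 2 voxels")
    m = cfg.n_lags
    if m >= t:
        raise ValueError(f"n_lags={m} must be smaller than series length {t}")
    x = series.data - series.data.mean(axis=1, keepdims=True)
    w = lag_window(cfg.window, m)
    omega = cfg.omega
    cos_k = w[1:] * np.cos(omega * np.arange(1, m + 1))
    sin_k = w[1:] * np.sin(omega * np.arange(1, m + 1))

    co = np.zeros((n, n))
    quad = np.zeros((n, n))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        xb = x[start:stop]
        co[start:stop] += (xb @ x.T) * (w[0] / t)
        for k in range(1, m + 1):
            fwd = (xb[:, :t - k] @ x[:, k:].T) / t      # lag +k
            bwd = (xb[:, k:] @ x[:, :t - k].T) / t      # lag -k
            co[start:stop] += cos_k[k - 1] * (fwd + bwd)
            quad[start:stop] += sin_k[k - 1] * (fwd - bwd)
    auto = np.diag(co).copy()
    bad = np.flatnonzero(auto <= 0)
    if bad.size:
        raise DegenerateSeriesError(
            f"non-positive auto-spectrum for voxel(s) {bad[:5].tolist()} "
            f"at {cfg.frequency_hz} Hz")
    coh = (co ** 2 + quad ** 2) / np.outer(auto, auto)
    if coh.max() > 1.0 + _COH_CLIP_TOL:
        i, j = np.unravel_index(np.argmax(coh), coh.shape)
        raise ValueError(
            f"coherence {coh[i, j]} > 1 beyond tolerance for voxel pair "
            f"({i}, {j})")
    coh = np.clip(coh, 0.0, 1.0)
    np.fill_diagonal(coh, 1.0)
    coh = (coh + coh.T) / 2.0
    return SimilarityMatrix(n=n, form="dense", dense_values=coh,
                            metric_tag=f"coherence@{cfg.frequency_hz:g}Hz")
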