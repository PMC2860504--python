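"""Group-level statistics for centrality maps.

Pipeline: rank-based Gaussianization of each map, voxel-wise paired t-test
between conditions, conversion to z, an initial z-threshold (default 2.33),
and a Monte-Carlo cluster null that records per-iteration maximum cluster
size and maximum peak value.  A cluster is significant when its size OR its
peak exceeds the corresponding (1 - alpha/2) null quantile — an alpha/2
Bonferroni split across the two criteria, so a large cluster with a modest
peak and a small cluster with a very high peak can both reach significance.
Positive and negative tails are handled by running the negated map through
the same machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats
from scipy.special import ndtri

from .nifti_io import MaskGeometry

__all__ = [
    "ZMap", "Cluster", "ClusterReport", "NullDistribution",
    "gaussianize", "paired_t_map", "two_sample_t_map", "t_to_z",
    "label_clusters", "monte_carlo_null", "apply_cluster_correction",
    "filter_report",
]

logger = logging.getLogger(__name__)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ZMap:
    """Voxel-wise statistic map on a mask geometry."""

    values: np.ndarray
    geometry: MaskGeometry
    df: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.n_voxels,):
            raise ValueError("values length must equal the voxel count")
        if not np.isfinite(self.values).all():
            raise ValueError("statistic map contains non-finite values")

    def negated(self) -> "ZMap":
        return ZMap(values=-self.values, geometry=self.geometry, df=self.df)


@dataclass
class Cluster:
    label: int
    size_voxels: int
    size_mm3: float
    peak_value: float
    peak_coordinate: tuple
    significant: bool | None = None
    #: in-mask voxel indices of the cluster members
    members: tuple = ()


@dataclass
class ClusterReport:
    """Suprathreshold clusters, optionally with Monte-Carlo significance."""

    clusters: list
    z_threshold: float
    alpha: float | None = None
    size_threshold: float | None = None
    peak_threshold: float | None = None
    null_summary: dict | None = None

    def __post_init__(self):
        labels = [c.label for c in self.clusters]
        if len(labels) != len(set(labels)):
            raise ValueError("cluster labels must be unique")
        if any(c.size_voxels < 1 for c in self.clusters):
            raise ValueError("cluster sizes must be >= 1")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c.significant]


@dataclass
class NullDistribution:
    """Per-iteration maxima from the Monte-Carlo cluster simulation."""

    n_iterations: int
    max_sizes: np.ndarray
    max_peaks: np.ndarray
    smoothness_fwhm_mm: float
    z_threshold: float
    seed: int | None = None
    connectivity: int = 26

    def __post_init__(self):
        self.max_sizes = np.asarray(self.max_sizes)
        self.max_peaks = np.asarray(self.max_peaks)
        if self.n_iterations < 100:
            raise ValueError("need at least 100 Monte-Carlo iterations")
        if (len(self.max_sizes) != self.n_iterations
                or len(self.max_peaks) != self.n_iterations):
            raise ValueError("null lists must have n_iterations entries")


def gaussianize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform preserving mean and sd.

    Ties get average ranks; rank r maps through the standard normal
    quantile of (r - 0.5)/n; the result is rescaled to the input's mean
    and standard deviation.  Strictly monotone in the input ranks.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("need a 1D vector with at least 3 entries")
    if not np.isfinite(values).all():
        raise ValueError("input contains non-finite values")
    sd = values.std()
    if sd == 0:
        raise ValueError("all values equal; rank transform undefined")
    ranks = stats.rankdata(values, method="average")
    z = ndtri((ranks - 0.5) / values.size)
    z_sd = z.std()
    return (z - z.mean()) / z_sd * sd + values.mean()


def paired_t_map(maps_a, maps_b, geometry: MaskGeometry) -> ZMap:
    """Voxel-wise paired t statistic on per-subject differences (a - b).

    Voxels with zero difference variance get statistic 0 (count logged).
    df = n_subjects - 1.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(
            f"paired groups must have matching (subjects x voxels) shapes, "
            f"got {a.shape} and {b.shape}")
    n_sub = a.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if a.shape[1] != geometry.n_voxels:
        raise ValueError("maps do not match the geometry voxel count")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros(geometry.n_voxels)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n_sub))
    n_flagged = int((~ok).sum())
    if n_flagged:
        logger.warning("%d voxel(s) had zero difference variance; "
                       "statistic set to 0", n_flagged)
    return ZMap(values=t, geometry=geometry, df=n_sub - 1)


def two_sample_t_map(maps_a, maps_b, geometry: MaskGeometry) -> ZMap:
    """Unpaired two-sample t map (equal-variance); convenience only."""
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    t, _ = stats.ttest_ind(a, b, axis=0)
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    return ZMap(values=t, geometry=geometry, df=a.shape[0] + b.shape[0] - 2)


def t_to_z(zmap: ZMap) -> ZMap:
    """Convert t statistics to equivalent standard-normal deviates."""
    t = zmap.values
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], zmap.df))
    z[~pos] = stats.norm.ppf(stats.t.cdf(t[~pos], zmap.df))
    z = np.clip(z, -40.0, 40.0)  # guard inf at extreme tails
    return ZMap(values=z, geometry=zmap.geometry, df=zmap.df)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(
            f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}, "
            f"got {connectivity}") from None
    return ndimage.generate_binary_structure(3, rank)


def label_clusters(zmap: ZMap, z_threshold: float,
                   connectivity: int = 26) -> ClusterReport:
    """Connected components of suprathreshold in-mask voxels.

    Handles one tail: run again on ``zmap.negated()`` for the other tail.
    Clusters are ordered by size descending.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    g = zmap.geometry
    vol = g.embed(zmap.values, fill=-np.inf)
    supra = (vol > z_threshold) & g.inside
    structure = _connectivity_structure(connectivity)
    labels, n_lab = ndimage.label(supra, structure=structure)
    index_vol = g.embed(np.arange(g.n_voxels, dtype=float), fill=-1)
    clusters = []
    voxvol = g.voxel_volume_mm3
    for lab in range(1, n_lab + 1):
        coords = np.argwhere(labels == lab)
        vals = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
        peak_idx = int(np.argmax(vals))
        members = index_vol[coords[:, 0], coords[:, 1], coords[:, 2]]
        clusters.append(Cluster(
            label=lab,
            size_voxels=int(coords.shape[0]),
            size_mm3=float(coords.shape[0] * voxvol),
            peak_value=float(vals[peak_idx]),
            peak_coordinate=tuple(int(c) for c in coords[peak_idx]),
            members=tuple(int(m) for m in members),
        ))
    clusters.sort(key=lambda c: c.size_voxels, reverse=True)
    return ClusterReport(clusters=clusters, z_threshold=z_threshold)


def _fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size) -> np.ndarray:
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return sigma_mm / np.asarray(voxel_size, dtype=float)


def monte_carlo_null(geometry: MaskGeometry, smoothness_fwhm_mm: float,
                     z_threshold: float, n_iterations: int, seed: int,
                     connectivity: int = 26) -> NullDistribution:
    """Simulate the null distribution of maximum cluster size and peak.

    Each iteration: Gaussian white noise on the grid, optional Gaussian
    smoothing at the stated FWHM, re-standardization to zero mean / unit
    variance inside the mask, thresholding at ``z_threshold``; the maximum
    cluster size (0 if none) and the maximum in-mask value are recorded.
    Deterministic given ``seed``.
    """
    if n_iterations < 100:
        raise ValueError("need at least 100 Monte-Carlo iterations")
    if smoothness_fwhm_mm < 0:
        raise ValueError("smoothness_fwhm_mm must be >= 0")
    if geometry.n_voxels < 2:
        raise ValueError("degenerate mask: need at least 2 voxels")
    rng = np.random.default_rng(seed)
    structure = _connectivity_structure(connectivity)
    sigma = (_fwhm_to_sigma_voxels(smoothness_fwhm_mm, geometry.voxel_size)
             if smoothness_fwhm_mm > 0 else None)
    max_sizes = np.zeros(n_iterations, dtype=int)
    max_peaks = np.zeros(n_iterations)
    inside = geometry.inside
    for i in range(n_iterations):
        noise = rng.standard_normal(geometry.shape)
        if sigma is not None:
            noise = ndimage.gaussian_filter(noise, sigma=sigma)
        vals = noise[inside]
        vals = (vals - vals.mean()) / vals.std()
        max_peaks[i] = float(vals.max())
        vol = np.zeros(geometry.shape)
        vol[inside] = vals
        supra = (vol > z_threshold) & inside
        if supra.any():
            labels, n_lab = ndimage.label(supra, structure=structure)
            counts = np.bincount(labels.ravel())[1:]
            max_sizes[i] = int(counts.max())
    return NullDistribution(n_iterations=n_iterations, max_sizes=max_sizes,
                            max_peaks=max_peaks,
                            smoothness_fwhm_mm=smoothness_fwhm_mm,
                            z_threshold=z_threshold, seed=seed,
                            connectivity=connectivity)


def apply_cluster_correction(report: ClusterReport, null: NullDistribution,
                             alpha: float) -> ClusterReport:
    """Mark clusters significant against the Monte-Carlo null.

    A cluster is significant if its voxel count exceeds the
    (1 - alpha/2)-quantile of the null maximum sizes OR its peak exceeds
    the (1 - alpha/2)-quantile of the null maximum peaks.
    """
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 0.5]")
    required = int(np.ceil(2.0 / alpha))
    if null.n_iterations < required:
        raise ValueError(
            f"null distribution too small for alpha={alpha}: need at least "
            f"{required} iterations, have {null.n_iterations}")
    q = 1.0 - alpha / 2.0
    size_thr = float(np.quantile(null.max_sizes, q))
    peak_thr = float(np.quantile(null.max_peaks, q))
    clusters = [
        replace(c, significant=bool(c.size_voxels > size_thr
                                    or c.peak_value > peak_thr))
        for c in report.clusters
    ]
    summary = {
        "size_q95": float(np.quantile(null.max_sizes, 0.95)),
        "peak_q95": float(np.quantile(null.max_peaks, 0.95)),
        "size_threshold": size_thr,
        "peak_threshold": peak_thr,
        "n_iterations": null.n_iterations,
        "smoothness_fwhm_mm": null.smoothness_fwhm_mm,
    }
    return ClusterReport(clusters=clusters, z_threshold=report.z_threshold,
                         alpha=alpha, size_threshold=size_thr,
                         peak_threshold=peak_thr, null_summary=summary)


def filter_report(report: ClusterReport, min_size_mm3: float) -> ClusterReport:
    """Drop clusters smaller than the volume floor; order by size descending."""
    if min_size_mm3 < 0:
        raise ValueError("min_size_mm3 must be >= 0")
    kept = [c for c in report.clusters if c.size_mm3 > min_size_mm3]
    kept.sort(key=lambda c: c.size_mm3, reverse=True)
    return ClusterReport(clusters=kept, z_threshold=report.z_threshold,
                         alpha=report.alpha,
                         size_threshold=report.size_threshold,
                         peak_threshold=report.peak_threshold,
                         null_summary=report.null_summary)
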