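"""Image quality metrics for 4D EPI series.

The central statistic is the scaled squared difference (SSD): the squared
intensity change of each voxel between consecutive volumes, divided by the
scan-wide mean squared difference, so that the SSD averages to exactly 1
over the whole scan. Sudden global signal changes, slice-restricted
artefacts (spikes, eye movement) and ghosting all surface as localised SSD
excursions well above 1.

Temporal SNR follows the protocol's definition: the mean intensity of
in-mask voxels divided by the standard deviation of a noise sample taken
from out-of-mask voxels whose temporal mean lies at or below a centile
(default the 25th) of the out-of-mask temporal means — i.e. background air,
avoiding out-of-mask tissue such as eyes and scalp.

The carpet matrix bins in-mask voxels into 50 groups by mean intensity and
tracks each group's mean over time; vertical banding across all bins marks
global signal events.
"""
from __future__ import annotations

import warnings

import numpy as np
from skimage.filters import threshold_otsu

from .errors import EmptyMaskError, InsufficientDataError
from .types import BrainMask, CoverageSummary, FunctionalSeries, QCMetrics

__all__ = [
    "scaled_squared_difference",
    "snr_metrics",
    "carpet_bins",
    "variance_map",
    "variance_map_threshold",
    "ssd_sum_threshold",
    "normalised_global_timecourse",
    "mask_coverage_summary",
    "compute_all",
    "DegenerateNormaliserWarning",
]


class DegenerateNormaliserWarning(UserWarning):
    """Raised when a normalising quantity (SSD denominator, noise SD,
    temporal SD) is zero and a degenerate convention is applied."""


# ---------------------------------------------------------------------------
# Scaled squared difference

def scaled_squared_difference(
    series: FunctionalSeries,
    mask: BrainMask | None = None,
    metrics: QCMetrics | None = None,
) -> QCMetrics:
    """Compute the SSD family of metrics.

    By default the SSD is computed over *all* voxels of the volume, not just
    the brain mask, because ghosting and eye artefacts live outside brain
    tissue; pass ``mask`` to restrict the computation (both the normaliser
    and the derived summaries are then mask-restricted).

    Fills ``ssd_voxelwise`` (x, y, z, t-1), per-transition mean and
    variance, slice-wise mean/min/max (slice = fixed index along the third
    spatial axis) and the voxel-wise sum map.
    """
    if series.n_volumes < 2:
        raise InsufficientDataError("SSD needs at least 2 volumes")
    data = series.data.astype(np.float64, copy=False)
    diff_sq = np.square(np.diff(data, axis=3))
    if mask is not None:
        mask.check_matches(series)
        sel = mask.data[..., None]
        d_norm = float(diff_sq[mask.data, :].mean()) if mask.n_voxels else 0.0
        diff_sq = np.where(sel, diff_sq, 0.0)
    else:
        d_norm = float(diff_sq.mean())

    m = metrics if metrics is not None else QCMetrics()
    if d_norm == 0.0:
        warnings.warn(
            "all consecutive volumes identical: SSD normaliser is zero, SSD set to 0",
            DegenerateNormaliserWarning,
            stacklevel=2,
        )
        ssd = np.zeros_like(diff_sq)
    else:
        ssd = diff_sq / d_norm

    nx, ny, nz, nt1 = ssd.shape
    flat = ssd.reshape(-1, nt1)
    m.ssd_voxelwise = ssd
    m.ssd_mean_per_transition = flat.mean(axis=0)
    m.ssd_variance_per_transition = flat.var(axis=0)
    per_slice = ssd.reshape(nx * ny, nz, nt1)
    m.ssd_slicewise_mean = per_slice.mean(axis=0)
    m.ssd_slicewise_min = per_slice.min(axis=0)
    m.ssd_slicewise_max = per_slice.max(axis=0)
    m.ssd_sum_map = ssd.sum(axis=3)
    return m


# ---------------------------------------------------------------------------
# Temporal SNR

def snr_metrics(
    series: FunctionalSeries,
    mask: BrainMask,
    noise_centile: float = 25.0,
    noise_mode: str = "centile",
    metrics: QCMetrics | None = None,
) -> QCMetrics:
    """Global and slice-wise temporal SNR against an out-of-mask noise sample.

    ``noise_mode="centile"`` (default) selects out-of-mask voxels whose
    temporal-mean intensity is at or below the ``noise_centile``-th centile
    of out-of-mask temporal means. ``noise_mode="absolute"`` treats
    ``noise_centile`` as an absolute intensity cutoff instead.

    The noise standard deviation pools every (voxel, time) sample of the
    noise voxel set. Slices with no in-mask voxels get NaN slice-wise SNR.
    """
    mask.check_matches(series)
    if mask.n_voxels == 0:
        raise EmptyMaskError("cannot compute SNR with an empty mask")
    out = ~mask.data
    if not out.any():
        raise EmptyMaskError("mask covers the whole volume: no out-of-mask noise voxels")

    data = series.data.astype(np.float64, copy=False)
    tmean = data.mean(axis=3)
    out_means = tmean[out]
    if noise_mode == "centile":
        cutoff = np.percentile(out_means, noise_centile)
    elif noise_mode == "absolute":
        cutoff = float(noise_centile)
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    noise_vox = out & (tmean <= cutoff)
    if not noise_vox.any():
        raise EmptyMaskError("noise cutoff selected no out-of-mask voxels")
    sigma = float(data[noise_vox, :].std())
    m = metrics if metrics is not None else QCMetrics()
    if sigma == 0.0:
        warnings.warn(
            "noise standard deviation is zero; SNR reported as inf",
            DegenerateNormaliserWarning,
            stacklevel=2,
        )
        sigma = 0.0
        m.snr_global = float("inf")
    else:
        m.snr_global = float(tmean[mask.data].mean() / sigma)

    nz = mask.data.shape[2]
    slicewise = np.full(nz, np.nan)
    frac = np.zeros(nz)
    per_slice_n = mask.data.shape[0] * mask.data.shape[1]
    for z in range(nz):
        sl = mask.data[:, :, z]
        frac[z] = sl.sum() / per_slice_n
        if sl.any():
            num = tmean[:, :, z][sl].mean()
            slicewise[z] = np.inf if sigma == 0.0 else num / sigma
    m.snr_slicewise = slicewise
    m.slice_mask_fraction = frac
    return m


# ---------------------------------------------------------------------------
# Carpet matrix

def carpet_bins(
    series: FunctionalSeries,
    mask: BrainMask,
    n_bins: int = 50,
    metrics: QCMetrics | None = None,
) -> QCMetrics:
    """Bin in-mask voxels by temporal-mean intensity and average per volume.

    Voxels are sorted ascending by temporal mean (ties broken by linear
    voxel index, so the ordering is stable and reproducible) and split into
    ``n_bins`` contiguous groups whose sizes differ by at most one. Row 0
    of the carpet is the lowest-intensity bin.
    """
    mask.check_matches(series)
    n_vox = mask.n_voxels
    if n_vox < n_bins:
        raise InsufficientDataError(
            f"carpet needs at least {n_bins} in-mask voxels, got {n_vox}"
        )
    data = series.data.astype(np.float64, copy=False)
    vox_ts = data[mask.data, :]           # (n_vox, t) in C-order = linear-index order
    order = np.argsort(vox_ts.mean(axis=1), kind="stable")
    groups = np.array_split(order, n_bins)
    carpet = np.vstack([vox_ts[g, :].mean(axis=0) for g in groups])
    assignment = np.empty(n_vox, dtype=np.intp)
    for i, g in enumerate(groups):
        assignment[g] = i
    m = metrics if metrics is not None else QCMetrics()
    m.carpet = carpet
    m.carpet_bin_assignment = assignment
    return m


# ---------------------------------------------------------------------------
# Maps and display thresholds

def variance_map(series: FunctionalSeries) -> np.ndarray:
    """Temporal variance of each voxel (population variance, divide by n)."""
    return series.data.astype(np.float64, copy=False).var(axis=3)


def variance_map_threshold(var_map: np.ndarray, n_bins: int = 1000, min_voxels: int = 400) -> float:
    """Display cutoff for the variance map.

    The map's values are histogrammed into ``n_bins`` equal-width bins over
    [min, max] and the lower edge of the highest-index bin holding at least
    ``min_voxels`` voxels is returned. A constant map returns that constant;
    if no bin qualifies the map maximum is returned with a warning.
    """
    vals = np.asarray(var_map, dtype=float).ravel()
    if not np.all(np.isfinite(vals)):
        raise ValueError("variance map contains non-finite values")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    qualifying = np.nonzero(counts >= min_voxels)[0]
    if qualifying.size == 0:
        warnings.warn(
            f"no histogram bin holds >= {min_voxels} voxels; "
            "falling back to the map maximum",
            UserWarning,
            stacklevel=2,
        )
        return hi
    return float(edges[qualifying[-1]])


def ssd_sum_threshold(ssd_sum_map: np.ndarray, n_bins: int = 50, upper_bin: int = 5) -> float:
    """Display cutoff for the sum-SSD map: the upper edge of the fifth of 50
    equal-width bins over [min, max], i.e. ``min + 5 * (max - min) / 50``."""
    vals = np.asarray(ssd_sum_map, dtype=float).ravel()
    if not np.all(np.isfinite(vals)):
        raise ValueError("sum-SSD map contains non-finite values")
    lo, hi = float(vals.min()), float(vals.max())
    return lo + upper_bin * (hi - lo) / n_bins


# ---------------------------------------------------------------------------
# Global signal

def normalised_global_timecourse(
    series: FunctionalSeries,
    mask: BrainMask,
    metrics: QCMetrics | None = None,
) -> QCMetrics:
    """Per-volume mean of in-mask intensities, z-scored over volumes.

    z-scoring (rather than min-max scaling) is used so that signal drops
    read directly in standard deviations. A temporally constant series
    yields all zeros with a warning.
    """
    if series.n_volumes < 2:
        raise InsufficientDataError("global timecourse needs at least 2 volumes")
    mask.check_matches(series)
    if mask.n_voxels == 0:
        raise EmptyMaskError("cannot compute global timecourse with an empty mask")
    g = series.data[mask.data, :].mean(axis=0).astype(np.float64)
    sd = g.std()
    m = metrics if metrics is not None else QCMetrics()
    m.global_mean_timecourse = g
    if sd == 0.0:
        warnings.warn(
            "global timecourse is temporally constant; normalised series set to 0",
            DegenerateNormaliserWarning,
            stacklevel=2,
        )
        m.global_mean_timecourse_normalised = np.zeros_like(g)
    else:
        m.global_mean_timecourse_normalised = (g - g.mean()) / sd
    return m


# ---------------------------------------------------------------------------
# Mask coverage advisory

def mask_coverage_summary(
    series: FunctionalSeries,
    mask: BrainMask,
    cutoff: float | None = None,
    metrics: QCMetrics | None = None,
) -> QCMetrics:
    """Advisory check of mask coverage against the high-intensity support.

    Reports the fraction of high-intensity voxels (temporal mean above an
    Otsu cutoff, or an explicit ``cutoff``) lying outside the mask, and
    whether the mask touches the first or last slice (possible truncated
    coverage). Advisory only: this never excludes a scan by itself.
    """
    mask.check_matches(series)
    tmean = series.data.astype(np.float64, copy=False).mean(axis=3)
    if cutoff is None:
        if float(tmean.min()) == float(tmean.max()):
            cutoff = float(tmean.min())
        else:
            # Otsu separates background from tissue, but with a wide empty
            # intensity gap any split inside the gap is a maximiser and the
            # lowest is returned; re-centre on the midpoint of the two
            # classes so noise tails do not count as "bright" voxels.
            t0 = float(threshold_otsu(tmean))
            lo, hi = tmean[tmean <= t0], tmean[tmean > t0]
            cutoff = float((lo.mean() + hi.mean()) / 2) if hi.size else t0
    bright = tmean > cutoff
    n_bright = int(bright.sum())
    outside = float((bright & ~mask.data).sum() / n_bright) if n_bright else 0.0
    m = metrics if metrics is not None else QCMetrics()
    m.coverage = CoverageSummary(
        outside_fraction=outside,
        cutoff=float(cutoff),
        touches_first_slice=bool(mask.data[:, :, 0].any()),
        touches_last_slice=bool(mask.data[:, :, -1].any()),
    )
    return m


# ---------------------------------------------------------------------------
# Convenience driver

def compute_all(
    series: FunctionalSeries,
    mask: BrainMask,
    noise_centile: float = 25.0,
    noise_mode: str = "centile",
    n_carpet_bins: int = 50,
    ssd_mask_restricted: bool = False,
) -> QCMetrics:
    """Compute every metric for one scan into a single :class:`QCMetrics`."""
    m = QCMetrics()
    scaled_squared_difference(series, mask=mask if ssd_mask_restricted else None, metrics=m)
    snr_metrics(series, mask, noise_centile=noise_centile, noise_mode=noise_mode, metrics=m)
    carpet_bins(series, mask, n_bins=n_carpet_bins, metrics=m)
    m.variance_map = variance_map(series)
    m.png_threshold_variance = variance_map_threshold(m.variance_map)
    m.png_threshold_ssd = ssd_sum_threshold(m.ssd_sum_map)
    normalised_global_timecourse(series, mask, metrics=m)
    mask_coverage_summary(series, mask, metrics=m)
    return m
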