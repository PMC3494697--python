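"""Resting-state functional metrics: ALFF, ReHo and RFCS.

ALFF (amplitude of low-frequency fluctuations) is the mean of the amplitude
spectrum — the square root of the power spectrum — of a voxel's time series
over a low-frequency band (0.01–0.1 Hz by default). ReHo (regional
homogeneity) is Kendall's coefficient of concordance W between a voxel's
time series and those of its 26 nearest neighbours. RFCS (regional
functional connectivity strength) of an atlas region is the average Pearson
correlation of the region's mean time series with every other region:
RFCS_i = (1/(N-1)) * sum_{j != i} R_ij.

ALFF and ReHo maps are normalised by their mean over the brain mask so that
subjects are comparable; RFCS is computed after regressing head motion and
the global (whole-brain mean) signal out of the region time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sp_signal
from scipy.stats import rankdata

from .volumes_io import AtlasParcellation, BrainMask, Volume4D

__all__ = [
    "BandSpec",
    "MetricMap",
    "CorrelationMatrix",
    "RoiFeatureVector",
    "bandpass",
    "bandpass_volume",
    "alff_map",
    "kendall_w",
    "reho_map",
    "nuisance_regress",
    "roi_time_series",
    "connectivity_matrix",
    "rfcs",
    "metric_to_roi_features",
]

METRIC_TAGS = ("ReHo", "ALFF", "RFCS", "GM", "WM", "CSF")


@dataclass(frozen=True)
class BandSpec:
    """Pass band in Hz. Default matches the preprocessing band."""

    low: float = 0.01
    high: float = 0.1

    def validate(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if not (0 <= self.low < self.high):
            raise ValueError(f"need 0 <= low < high, got {self}")
        if self.high > nyquist + 1e-12:
            raise ValueError(
                f"band high {self.high} Hz exceeds Nyquist {nyquist} Hz for tr={tr}"
            )


@dataclass
class MetricMap:
    metric_tag: str
    values: np.ndarray
    normalized: bool


@dataclass
class CorrelationMatrix:
    r: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        n = self.r.shape[0]
        if self.r.shape != (n, n) or len(self.region_ids) != n:
            raise ValueError("correlation matrix / region_ids shape mismatch")


@dataclass
class RoiFeatureVector:
    metric_tag: str
    values: np.ndarray
    region_ids: np.ndarray
    flagged: np.ndarray | None = None  # regions with no usable voxels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        if len(self.values) != len(self.region_ids):
            raise ValueError("values / region_ids length mismatch")


# ---------------------------------------------------------------------------
# Band-pass filtering


def bandpass(series: np.ndarray, tr: float, band: BandSpec = BandSpec(),
             method: str = "fft") -> np.ndarray:
    """Band-pass filter time series along the last axis.

    ``method='fft'`` (default) zeroes spectral bins outside [low, high],
    the ideal-filter convention of the classic resting-state toolchains;
    ``method='butter'`` applies a zero-phase 4th-order Butterworth filter.
    The DC component is removed whenever ``band.low > 0``.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < 8:
        raise ValueError("series too short to filter (need >= 8 frames)")
    band.validate(tr)
    if method == "fft":
        freqs = np.fft.rfftfreq(n, d=tr)
        spec = np.fft.rfft(series, axis=-1)
        keep = (freqs >= band.low) & (freqs <= band.high)
        spec[..., ~keep] = 0.0
        return np.fft.irfft(spec, n=n, axis=-1)
    if method == "butter":
        nyq = 1.0 / (2.0 * tr)
        high = min(band.high / nyq, 0.999)
        low = max(band.low / nyq, 1e-6)
        sos = sp_signal.butter(4, [low, high], btype="bandpass", output="sos")
        return sp_signal.sosfiltfilt(sos, series, axis=-1)
    raise ValueError(f"unknown filter method {method!r}")


def bandpass_volume(vol: Volume4D, band: BandSpec = BandSpec(),
                    method: str = "fft") -> Volume4D:
    """Convenience wrapper: filter every voxel of a 4-D series."""
    filtered = bandpass(vol.data, vol.tr, band, method=method)
    return Volume4D(data=filtered, voxel_size=vol.voxel_size, tr=vol.tr)


# ---------------------------------------------------------------------------
# ALFF


def alff_map(vol: Volume4D, mask: BrainMask, band: BandSpec = BandSpec(),
             normalize: bool = True) -> MetricMap:
    """Amplitude of low-frequency fluctuations, voxelwise.

    The one-sided amplitude spectrum (square root of the power spectrum) is
    averaged over the frequency bins inside ``band``; a pure in-band
    sinusoid of amplitude A contributes amplitude ~A at its bin. If
    ``normalize``, the map is divided by its mean over the mask, making the
    mask-mean exactly 1.
    """
    _check_mask(vol.shape3d, mask)
    n = vol.n_timepoints
    freqs = np.fft.rfftfreq(n, d=vol.tr)
    in_band = (freqs >= band.low) & (freqs <= band.high)
    if not in_band.any():
        raise ValueError("no frequency bin falls inside the band")
    spec = np.fft.rfft(vol.data, axis=-1)
    # one-sided amplitude: |X_k| * 2/n recovers sinusoid amplitudes
    amp = np.abs(spec[..., in_band]) * (2.0 / n)
    values = amp.mean(axis=-1)
    values[~mask.mask] = 0.0
    if normalize:
        values = _normalize_by_mask_mean(values, mask)
    return MetricMap(metric_tag="ALFF", values=values, normalized=normalize)


# ---------------------------------------------------------------------------
# Kendall's W and ReHo


def kendall_w(series: np.ndarray, tie_correction: bool = False) -> float:
    """Kendall's coefficient of concordance over K series of n timepoints.

    Each of the K series ranks the n timepoints (average ranks on ties).
    With R_t the rank sum of timepoint t over the K series,

        W = (sum_t R_t^2 - n * Rbar^2) / (K^2 (n^3 - n) / 12)

    The classic ReHo convention applies no tie-correction term; pass
    ``tie_correction=True`` for the corrected denominator. The result is
    clipped to [0, 1] against floating-point overshoot.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("expected a (K, n) array")
    k, n = series.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 series and 2 timepoints")
    ranks = rankdata(series, axis=1, method="average")
    rank_sums = ranks.sum(axis=0)
    rbar = k * (n + 1) / 2.0
    numer = float(np.sum(rank_sums**2) - n * rbar**2)
    denom = k * k * (n**3 - n) / 12.0
    if tie_correction:
        # sum over series of sum(t_j^3 - t_j) for each group of t_j ties
        correction = 0.0
        for row in ranks:
            _, counts = np.unique(row, return_counts=True)
            correction += float(np.sum(counts**3 - counts))
        denom -= k * correction / 12.0
    if denom <= 0:
        # every series fully tied: concordance undefined, report 0
        return 0.0
    return float(np.clip(numer / denom, 0.0, 1.0))


_NEIGHBORHOOD_FOOTPRINTS = {}


def _footprint(neighborhood: int) -> np.ndarray:
    if neighborhood not in (6, 18, 26):
        raise ValueError("neighborhood must be 6, 18 or 26")
    if neighborhood not in _NEIGHBORHOOD_FOOTPRINTS:
        fp = np.zeros((3, 3, 3), dtype=bool)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    order = abs(dx) + abs(dy) + abs(dz)
                    if order == 0:
                        fp[1, 1, 1] = True  # centre voxel always included
                    elif neighborhood == 6 and order == 1:
                        fp[dx + 1, dy + 1, dz + 1] = True
                    elif neighborhood == 18 and order <= 2:
                        fp[dx + 1, dy + 1, dz + 1] = True
                    elif neighborhood == 26:
                        fp[dx + 1, dy + 1, dz + 1] = True
        _NEIGHBORHOOD_FOOTPRINTS[neighborhood] = fp
    return _NEIGHBORHOOD_FOOTPRINTS[neighborhood]


def reho_map(vol: Volume4D, mask: BrainMask, neighborhood: int = 26,
             normalize: bool = True, strict: bool = False) -> MetricMap:
    """Regional homogeneity: Kendall's W over each voxel's neighbourhood.

    Every in-mask voxel is scored with the W of its own series plus those of
    its in-mask neighbours (K <= neighborhood + 1). At grid edges and mask
    borders only available neighbours are used; with ``strict=True`` voxels
    whose neighbourhood is incomplete are zeroed instead.

    Vectorised computation: since rank sums per series total n(n+1)/2
    regardless of ties, Rbar = K(n+1)/2 exactly, and the per-voxel rank-sum
    squares are accumulated with a box convolution of the rank volumes.
    """
    _check_mask(vol.shape3d, mask)
    n = vol.n_timepoints
    fp = _footprint(neighborhood).astype(float)
    m = mask.mask

    ranks = rankdata(vol.data, axis=-1, method="average")
    ranks[~m] = 0.0

    kcount = ndimage.convolve(m.astype(float), fp, mode="constant", cval=0.0)
    kcount = np.rint(kcount)

    sum_sq = np.zeros(vol.shape3d)
    for t in range(n):
        rt = ndimage.convolve(ranks[..., t], fp, mode="constant", cval=0.0)
        sum_sq += rt * rt

    with np.errstate(divide="ignore", invalid="ignore"):
        rbar = kcount * (n + 1) / 2.0
        numer = sum_sq - n * rbar**2
        denom = kcount**2 * (n**3 - n) / 12.0
        values = np.where(denom > 0, numer / denom, 0.0)
    values = np.clip(values, 0.0, 1.0)
    values[~m] = 0.0
    values[kcount < 2] = 0.0  # isolated voxels have no concordance
    if strict:
        values[kcount < neighborhood + 1] = 0.0
    if normalize:
        values = _normalize_by_mask_mean(values, mask)
    return MetricMap(metric_tag="ReHo", values=values, normalized=normalize)


# ---------------------------------------------------------------------------
# Connectivity


def nuisance_regress(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each series against [intercept, confounds].

    ``series`` is (n_series, n_timepoints); ``confounds`` is
    (n_timepoints, n_confounds). Residuals are orthogonal to every confound
    column. A rank-deficient confound matrix triggers a warning and a
    pseudo-inverse solution.
    """
    series = np.asarray(series, dtype=float)
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != series.shape[-1]:
        raise ValueError("confound rows must match series length")
    design = np.column_stack([np.ones(confounds.shape[0]), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient confound matrix; using pseudo-inverse",
                      stacklevel=2)
    beta = np.linalg.pinv(design) @ series.T
    return series - (design @ beta).T


def roi_time_series(vol: Volume4D, atlas: AtlasParcellation,
                    mask: BrainMask | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean time series per atlas region.

    Returns (matrix of shape (n_regions, n_timepoints) in atlas-table order,
    boolean flags for regions with zero usable voxels — their rows are 0).
    """
    if atlas.labels.shape != vol.shape3d:
        raise ValueError("atlas grid does not match the volume")
    labels = atlas.labels
    if mask is not None:
        _check_mask(vol.shape3d, mask)
        labels = np.where(mask.mask, labels, 0)
    flat_labels = labels.reshape(-1)
    data2d = vol.data.reshape(-1, vol.n_timepoints)
    max_label = int(atlas.region_ids.max())
    counts = np.bincount(flat_labels, minlength=max_label + 1)
    sums = np.zeros((max_label + 1, vol.n_timepoints))
    np.add.at(sums, flat_labels, data2d)
    ids = atlas.region_ids
    if counts[ids].sum() == 0:
        raise ValueError("no atlas voxel overlaps the data support")
    empty = counts[ids] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        means = sums[ids] / counts[ids, None]
    means[empty] = 0.0
    return means, empty


def connectivity_matrix(roi_series: np.ndarray,
                        region_ids: np.ndarray | None = None) -> CorrelationMatrix:
    """Pearson correlations between all pairs of region time series.

    Zero-variance rows are flagged with a warning and their correlations set
    to 0 (diagonal stays 1), so one degenerate region cannot poison the
    matrix.
    """
    roi_series = np.asarray(roi_series, dtype=float)
    n_regions, n_t = roi_series.shape
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if n_t < 3:
        raise ValueError("need at least 3 timepoints")
    if region_ids is None:
        region_ids = np.arange(1, n_regions + 1)
    sd = roi_series.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance region series; "
                      "their correlations are set to 0", stacklevel=2)
    safe = roi_series.copy()
    # give degenerate rows unit noise-free variance placeholder to avoid NaN
    safe[degenerate] = 0.0
    safe[degenerate, 0] = 1.0
    r = np.corrcoef(safe)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r=r, region_ids=np.asarray(region_ids))


def rfcs(corr: CorrelationMatrix, variant: str = "signed") -> RoiFeatureVector:
    """Regional functional connectivity strength.

    RFCS_i = (1/(N-1)) * sum_{j != i} R_ij. ``variant`` selects how the
    off-diagonal correlations enter the average: 'signed' (default), 'abs',
    or 'positive' (negative correlations contribute 0).
    """
    r = corr.r
    n = r.shape[0]
    if n < 2:
        raise ValueError("need at least 2 regions")
    off = r - np.eye(n)  # zero the diagonal contribution
    if variant == "signed":
        values = off.sum(axis=1) / (n - 1)
    elif variant == "abs":
        values = np.abs(off).sum(axis=1) / (n - 1)
    elif variant == "positive":
        values = np.clip(off, 0.0, None).sum(axis=1) / (n - 1)
    else:
        raise ValueError(f"unknown RFCS variant {variant!r}")
    return RoiFeatureVector(metric_tag="RFCS", values=values,
                            region_ids=corr.region_ids)


# ---------------------------------------------------------------------------
# Map -> ROI features


def metric_to_roi_features(metric: MetricMap, atlas: AtlasParcellation,
                           mask: BrainMask | None = None) -> RoiFeatureVector:
    """Mean metric value per atlas region, in atlas-table order.

    A region with no usable voxels gets the map's mask-mean (so vector
    length stays fixed at the atlas size) and is flagged.
    """
    if atlas.labels.shape != metric.values.shape:
        raise ValueError("atlas grid does not match the map")
    labels = atlas.labels
    support = np.ones(labels.shape, dtype=bool) if mask is None else mask.mask
    labels = np.where(support, labels, 0)
    flat = labels.reshape(-1)
    vals = metric.values.reshape(-1)
    max_label = int(atlas.region_ids.max())
    counts = np.bincount(flat, minlength=max_label + 1)
    sums = np.bincount(flat, weights=vals, minlength=max_label + 1)
    ids = atlas.region_ids
    empty = counts[ids] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        means = sums[ids] / counts[ids]
    if empty.any():
        fallback = metric.values[support].mean() if support.any() else 0.0
        means[empty] = fallback
        warnings.warn(f"{int(empty.sum())} empty atlas regions filled with "
                      "the mask-mean", stacklevel=2)
    return RoiFeatureVector(metric_tag=metric.metric_tag, values=means,
                            region_ids=ids, flagged=empty)


# ---------------------------------------------------------------------------


def _check_mask(shape3d: tuple[int, int, int], mask: BrainMask) -> None:
    if mask.mask.shape != shape3d:
        raise ValueError("mask shape does not match the volume")


def _normalize_by_mask_mean(values: np.ndarray, mask: BrainMask) -> np.ndarray:
    mean = values[mask.mask].mean()
    if mean == 0:
        raise ValueError("cannot normalise: mask-mean is zero")
    return values / mean
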