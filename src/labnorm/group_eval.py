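"""Group-level evaluation: median volumes and ROI-masked colocalization.

After registering every subject to the atlas, a method's group result is
its voxelwise median volume.  Agreement between a registered (or median)
volume and the atlas is quantified inside a region-of-interest mask with
the colocalization battery standard in fluorescence microscopy:

* Costes auto-threshold — orthogonal (total-least-squares) regression of
  channel 2 on channel 1, then a sweep of the candidate threshold down
  from the channel-1 maximum until the Pearson correlation of the voxels
  *below* both thresholds is no longer positive;
* thresholded Manders split coefficients tM1/tM2 — the fraction of one
  channel's summed intensity lying where the other channel exceeds its
  threshold;
* voxelwise Pearson and Spearman correlation and an ordinary
  least-squares regression line.

The ROI mask is mandatory: without it, the abundant background voxels
dominate every statistic and manufacture false-positive colocalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import BinaryMask, Volume

__all__ = [
    "ColocResult",
    "CostesThresholds",
    "median_volume",
    "costes_threshold",
    "manders_split",
    "voxel_correlation",
    "coloc_regression",
    "colocalize",
]

log = logging.getLogger(__name__)


def median_volume(stack: Sequence[Volume]) -> Volume:
    """Voxelwise median across co-registered volumes.

    All volumes must share one grid.  For an even number of volumes the
    median is the mean of the two central order statistics.
    """
    if len(stack) == 0:
        raise ValueError("median of an empty stack")
    ref = stack[0]
    for v in stack[1:]:
        if not ref.same_grid(v):
            raise ValueError("all volumes in the stack must share one grid")
    data = np.stack([np.asarray(v.voxels, dtype=float) for v in stack])
    return ref.with_voxels(np.median(data, axis=0))


def _roi_values(ch1: Volume, ch2: Volume, roi: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    if not (ch1.same_grid(ch2) and ch1.same_grid(roi)):
        raise ValueError("channels and ROI must share one grid")
    roi.require_nonempty("colocalization ROI")
    sel = roi.voxels
    return np.asarray(ch1.voxels, float)[sel], np.asarray(ch2.voxels, float)[sel]


@dataclass(frozen=True)
class CostesThresholds:
    """Costes auto-threshold result (T2 lies on the orthogonal fit at T1)."""

    threshold_ch1: float
    threshold_ch2: float
    slope: float
    intercept: float
    no_positive_colocalization: bool = False


def _orthogonal_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line y = a x + b (first principal axis)."""
    xc = x - x.mean()
    yc = y - y.mean()
    cov = np.cov(np.stack([xc, yc]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if v[0] == 0:
        raise ValueError("orthogonal regression is vertical; channel 1 is (nearly) constant")
    a = v[1] / v[0]
    b = y.mean() - a * x.mean()
    return float(a), float(b)


def costes_threshold(ch1: Volume, ch2: Volume, roi: BinaryMask) -> CostesThresholds:
    """Costes auto-threshold inside the ROI.

    Candidate thresholds T are the distinct observed channel-1 intensities,
    swept downward from the maximum; at each T the Pearson correlation of
    the voxels with ``ch1 < T`` and ``ch2 < a*T + b`` is evaluated and the
    largest T at which that below-threshold correlation is <= 0 is
    returned (with T2 = a*T + b).  If the whole-ROI correlation is already
    <= 0 the thresholds stay at the channel maxima and the result is
    flagged; if the correlation never drops to 0 the sweep descends to the
    minimum observed intensity.

    Membership below threshold is evaluated as ``max(ch1, (ch2-b)/a) < T``
    so the sweep can run on prefix sums of the r-sorted voxels (the two
    formulations coincide except on exact floating-point boundary ties).
    """
    x, y = _roi_values(ch1, ch2, roi)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("a channel is constant within the ROI; Costes threshold undefined")
    a, b = _orthogonal_fit(x, y)
    r_all = float(np.corrcoef(x, y)[0, 1])
    if r_all <= 0 or a <= 0:
        log.info("no positive colocalization in ROI (r=%.3f, slope=%.3f)", r_all, a)
        return CostesThresholds(float(x.max()), float(y.max()), a, b, True)

    # voxel i is below threshold T iff T > max(ch1_i, (ch2_i - b)/a) =: r_i
    ri = np.maximum(x, (y - b) / a)
    order = np.argsort(ri, kind="stable")
    rs = ri[order]
    xs, ys = x[order], y[order]
    cx = np.concatenate([[0.0], np.cumsum(xs)])
    cy = np.concatenate([[0.0], np.cumsum(ys)])
    cxx = np.concatenate([[0.0], np.cumsum(xs * xs)])
    cyy = np.concatenate([[0.0], np.cumsum(ys * ys)])
    cxy = np.concatenate([[0.0], np.cumsum(xs * ys)])

    candidates = np.unique(x)[::-1]  # descending distinct ch1 intensities
    chosen = float(np.min(x))
    found = False
    for T in candidates:
        m = int(np.searchsorted(rs, T, side="left"))  # voxels with r_i < T
        if m < 2:
            continue
        sxx = cxx[m] - cx[m] ** 2 / m
        syy = cyy[m] - cy[m] ** 2 / m
        if sxx <= 0 or syy <= 0:
            continue  # degenerate below-threshold subset
        sxy = cxy[m] - cx[m] * cy[m] / m
        r_below = sxy / np.sqrt(sxx * syy)
        if r_below <= 0:
            chosen = float(T)
            found = True
            break
    if not found:
        chosen = float(np.min(x))
    return CostesThresholds(chosen, float(a * chosen + b), a, b, False)


def manders_split(
    ch1: Volume,
    ch2: Volume,
    threshold_ch1: float,
    threshold_ch2: float,
    roi: BinaryMask,
) -> tuple[float, float]:
    """Thresholded Manders split coefficients (tM1, tM2) inside the ROI.

    tM1 is the fraction of channel-1 intensity located where channel 2
    exceeds its threshold, and symmetrically for tM2.  Negative
    intensities are clipped to zero (with a logged count) so both
    coefficients stay in [0, 1].
    """
    x, y = _roi_values(ch1, ch2, roi)
    n_neg = int(np.sum(x < 0) + np.sum(y < 0))
    if n_neg:
        log.info("clipping %d negative intensities to 0 for Manders sums", n_neg)
    x = np.clip(x, 0, None)
    y = np.clip(y, 0, None)
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        raise ValueError("a channel is all-zero within the ROI; Manders coefficients undefined")
    tm1 = float(x[y > threshold_ch2].sum() / sx)
    tm2 = float(y[x > threshold_ch1].sum() / sy)
    return tm1, tm2


def voxel_correlation(ch1: Volume, ch2: Volume, roi: BinaryMask) -> tuple[float, float]:
    """(Pearson r, Spearman rho) of the two channels over the ROI voxels.

    Spearman is Pearson on average-ranked intensities (ties get the mean
    of the ranks they span).
    """
    x, y = _roi_values(ch1, ch2, roi)
    if x.size < 3:
        raise ValueError("need at least 3 ROI voxels for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant channel")
    pearson = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return pearson, rho


def coloc_regression(ch1: Volume, ch2: Volume, roi: BinaryMask) -> tuple[float, float]:
    """Ordinary least-squares fit ch2 = slope * ch1 + intercept over the ROI."""
    x, y = _roi_values(ch1, ch2, roi)
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for a constant predictor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


@dataclass(frozen=True)
class ColocResult:
    """Full colocalization summary of one volume against the atlas."""

    costes_threshold_ch1: float
    costes_threshold_ch2: float
    manders_tm1: float
    manders_tm2: float
    pearson_r: float
    spearman_rho: float
    regression_slope: float
    regression_intercept: float
    n_voxels: int
    no_positive_colocalization: bool = False

    def to_dict(self) -> dict:
        return {
            "costes_threshold_ch1": self.costes_threshold_ch1,
            "costes_threshold_ch2": self.costes_threshold_ch2,
            "manders_tm1": self.manders_tm1,
            "manders_tm2": self.manders_tm2,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "regression_slope": self.regression_slope,
            "regression_intercept": self.regression_intercept,
            "n_voxels": self.n_voxels,
            "no_positive_colocalization": self.no_positive_colocalization,
        }


def colocalize(image: Volume, atlas: Volume, roi: BinaryMask) -> ColocResult:
    """Run the whole battery: Costes thresholds, Manders split, correlations, OLS.

    Channel 1 is the atlas, channel 2 the registered image, matching the
    scatter-plot convention of plotting the atlas on the abscissa.
    """
    ct = costes_threshold(atlas, image, roi)
    tm1, tm2 = manders_split(atlas, image, ct.threshold_ch1, ct.threshold_ch2, roi)
    pearson, rho = voxel_correlation(atlas, image, roi)
    slope, intercept = coloc_regression(atlas, image, roi)
    return ColocResult(
        costes_threshold_ch1=ct.threshold_ch1,
        costes_threshold_ch2=ct.threshold_ch2,
        manders_tm1=tm1,
        manders_tm2=tm2,
        pearson_r=pearson,
        spearman_rho=rho,
        regression_slope=slope,
        regression_intercept=intercept,
        n_voxels=roi.n_true,
        no_positive_colocalization=ct.no_positive_colocalization,
    )
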