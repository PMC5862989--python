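"""GC-bias quantification (loess-based ΔR_GC) and binned weighted correction.

Let R_1 ... R_W be the unique deduplicated read counts of the W autosomal
windows, M their mean, and L_w the value at window w of a loess (degree-1
tricube local regression) fit of counts against window GC fraction.  Then

    TV      = (1/W) Σ_w (R_w − M)²        total variance
    LV      = (1/W) Σ_w (R_w − L_w)²      variance left after the GC fit
    ΔR_GC   = 1 − LV / TV                 fraction of variance explained by GC

ΔR_GC is 0 when counts are independent of GC and approaches 1 when counts
are a deterministic smooth function of GC.  It is scale-invariant, so it is
identical whether computed on raw counts or on NDR.  Note it is a relative
measure: at fixed GC bias, noisier (less uniform) amplification lowers it.

The correction is the minimal faithful "weighted" strategy: partition
[0,1] into equal-width GC bins, weight each window's count by
(global autosomal mean) / (its bin's mean count), then rescale so the
autosomal mean is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .count_profile import WindowCounts

__all__ = [
    "GCBiasResult", "CorrectionModel", "loess", "loess_fit", "delta_r_gc",
    "fit_gc_correction", "apply_gc_correction",
]


@dataclass
class GCBiasResult:
    """ΔR_GC and its ingredients for one sample."""

    tv: float
    lv: float
    delta_r_gc: Optional[float]
    loess_gc: np.ndarray      # window GC values (autosomal, usable)
    loess_curve: np.ndarray   # fitted L_w at those GC values
    span: float
    n_windows: int
    flagged: bool = False
    note: str = ""


@dataclass
class CorrectionModel:
    """Per-GC-bin multiplicative weights (global mean / bin mean)."""

    bin_edges: np.ndarray
    weights: np.ndarray
    reference_mean: float

    def weight_at(self, gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        idx = np.clip(np.digitize(gc, self.bin_edges) - 1, 0, len(self.weights) - 1)
        return self.weights[idx]


def loess(x: np.ndarray, y: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Degree-1 loess: tricube-weighted local linear fit at every x.

    The neighbourhood of each point is its ``k = max(2, int(span * n))``
    nearest x-values (a contiguous run once x is sorted); weights are
    tricube in |x_j − x_i| scaled by the neighbourhood's maximum distance.
    No robustness iterations.  Deterministic; O(n·k).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("degenerate GC support: all x identical")
    k = max(2, int(span * n))
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    fitted_s = np.empty(n)
    lo = 0
    for i in range(n):
        xi = xs[i]
        # slide the k-window to the nearest-neighbour position for xi
        while lo + k < n and xs[lo + k] - xi < xi - xs[lo]:
            lo += 1
        xw = xs[lo:lo + k]
        yw = ys[lo:lo + k]
        dmax = max(xi - xw[0], xw[-1] - xi)
        if dmax <= 0:
            fitted_s[i] = yw.mean()
            continue
        u = np.abs(xw - xi) / dmax
        w = np.clip(1.0 - u ** 3, 0.0, None) ** 3
        sw = w.sum()
        xm = (w @ xw) / sw
        ym = (w @ yw) / sw
        dxw = xw - xm
        sxx = w @ (dxw * dxw)
        if sxx <= 0:
            fitted_s[i] = ym
        else:
            beta = (w @ (dxw * yw)) / sxx
            fitted_s[i] = ym + beta * (xi - xm)
    fitted = np.empty(n)
    fitted[order] = fitted_s
    return fitted


def _autosomal_arrays(counts: WindowCounts) -> tuple[np.ndarray, np.ndarray]:
    mask = counts.autosomal_usable
    gc = counts.windows.gc[mask]
    y = np.asarray(counts.counts, dtype=float)[mask]
    return gc, y


def loess_fit(counts: WindowCounts, span: float = 0.3) -> np.ndarray:
    """Fitted loess values L_w at every usable autosomal window's GC."""
    gc, y = _autosomal_arrays(counts)
    if len(gc) < 10:
        raise ValueError("need at least 10 usable autosomal windows")
    return loess(gc, y, span=span)


def delta_r_gc(counts: WindowCounts, span: float = 0.3) -> GCBiasResult:
    """Compute TV, LV and ΔR_GC = 1 − LV/TV over usable autosomal windows.

    All-equal counts (TV = 0) make the statistic undefined: the result is
    flagged with ``delta_r_gc=None``.  A fit with LV > TV (possible only
    through numerical pathology) is clamped to 0 and flagged.
    """
    gc, y = _autosomal_arrays(counts)
    if len(gc) < 10:
        raise ValueError("need at least 10 usable autosomal windows")
    W = len(y)
    M = y.mean()
    tv = float(np.sum((y - M) ** 2) / W)
    if tv == 0.0:
        return GCBiasResult(tv=0.0, lv=0.0, delta_r_gc=None, loess_gc=gc,
                            loess_curve=np.full(W, M), span=span, n_windows=W,
                            flagged=True, note="TV=0: all counts equal")
    L = loess(gc, y, span=span)
    lv = float(np.sum((y - L) ** 2) / W)
    delta = 1.0 - lv / tv
    flagged = False
    note = ""
    if delta < 0:
        delta, flagged, note = 0.0, True, "LV>TV: clamped to 0"
    return GCBiasResult(tv=tv, lv=lv, delta_r_gc=delta, loess_gc=gc,
                        loess_curve=L, span=span, n_windows=W,
                        flagged=flagged, note=note)


def fit_gc_correction(counts: WindowCounts, n_bins: int = 100,
                      copy_ratio: Optional[np.ndarray] = None,
                      smooth_weights: int = 0) -> CorrectionModel:
    """Per-GC-bin weights: global autosomal mean / bin mean count.

    Bins partition [0,1] with equal width; empty bins (and bins whose mean
    is zero) inherit the nearest non-empty bin's weight.

    ``copy_ratio`` (full-length per-window array, diploid = 1) makes the
    fit copy-number-aware: counts are divided by it before the bin means,
    so windows inside known or provisionally-called CNVs do not drag their
    GC bin's weight and the correction does not flatten real copy-number
    signal.  Windows with ratio <= 0 are excluded from the fit.

    ``smooth_weights`` (odd window length, 0 = off) applies a running
    median across the bin weights.  Amplification GC bias is smooth in
    GC, so a single outlier bin — typically one populated only by windows
    of an uncalled CNV — is pulled back to the level of its neighbours.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    gc, y = _autosomal_arrays(counts)
    if copy_ratio is not None:
        ratio = np.asarray(copy_ratio, dtype=float)[counts.autosomal_usable]
        keep = ratio > 0
        gc, y = gc[keep], y[keep] / ratio[keep]
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(gc, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    ns = np.bincount(idx, minlength=n_bins)
    M = y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        bin_mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    ok = (ns > 0) & (bin_mean > 0)
    if not ok.any():
        raise ValueError("no populated GC bins")
    if ok.sum() == 1:
        warnings.warn("all windows fall in one GC bin; correction is identity-like")
    weights = np.empty(n_bins)
    ok_idx = np.nonzero(ok)[0]
    for b in range(n_bins):
        src = b if ok[b] else ok_idx[np.argmin(np.abs(ok_idx - b))]
        weights[b] = M / bin_mean[src]
    if smooth_weights:
        if smooth_weights % 2 == 0 or smooth_weights < 3:
            raise ValueError("smooth_weights must be an odd integer >= 3")
        from scipy.ndimage import median_filter

        weights = median_filter(weights, size=smooth_weights, mode="nearest")
    return CorrectionModel(bin_edges=edges, weights=weights, reference_mean=M)


def apply_gc_correction(counts: WindowCounts, model: CorrectionModel) -> WindowCounts:
    """Multiply each window count by its GC-bin weight.

    The corrected autosomal mean is re-normalised to the pre-correction
    mean, so downstream NDR and copy-number scales are unchanged.
    Corrected counts are floats.
    """
    gc = counts.windows.gc
    w = model.weight_at(np.nan_to_num(gc, nan=0.5))
    corrected = np.asarray(counts.counts, dtype=float) * w
    mask = counts.autosomal_usable
    mean_now = corrected[mask].mean()
    if mean_now > 0:
        corrected *= counts.M / mean_now
    return WindowCounts(windows=counts.windows, counts=corrected,
                        sample_id=counts.sample_id,
                        n_total_reads=counts.n_total_reads,
                        n_unassigned=counts.n_unassigned)
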