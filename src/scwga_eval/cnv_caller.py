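"""CNV calling: dynamic window merging, binary segmentation, segment calls.

Fixed mappability windows are first merged into "dynamic" windows large
enough that each carries a guaranteed expected read count (so the merged
NDR noise scale is depth-controlled), then each chromosome's merged NDR
signal is recursively split by binary segmentation: at every step the
candidate breakpoint maximises a two-sample t-like statistic

    |mean_L − mean_R| / (s · sqrt(1/n_L + 1/n_R))

with s the pooled within-half standard deviation; the split is accepted
when its normal-approximation p-value is below ``alpha`` and both halves
keep at least ``min_seg`` merged windows.  Segments are then classified by
mean NDR: gain at >= 1.25, loss at <= 0.75 (midpoints between integer
copy states over 2), with copy number round(2 x mean NDR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .count_profile import WindowCounts
from .window_builder import WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicWindowPlan", "Segment", "ExclusionPolicy", "merge_dynamic_windows",
    "binary_segment", "call_segments", "exclude_regions", "call_cnvs",
    "call_cnvs_corrected", "merge_same_call", "bridge_short_gaps",
    "copy_ratio_from_segments",
]


@dataclass
class DynamicWindowPlan:
    """Contiguous runs of fixed windows forming merged windows.

    ``runs`` are (chrom, first_fixed_index, last_fixed_index_exclusive);
    runs partition each chromosome's fixed windows.  ``ndr`` is the merged
    signal: sum of counts in the run / (M x run length).
    """

    runs: list[tuple[str, int, int]]
    ndr: np.ndarray
    flagged: np.ndarray   # short chromosome tails below the read floor
    M: float
    min_expected_reads: float

    def chrom_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        start = 0
        cur = None
        for i, (chrom, _, _) in enumerate(self.runs):
            if chrom != cur:
                if cur is not None:
                    out[cur] = slice(start, i)
                cur, start = chrom, i
        if cur is not None:
            out[cur] = slice(start, len(self.runs))
        return out


@dataclass
class Segment:
    """A called copy-number segment (0-based half-open genomic coordinates)."""

    chrom: str
    start: int
    end: int
    mean_ndr: float
    n_windows: int
    copy_number: int
    call: str               # gain | loss | neutral
    flag: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_dynamic_windows(counts: WindowCounts,
                          min_expected_reads: float = 30.0
                          ) -> DynamicWindowPlan:
    """Greedily merge consecutive fixed windows until the diploid-expected
    count (M per fixed window) reaches ``min_expected_reads``.

    A chromosome tail (or a whole short chromosome) that cannot reach the
    floor becomes one flagged merged window.
    """
    if min_expected_reads <= 0:
        raise ValueError("min_expected_reads must be positive")
    ws = counts.windows
    M = counts.M
    vals = np.asarray(counts.counts, dtype=float)
    runs: list[tuple[str, int, int]] = []
    ndr: list[float] = []
    flagged: list[bool] = []
    for chrom in ws.chrom_names():
        # flagged fixed windows (short tails, undefined GC) are excluded
        idx = np.nonzero((ws.chrom == chrom) & ws.usable)[0]
        if len(idx) == 0:
            continue
        i = 0
        while i < len(idx):
            j = i
            acc = 0.0
            while j < len(idx) and acc < min_expected_reads:
                acc += M
                j += 1
            short = acc < min_expected_reads
            members = idx[i:j]
            runs.append((chrom, int(members[0]), int(members[-1]) + 1))
            ndr.append(vals[members].sum() / (M * len(members)))
            flagged.append(short)
            if short:
                logger.warning("chromosome %s tail of %d window(s) below the "
                               "%.0f-read floor; flagged", chrom, len(members),
                               min_expected_reads)
            i = j
    return DynamicWindowPlan(runs=runs, ndr=np.asarray(ndr),
                             flagged=np.asarray(flagged, dtype=bool), M=M,
                             min_expected_reads=min_expected_reads)


def _split_statistics(x: np.ndarray, min_seg: int) -> tuple[np.ndarray, np.ndarray]:
    """t-like statistic for every admissible split of ``x``.

    Returns (split positions k, statistic), where k splits x into x[:k]
    and x[k:].  Vectorised via cumulative sums.
    """
    n = len(x)
    ks = np.arange(min_seg, n - min_seg + 1)
    if len(ks) == 0:
        return ks, np.empty(0)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    nl = ks.astype(float)
    nr = n - nl
    sl = c1[ks - 1]
    sr = c1[-1] - sl
    ql = c2[ks - 1]
    qr = c2[-1] - ql
    ml = sl / nl
    mr = sr / nr
    ssl = np.maximum(ql - nl * ml * ml, 0.0)
    ssr = np.maximum(qr - nr * mr * mr, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.sqrt((ssl + ssr) / (n - 2)) if n > 2 else np.zeros_like(nl)
        t = np.abs(ml - mr) / (s * np.sqrt(1.0 / nl + 1.0 / nr))
    t = np.where((s == 0) & (ml != mr), np.inf, t)
    t = np.where((s == 0) & (ml == mr), 0.0, t)
    return ks, t


def binary_segment(signal: np.ndarray, alpha: float = 0.01,
                   min_seg: int = 3) -> list[int]:
    """Recursive binary segmentation of one chromosome's merged NDR signal.

    Returns sorted internal breakpoints (indices k meaning a boundary
    between signal[k-1] and signal[k]).  The best split's two-sided
    normal p-value is Bonferroni-adjusted for the number of candidate
    split positions scanned, so ``alpha`` bounds the per-segment false
    split rate.  Deterministic: ties in the split statistic are broken
    leftmost.  A constant signal yields none.
    """
    signal = np.asarray(signal, dtype=float)
    if min_seg < 1:
        raise ValueError("min_seg must be >= 1")
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        x = signal[lo:hi]
        n = len(x)
        if n < 2 * min_seg:
            return
        ks, t = _split_statistics(x, min_seg)
        if len(ks) == 0:
            return
        best = int(np.argmax(t))  # argmax takes the first (leftmost) maximum
        tbest = t[best]
        if tbest == 0 or not (tbest > 0):
            return
        p = 0.0 if math.isinf(tbest) else min(1.0, len(ks) * 2.0 * norm.sf(tbest))
        if p >= alpha:
            return
        k = int(ks[best])
        breaks.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, len(signal))
    return sorted(breaks)


def call_segments(plan: DynamicWindowPlan, breakpoints: dict[str, list[int]],
                  windows: WindowSet, gain_threshold: float = 1.25,
                  loss_threshold: float = 0.75) -> list[Segment]:
    """Turn per-chromosome breakpoints into classified genomic segments.

    ``breakpoints`` maps chromosome name to indices local to that
    chromosome's merged signal.  Segment coordinates are mapped back
    through the plan to the fixed windows' genomic span.
    """
    segments: list[Segment] = []
    slices = plan.chrom_slices()
    for chrom, sl in slices.items():
        n = sl.stop - sl.start
        bks = sorted(breakpoints.get(chrom, []))
        bounds = [0] + [b for b in bks if 0 < b < n] + [n]
        for a, b in zip(bounds, bounds[1:]):
            runs = plan.runs[sl.start + a: sl.start + b]
            vals = plan.ndr[sl.start + a: sl.start + b]
            first_fixed = runs[0][1]
            last_fixed = runs[-1][2] - 1
            mean = float(np.mean(vals))
            cn = int(round(2.0 * mean))
            if mean >= gain_threshold:
                call = "gain"
            elif mean <= loss_threshold:
                call = "loss"
            else:
                call = "neutral"
            flag = "short" if plan.flagged[sl.start + a: sl.start + b].any() else ""
            segments.append(Segment(
                chrom=chrom, start=int(windows.start[first_fixed]),
                end=int(windows.end[last_fixed]), mean_ndr=mean,
                n_windows=b - a, copy_number=cn, call=call, flag=flag,
            ))
    return segments


def merge_same_call(segments: Sequence[Segment]) -> list[Segment]:
    """Merge consecutive same-chromosome segments with the same call.

    Binary segmentation at high depth can split one copy-number event into
    several adjacent segments over statistically-significant but tiny mean
    differences; merging identical calls restores one segment per event.
    Means are window-weighted; copy number is re-derived from the merged
    mean.
    """
    out: list[Segment] = []
    for seg in segments:
        prev = out[-1] if out else None
        if (prev is not None and prev.chrom == seg.chrom
                and prev.call == seg.call):
            n = prev.n_windows + seg.n_windows
            mean = (prev.mean_ndr * prev.n_windows
                    + seg.mean_ndr * seg.n_windows) / n
            out[-1] = replace(prev, end=seg.end, mean_ndr=mean, n_windows=n,
                              copy_number=int(round(2.0 * mean)),
                              flag=prev.flag or seg.flag)
        else:
            out.append(seg)
    return out


def bridge_short_gaps(segments: Sequence[Segment],
                      max_gap_windows: int = 8) -> list[Segment]:
    """Absorb short neutral interruptions between two identical calls.

    A neutral segment of at most ``max_gap_windows`` merged windows whose
    two neighbours carry the same non-neutral call is an artifact of the
    window-level correction, not an independent event: the three segments
    are merged (window-weighted mean, copy number re-derived).  The
    segmentation-level analogue of undo-splits pruning.
    """
    segs = list(segments)
    merged = True
    while merged:
        merged = False
        for i in range(1, len(segs) - 1):
            a, gap, b = segs[i - 1], segs[i], segs[i + 1]
            if (gap.call == "neutral" and gap.n_windows <= max_gap_windows
                    and a.chrom == gap.chrom == b.chrom
                    and a.call == b.call != "neutral"):
                n = a.n_windows + gap.n_windows + b.n_windows
                mean = (a.mean_ndr * a.n_windows + gap.mean_ndr * gap.n_windows
                        + b.mean_ndr * b.n_windows) / n
                segs[i - 1:i + 2] = [replace(
                    a, end=b.end, mean_ndr=mean, n_windows=n,
                    copy_number=int(round(2.0 * mean)),
                    flag=a.flag or gap.flag or b.flag)]
                merged = True
                break
    return segs


def copy_ratio_from_segments(windows: WindowSet,
                             segments: Sequence[Segment]) -> np.ndarray:
    """Per-window expected copy ratio (copy_number / 2) implied by calls.

    Windows outside any non-neutral segment get ratio 1.  Used to make a
    GC-correction fit copy-number-aware on a second pass.
    """
    ratio = np.ones(windows.n_windows)
    mid = (windows.start + windows.end) // 2
    for seg in segments:
        if seg.call == "neutral":
            continue
        m = (windows.chrom == seg.chrom) & (mid >= seg.start) & (mid < seg.end)
        ratio[m] = max(seg.copy_number, 0) / 2.0
    return ratio


@dataclass
class ExclusionPolicy:
    """Regions whose calls are unreliable (e.g. sex chromosomes).

    ``mode='flag'`` marks partially-overlapping calls; calls fully inside
    an excluded region are always dropped.  ``mode='drop'`` drops any
    overlap.
    """

    chroms: frozenset[str] = frozenset()
    intervals: tuple[tuple[str, int, int], ...] = ()
    mode: str = "flag"

    def __post_init__(self) -> None:
        if self.mode not in ("flag", "drop"):
            raise ValueError("mode must be 'flag' or 'drop'")

    @classmethod
    def sex_chromosomes(cls, mode: str = "flag") -> "ExclusionPolicy":
        return cls(chroms=frozenset({"chrX", "chrY", "X", "Y"}), mode=mode)

    def overlap(self, seg: Segment) -> str:
        """'full', 'partial' or 'none'."""
        if seg.chrom in self.chroms:
            return "full"
        best = "none"
        for chrom, s, e in self.intervals:
            if chrom != seg.chrom:
                continue
            ov = min(seg.end, e) - max(seg.start, s)
            if ov <= 0:
                continue
            if seg.start >= s and seg.end <= e:
                return "full"
            best = "partial"
        return best


def exclude_regions(segments: Sequence[Segment],
                    policy: Optional[ExclusionPolicy]) -> list[Segment]:
    """Apply an exclusion policy: full overlaps dropped, partial overlaps
    flagged (default) or dropped."""
    if policy is None:
        return list(segments)
    out: list[Segment] = []
    for seg in segments:
        ov = policy.overlap(seg)
        if ov == "full":
            continue
        if ov == "partial":
            if policy.mode == "drop":
                continue
            seg = replace(seg, flag=(seg.flag + ";excluded-region").lstrip(";"))
        out.append(seg)
    return out


def call_cnvs(counts: WindowCounts, alpha: float = 0.01, min_seg: int = 3,
              min_expected_reads: float = 30.0, gain_threshold: float = 1.25,
              loss_threshold: float = 0.75,
              policy: Optional[ExclusionPolicy] = None,
              merge_calls: bool = True, bridge_windows: int = 8) -> list[Segment]:
    """End-to-end caller: merge, segment per chromosome, classify, exclude.

    ``counts`` should already be GC-corrected.  Returns all segments
    (neutral included); filter on ``call != 'neutral'`` for CNV calls.
    """
    plan = merge_dynamic_windows(counts, min_expected_reads=min_expected_reads)
    breaks: dict[str, list[int]] = {}
    for chrom, sl in plan.chrom_slices().items():
        breaks[chrom] = binary_segment(plan.ndr[sl], alpha=alpha, min_seg=min_seg)
    segments = call_segments(plan, breaks, counts.windows,
                             gain_threshold=gain_threshold,
                             loss_threshold=loss_threshold)
    if merge_calls:
        segments = merge_same_call(segments)
        if bridge_windows:
            segments = merge_same_call(bridge_short_gaps(segments, bridge_windows))
    return exclude_regions(segments, policy)


def call_cnvs_corrected(raw_counts: WindowCounts, n_bins: int = 100,
                        max_passes: int = 4, smooth_weights: int = 5,
                        **kwargs) -> list[Segment]:
    """Iterative GC-corrected calling from raw counts.

    Pass 1: plain binned correction, provisional calls.  Subsequent
    passes re-fit the correction with counts neutralised by the
    provisional copy ratio (so CNVs that dominate a GC bin are not
    flattened into it), re-apply and call again, until the call set is
    stable or ``max_passes`` is reached.  Iterating correction and
    segmentation is the standard remedy for single-sample GC correction
    absorbing genuine copy-number signal.
    """
    from . import gc_bias

    ratio = None
    prev_key = None
    segments: list[Segment] = []
    for _ in range(max_passes):
        model = gc_bias.fit_gc_correction(raw_counts, n_bins=n_bins,
                                          copy_ratio=ratio,
                                          smooth_weights=smooth_weights)
        corrected = gc_bias.apply_gc_correction(raw_counts, model)
        segments = call_cnvs(corrected, **kwargs)
        key = tuple((s.chrom, s.start, s.end, s.call) for s in segments
                    if s.call != "neutral")
        if key == prev_key:
            break
        prev_key = key
        ratio = copy_ratio_from_segments(raw_counts.windows, segments)
    return segments
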