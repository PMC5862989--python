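"""Benchmark scoring: confusion rates and sensitivity/specificity.

Truth "signals" are the units of the confusion table: every true
non-neutral segment (a focal CNV, or a whole-chromosome aneuploidy) is one
positive signal; every chromosome that is copy-neutral in the truth is one
negative signal.  A positive signal is detected (TP) when some call of the
same direction (gain vs loss) reciprocally overlaps it by at least the
matching threshold; undetected positives are FN; calls matching no truth
are FP; neutral chromosomes untouched by any call are TN.  Rates:

    TPR = tp/(tp+fn)    FNR = fn/(tp+fn)
    TNR = tn/(tn+fp)    FPR = fp/(tn+fp)

and the headline scores are

    Sensitivity = TPR / (TPR + FNR)        Specificity = TNR / (TNR + FPR)

which, given the rate identities, equal TPR and TNR respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnv_caller import Segment
from .synthetic_data import TruthProfile
from .window_builder import is_autosome

__all__ = [
    "TruthSet", "MatchLabels", "EvalResult", "match_calls", "confusion_rates",
    "sensitivity_specificity", "evaluate_sample", "aggregate_by_combination",
]


@dataclass
class TruthSet:
    """Per-sample positive truth segments plus the implied neutral complement.

    ``positives`` maps sample id -> list of (chrom, start, end, copy_number)
    with copy_number != 2.  ``chromosomes`` lists every chromosome under
    evaluation; chromosomes without a positive segment for a sample are
    that sample's neutral (negative) units.
    """

    positives: dict[str, list[tuple[str, int, int, int]]]
    chromosomes: list[str]

    def __post_init__(self) -> None:
        if not self.positives:
            raise ValueError("truth set needs at least one sample")
        for sample, segs in self.positives.items():
            for chrom, s, e, cn in segs:
                if chrom not in self.chromosomes:
                    raise ValueError(f"{sample}: truth segment on unknown chromosome {chrom}")
                if e <= s:
                    raise ValueError(f"{sample}: invalid segment {(chrom, s, e)}")
                if cn == 2:
                    raise ValueError(f"{sample}: neutral segment listed as positive")

    @classmethod
    def from_profiles(cls, profiles: Sequence[TruthProfile],
                      chromosomes: Sequence[str],
                      autosomes_only: bool = True) -> "TruthSet":
        chroms = [c for c in chromosomes if not autosomes_only or is_autosome(c)]
        positives = {}
        for p in profiles:
            positives[p.line_id] = [
                (c, s, e, cn) for c, s, e, cn in p.positive_segments if c in chroms
            ]
        return cls(positives=positives, chromosomes=chroms)

    def neutral_chromosomes(self, sample: str) -> list[str]:
        hit = {c for c, *_ in self.positives[sample]}
        return [c for c in self.chromosomes if c not in hit]


@dataclass
class MatchLabels:
    """Signal-level confusion counts for one sample."""

    sample_id: str
    tp: int
    fn: int
    fp: int
    tn: int
    matched_truth: list = field(default_factory=list)
    unmatched_truth: list = field(default_factory=list)
    false_calls: list = field(default_factory=list)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _direction(cn: int) -> str:
    return "gain" if cn > 2 else "loss"


def match_calls(calls: Sequence[Segment], truth: TruthSet, sample_id: str,
                min_reciprocal_overlap: float = 0.5) -> MatchLabels:
    """Label one sample's non-neutral calls against its truth signals.

    Direction-aware reciprocal-overlap matching; see the module docstring
    for the signal-unit definitions.
    """
    if not 0 < min_reciprocal_overlap <= 1:
        raise ValueError("min_reciprocal_overlap must be in (0,1]")
    if sample_id not in truth.positives:
        raise ValueError(f"sample {sample_id!r} absent from truth set")
    cnv_calls = [c for c in calls if c.call != "neutral"]
    for c in cnv_calls:
        if c.chrom not in truth.chromosomes:
            raise ValueError(f"call on chromosome {c.chrom} absent from truth")
    truth_segs = truth.positives[sample_id]
    matched_truth: list = []
    unmatched_truth: list = []
    used_calls: set[int] = set()
    for seg in truth_segs:
        chrom, s, e, cn = seg
        hit = None
        for i, call in enumerate(cnv_calls):
            if call.chrom != chrom or call.call != _direction(cn):
                continue
            if _reciprocal_overlap((s, e), (call.start, call.end)) >= min_reciprocal_overlap:
                hit = i
                break
        if hit is None:
            unmatched_truth.append(seg)
        else:
            matched_truth.append(seg)
            used_calls.add(hit)
    false_calls = [c for i, c in enumerate(cnv_calls) if i not in used_calls]
    touched = {c.chrom for c in false_calls}
    tn = sum(1 for chrom in truth.neutral_chromosomes(sample_id) if chrom not in touched)
    return MatchLabels(sample_id=sample_id, tp=len(matched_truth),
                       fn=len(unmatched_truth), fp=len(false_calls), tn=tn,
                       matched_truth=matched_truth,
                       unmatched_truth=unmatched_truth, false_calls=false_calls)


def confusion_rates(labels: MatchLabels) -> dict[str, float]:
    """TPR/FNR over positive signals, TNR/FPR over negative signals.

    Empty denominators give NaN rates (flagged by being NaN; aggregation
    skips them).
    """
    pos = labels.tp + labels.fn
    neg = labels.tn + labels.fp
    nan = float("nan")
    return {
        "TPR": labels.tp / pos if pos else nan,
        "FNR": labels.fn / pos if pos else nan,
        "TNR": labels.tn / neg if neg else nan,
        "FPR": labels.fp / neg if neg else nan,
    }


def sensitivity_specificity(rates: Mapping[str, float]) -> tuple[float, float]:
    """Sensitivity = TPR/(TPR+FNR); Specificity = TNR/(TNR+FPR)."""
    nan = float("nan")
    tpr, fnr = rates["TPR"], rates["FNR"]
    tnr, fpr = rates["TNR"], rates["FPR"]
    sens = tpr / (tpr + fnr) if np.isfinite(tpr) and (tpr + fnr) > 0 else (
        nan if not np.isfinite(tpr) else nan)
    spec = tnr / (tnr + fpr) if np.isfinite(tnr) and (tnr + fpr) > 0 else (
        nan if not np.isfinite(tnr) else nan)
    return sens, spec


@dataclass
class EvalResult:
    """Pooled confusion counts and scores for a sample or a combination."""

    name: str
    tp: int
    fn: int
    fp: int
    tn: int
    n_samples: int = 1
    excluded: list[str] = field(default_factory=list)

    @property
    def rates(self) -> dict[str, float]:
        return confusion_rates(MatchLabels(self.name, self.tp, self.fn, self.fp, self.tn))

    @property
    def sensitivity(self) -> float:
        return sensitivity_specificity(self.rates)[0]

    @property
    def specificity(self) -> float:
        return sensitivity_specificity(self.rates)[1]


def evaluate_sample(calls: Sequence[Segment], truth: TruthSet, sample_id: str,
                    min_reciprocal_overlap: float = 0.5) -> EvalResult:
    labels = match_calls(calls, truth, sample_id, min_reciprocal_overlap)
    return EvalResult(name=sample_id, tp=labels.tp, fn=labels.fn,
                      fp=labels.fp, tn=labels.tn)


def aggregate_by_combination(results: Mapping[str, EvalResult],
                             design: Mapping[str, tuple],
                             excluded: Sequence[str] = ()) -> pd.DataFrame:
    """Pool signal counts per experimental combination.

    ``design`` maps sample id -> combination key (e.g. (kit, cell_number)
    or a label such as "RS").  Excluded samples (e.g. failing a CV
    ceiling) are dropped from pooling and listed in the output.  Returns a
    table with pooled counts, rates, sensitivity and specificity per
    combination.
    """
    unmapped = [s for s in results if s not in design]
    if unmapped:
        raise ValueError(f"samples missing from design: {unmapped}")
    pools: dict[tuple, EvalResult] = {}
    for sample, res in results.items():
        if sample in excluded:
            continue
        key = design[sample]
        pool = pools.setdefault(key, EvalResult(name=str(key), tp=0, fn=0,
                                                fp=0, tn=0, n_samples=0))
        pool.tp += res.tp
        pool.fn += res.fn
        pool.fp += res.fp
        pool.tn += res.tn
        pool.n_samples += 1
    for sample in excluded:
        if sample in results and design.get(sample) in pools:
            pools[design[sample]].excluded.append(sample)
    rows = []
    for key, pool in pools.items():
        rates = pool.rates
        rows.append({
            "combination": key, "n_samples": pool.n_samples,
            "tp": pool.tp, "fn": pool.fn, "fp": pool.fp, "tn": pool.tn,
            **rates, "sensitivity": pool.sensitivity,
            "specificity": pool.specificity,
            "excluded": ",".join(pool.excluded),
        })
    return pd.DataFrame(rows)
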