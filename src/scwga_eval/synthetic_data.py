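"""Synthetic genomes, cell-line copy-number truth profiles and WGA read data.

Whole-genome amplification (WGA) from one or a few cells distorts read
depth in two characteristic ways: a smooth dependence of amplification
efficiency on local GC composition (GC bias) and overdispersion of window
counts relative to Poisson sampling (amplification noise, stronger for a
single cell than for 3-8 pooled cells).  This module generates data with
exactly that statistical structure so the downstream pipeline — depth
normalisation, GC-bias quantification/correction, CNV calling and
benchmark scoring — can be exercised end to end at desk scale:

* :func:`generate_genome` — random reference with a smooth spatial GC
  landscape (a Gaussian-smoothed noise field sets the local GC
  probability, bases are drawn per position);
* :func:`generate_truth_profiles` — a panel of cell lines: focal CNVs of
  copy number 1 or 3, one whole-chromosome trisomy, and one copy-neutral
  "negative" line (a balanced-at-depth rearrangement carrier: invisible
  to read-depth analysis, hence modelled as all-diploid);
* :func:`simulate_window_counts` — negative-binomial window counts whose
  expectation is proportional to (copy number / 2) x kit GC efficiency;
* :func:`simulate_alignments` — toy aligned-read records (position,
  strand, MAPQ, CIGAR) with injected positional duplicates and per-base
  mismatch/insertion/deletion events, such that window re-counting after
  deduplication reproduces the input counts exactly.

Every operation is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .count_profile import AlignedRead, WindowCounts, FLAG_REVERSE
from .window_builder import WindowSet, is_autosome

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GCLandscape:
    """Parameters of the smooth spatial GC-composition process.

    ``mean`` is the genome-wide GC level; ``amplitude`` scales a
    unit-variance smoothed noise field added to it; ``correlation_length``
    (bp) is the Gaussian smoothing scale, i.e. the distance over which
    local GC content stays correlated.
    """

    mean: float = 0.42
    amplitude: float = 0.12
    correlation_length: int = 3000

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0:
            raise ValueError("mean GC must be in (0,1)")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")


@dataclass(frozen=True)
class SyntheticGenome:
    """A synthetic reference: named chromosomes over the A/C/G/T alphabet."""

    chromosomes: tuple[tuple[str, str], ...]
    gc_params: GCLandscape = field(default_factory=GCLandscape)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must have at least one chromosome")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"chromosome {name} is empty")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)


def generate_genome(n_chrom: int, lengths: Sequence[int] | int,
                    gc_params: GCLandscape | None = None, seed: int = 0,
                    names: Optional[Sequence[str]] = None) -> SyntheticGenome:
    """Generate a random genome with a smooth GC landscape.

    The local GC probability along each chromosome is
    ``clip(mean + amplitude * z, 0.02, 0.98)`` where ``z`` is white noise
    smoothed with a Gaussian kernel of scale ``correlation_length`` and
    rescaled to unit variance; each base is then drawn independently
    (G/C with that probability, split evenly, likewise A/T).
    Deterministic given ``seed``.
    """
    gc_params = gc_params or GCLandscape()
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if isinstance(lengths, (int, np.integer)):
        lengths = [int(lengths)] * n_chrom
    lengths = [int(x) for x in lengths]
    if len(lengths) != n_chrom:
        raise ValueError("lengths must match n_chrom")
    if any(x <= 0 for x in lengths):
        raise ValueError(f"chromosome lengths must be positive, got {lengths}")
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chrom)]
    rng = np.random.default_rng(seed)
    chroms = []
    for name, L in zip(names, lengths):
        p = np.full(L, gc_params.mean)
        if gc_params.amplitude > 0:
            z = gaussian_filter1d(rng.standard_normal(L),
                                  sigma=gc_params.correlation_length,
                                  mode="reflect")
            sd = z.std()
            if sd > 0:
                z /= sd
            p = np.clip(gc_params.mean + gc_params.amplitude * z, 0.02, 0.98)
        is_gc = rng.random(L) < p
        second = rng.random(L) < 0.5  # C vs G, T vs A
        codes = np.where(is_gc, np.where(second, 1, 2), np.where(second, 0, 3))
        seq = _BASES[codes].tobytes().decode("ascii")
        chroms.append((name, seq))
    return SyntheticGenome(chromosomes=tuple(chroms), gc_params=gc_params, seed=seed)


# ---------------------------------------------------------------------------
# truth profiles


@dataclass(frozen=True)
class TruthProfile:
    """Known copy-number state of one cell line.

    ``segments`` are (chrom, start, end, copy_number) with 0-based
    half-open coordinates and non-negative integer copy number; regions
    not covered by any segment are diploid (copy 2).  ``label`` is one of
    ``cnv`` (focal change), ``aneuploid`` (whole-chromosome change) or
    ``negative`` (copy-neutral everywhere).
    """

    line_id: str
    segments: tuple[tuple[str, int, int, int], ...]
    label: str = "cnv"

    def __post_init__(self) -> None:
        if self.label not in ("cnv", "aneuploid", "negative"):
            raise ValueError(f"unknown label {self.label!r}")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, cn in self.segments:
            if e <= s or s < 0:
                raise ValueError(f"invalid segment {(chrom, s, e)}")
            if cn < 0 or int(cn) != cn:
                raise ValueError(f"copy number must be a non-negative integer, got {cn}")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping segments on {chrom} in {self.line_id}")
        if self.label == "negative" and any(cn != 2 for _, _, _, cn in self.segments):
            raise ValueError("negative profile must be copy 2 everywhere")

    def copy_number(self, chrom: str, pos: int) -> int:
        for c, s, e, cn in self.segments:
            if c == chrom and s <= pos < e:
                return int(cn)
        return 2

    def copy_number_at(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorised copy-number lookup (one position per entry)."""
        cn = np.full(len(positions), 2, dtype=np.int64)
        for c, s, e, k in self.segments:
            m = (chroms == c) & (positions >= s) & (positions < e)
            cn[m] = int(k)
        return cn

    @property
    def positive_segments(self) -> list[tuple[str, int, int, int]]:
        return [(c, s, e, cn) for c, s, e, cn in self.segments if cn != 2]


def generate_truth_profiles(genome: SyntheticGenome,
                            spec: Optional[Iterable[tuple[str, list]]] = None,
                            seed: int = 0) -> list[TruthProfile]:
    """Build a panel of cell-line truth profiles.

    ``spec`` is a list of ``(label, segments)`` pairs; segments are
    ``(chrom, start, end, copy_number)``.  The default panel (spec=None)
    emulates an 11-line benchmark carrying ten focal CNVs: nine CNV lines
    (the first carries two CNVs on different chromosomes, the rest one
    each; copy numbers alternate 3 and 1, placed on cycling autosomes),
    one whole-chromosome trisomy, and one copy-neutral negative line.
    """
    lengths = genome.lengths
    autosomes = [n for n in lengths if is_autosome(n)]
    if spec is None:
        if not autosomes:
            raise ValueError("default panel needs at least one autosome")
        rng = np.random.default_rng(seed)
        cnvs = []
        for i in range(10):
            chrom = autosomes[i % len(autosomes)]
            L = lengths[chrom]
            seg_len = max(L // 5, 1)
            start = int(rng.integers(0, L - seg_len + 1))
            cn = 3 if i % 2 == 0 else 1
            cnvs.append((chrom, start, start + seg_len, cn))
        c0, c1 = cnvs[0], cnvs[1]
        for _ in range(100):   # line 1 carries two CNVs; they must not overlap
            if c0[0] != c1[0] or min(c0[2], c1[2]) <= max(c0[1], c1[1]):
                break
            L = lengths[c1[0]]
            seg_len = c1[2] - c1[1]
            start = int(rng.integers(0, L - seg_len + 1))
            c1 = (c1[0], start, start + seg_len, c1[3])
        else:
            raise ValueError("could not place two non-overlapping CNVs on line 1")
        spec = [("cnv", [c0, c1])]                # ten CNVs across nine lines
        spec += [("cnv", [c]) for c in cnvs[2:]]
        tri = autosomes[min(1, len(autosomes) - 1)]
        spec.append(("aneuploid", [(tri, 0, lengths[tri], 3)]))
        spec.append(("negative", []))
    profiles = []
    for i, (label, segments) in enumerate(spec):
        for chrom, s, e, _cn in segments:
            if chrom not in lengths:
                raise ValueError(f"segment references unknown chromosome {chrom}")
            if e > lengths[chrom]:
                raise ValueError(f"segment {(chrom, s, e)} exceeds chromosome length")
        profiles.append(TruthProfile(line_id=f"CL{i + 1:02d}",
                                     segments=tuple(tuple(x) for x in segments),
                                     label=label))
    return profiles


# ---------------------------------------------------------------------------
# kit profiles


@dataclass(frozen=True)
class KitProfile:
    """Statistical signature of a WGA kit.

    ``gc_efficiency`` maps GC fraction to relative amplification
    efficiency (strictly positive on [0,1]).  ``dispersion_single`` /
    ``dispersion_multi`` are negative-binomial overdispersion parameters
    (variance = mu + d*mu^2) for single-cell and 3-8-cell input; single
    cells amplify less evenly, so dispersion_single >= dispersion_multi.
    ``error_rates`` are per-base (mismatch, deletion, insertion)
    probabilities used when emitting read records.
    """

    name: str
    gc_efficiency: Callable[[np.ndarray], np.ndarray]
    dispersion_single: float = 0.132
    dispersion_multi: float = 0.056
    duplication_rate: float = 0.03
    error_rates: tuple[float, float, float] = (0.015, 0.0005, 0.0005)

    def __post_init__(self) -> None:
        if not self.dispersion_single >= self.dispersion_multi >= 0:
            raise ValueError("require dispersion_single >= dispersion_multi >= 0")
        if not 0 <= self.duplication_rate < 1:
            raise ValueError("duplication_rate must be in [0,1)")
        if any(not 0 <= r < 1 for r in self.error_rates):
            raise ValueError("error rates must be in [0,1)")
        grid = np.linspace(0.0, 1.0, 201)
        if np.any(np.asarray(self.gc_efficiency(grid)) <= 0):
            raise ValueError("gc_efficiency must be strictly positive on [0,1]")

    def dispersion(self, n_cells: int) -> float:
        return self.dispersion_single if n_cells == 1 else self.dispersion_multi


def quadratic_efficiency(c1: float, c2: float, center: float = 0.42,
                         floor: float = 0.05) -> Callable[[np.ndarray], np.ndarray]:
    """Efficiency curve 1 + c1*(g-center) + c2*(g-center)^2, floored at ``floor``."""

    def f(g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        return np.maximum(1.0 + c1 * (g - center) + c2 * (g - center) ** 2, floor)

    return f


def flat_efficiency() -> Callable[[np.ndarray], np.ndarray]:
    return lambda g: np.ones_like(np.asarray(g, dtype=float))


def wga4_like_kit() -> KitProfile:
    """DOP-PCR-style kit: mild GC dependence, moderate duplication."""
    return KitProfile(name="wga4_like",
                      gc_efficiency=quadratic_efficiency(0.9, -1.0),
                      dispersion_single=0.132, dispersion_multi=0.056,
                      duplication_rate=0.05,
                      error_rates=(0.018, 0.0003, 0.0002))


def picoplex_like_kit() -> KitProfile:
    """Displacement+PCR-style kit: stronger preference for GC-rich regions."""
    return KitProfile(name="picoplex_like",
                      gc_efficiency=quadratic_efficiency(1.6, 2.0),
                      dispersion_single=0.132, dispersion_multi=0.056,
                      duplication_rate=0.012,
                      error_rates=(0.015, 0.0004, 0.0005))


# ---------------------------------------------------------------------------
# count simulation


def simulate_window_counts(windows: WindowSet, truth: TruthProfile,
                           kit: KitProfile, n_cells: int, total_reads: int,
                           seed: int = 0, noise: str = "nb") -> WindowCounts:
    """Draw per-window read counts under a copy-number + GC-bias model.

    The expected count of window ``w`` is proportional to
    ``(copy_number_w / 2) * gc_efficiency(GC_w)``, scaled so expected
    counts sum to ``total_reads``.  ``noise``: ``"nb"`` draws from a
    negative binomial with the kit dispersion for ``n_cells`` (Poisson at
    dispersion 0); ``"poisson"`` forces Poisson; ``"none"`` returns the
    rounded expectations (a noise-free fixture).
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if noise not in ("nb", "poisson", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    gc = windows.gc
    if not np.isfinite(gc[~windows.flagged]).all():
        raise ValueError("window with undefined GC; run window_gc first or flag it")
    mid = (windows.start + windows.end) // 2
    cn = truth.copy_number_at(windows.chrom, mid)
    eff = np.asarray(kit.gc_efficiency(np.nan_to_num(gc, nan=0.5)), dtype=float)
    mu = (cn / 2.0) * eff
    mu[windows.flagged] = 0.0
    tot = mu.sum()
    if tot <= 0:
        raise ValueError("degenerate truth/window combination: zero expected depth")
    mu *= total_reads / tot
    rng = np.random.default_rng(seed)
    if noise == "none":
        counts = np.rint(mu).astype(np.int64)
    else:
        d = 0.0 if noise == "poisson" else kit.dispersion(n_cells)
        if d == 0.0:
            counts = rng.poisson(mu)
        else:
            r = 1.0 / d
            p = r / (r + mu)
            counts = rng.negative_binomial(np.where(mu > 0, r, 1.0),
                                           np.where(mu > 0, p, 1.0))
            counts = np.where(mu > 0, counts, 0)
    return WindowCounts(windows=windows, counts=counts.astype(np.int64),
                        sample_id=truth.line_id, n_total_reads=total_reads)


def expected_window_counts(windows: WindowSet, truth: TruthProfile,
                           kit: KitProfile, total_reads: int) -> np.ndarray:
    """The (un-rounded) expected count vector used by simulate_window_counts."""
    mid = (windows.start + windows.end) // 2
    cn = truth.copy_number_at(windows.chrom, mid)
    eff = np.asarray(kit.gc_efficiency(np.nan_to_num(windows.gc, nan=0.5)), dtype=float)
    mu = (cn / 2.0) * eff
    mu[windows.flagged] = 0.0
    return mu * (total_reads / mu.sum())


# ---------------------------------------------------------------------------
# read-record simulation


def _build_cigar(read_len: int, n_ins: int, n_del: int,
                 rng: np.random.Generator) -> str:
    """Compose an M/I/D CIGAR with the given event counts.

    Single-base I and D events are placed at distinct interior breakpoints
    of the aligned read; M blocks always open and close the alignment.
    """
    n_match = read_len - n_ins
    n_events = n_ins + n_del
    if n_events == 0 or n_match < 2 or n_events > n_match - 1:
        return f"{read_len}M"
    cuts = rng.choice(np.arange(1, n_match), size=n_events, replace=False)
    cuts.sort()
    ops = []
    kinds = ["I"] * n_ins + ["D"] * n_del
    rng.shuffle(kinds)
    prev = 0
    for cut, kind in zip(cuts, kinds):
        ops.append(f"{cut - prev}M")
        ops.append(f"1{kind}")
        prev = int(cut)
    ops.append(f"{n_match - prev}M")
    return "".join(ops)


def simulate_alignments(windows: WindowSet, counts: WindowCounts,
                        kit: KitProfile, read_length_mode: str = "fixed-49",
                        seed: int = 0) -> list[AlignedRead]:
    """Emit toy aligned-read records realising a window-count vector.

    One record per counted read, placed at a distinct start position inside
    its window's exclusive zone (the start range not shared with a
    neighbouring window), so that window re-counting after position
    deduplication reproduces ``counts`` exactly.  Positional duplicates
    are injected at the kit duplication rate (identical chrom/pos/strand)
    and per-base mismatch/deletion/insertion events at the kit error
    rates.  ``read_length_mode`` is ``"fixed-49"`` (one platform dialect)
    or ``"variable-min30"`` (lengths drawn around 130 bp, floored at
    20 bp; downstream filtering drops <= 30 bp).
    """
    if counts.windows is not windows and counts.windows.n_windows != windows.n_windows:
        raise ValueError("counts are not consistent with the window set")
    if read_length_mode not in ("fixed-49", "variable-min30"):
        raise ValueError(f"unknown read_length_mode {read_length_mode!r}")
    rng = np.random.default_rng(seed)
    pm, pd_, pi = kit.error_rates
    reads: list[AlignedRead] = []
    n_win = windows.n_windows
    for w in range(n_win):
        c = int(counts.counts[w])
        if c == 0:
            continue
        chrom = windows.chrom[w]
        lo = int(windows.start[w])
        hi = int(windows.start_last[w])
        if w > 0 and windows.chrom[w - 1] == chrom:
            lo = max(lo, int(windows.start_last[w - 1]) + 1)
        if w + 1 < n_win and windows.chrom[w + 1] == chrom:
            hi = min(hi, int(windows.start[w + 1]) - 1)
        zone = np.arange(lo, hi + 1)
        if c <= len(zone):
            starts = rng.choice(zone, size=c, replace=False)
        else:
            logger.warning("window %d: count %d exceeds exclusive zone size %d; "
                           "sampling with replacement", w, c, len(zone))
            starts = rng.choice(zone, size=c, replace=True)
        strands = rng.random(c) < 0.5
        if read_length_mode == "fixed-49":
            lens = np.full(c, 49, dtype=np.int64)
        else:
            lens = np.clip(np.rint(rng.normal(130.0, 45.0, size=c)), 20, 200).astype(np.int64)
        n_mm = rng.binomial(lens, pm)
        n_dl = rng.binomial(lens, pd_)
        n_in = rng.binomial(lens, pi)
        for j in range(c):
            L = int(lens[j])
            reads.append(AlignedRead(
                chrom=chrom, pos=int(starts[j]) + 1,
                strand="-" if strands[j] else "+",
                mapq=60, flag=FLAG_REVERSE if strands[j] else 0,
                cigar=_build_cigar(L, int(n_in[j]), int(n_dl[j]), rng),
                read_length=L, n_mismatch=int(n_mm[j]),
            ))
    r = kit.duplication_rate
    if r > 0 and reads:
        n_dup = rng.binomial(len(reads), r / (1.0 - r))
        templates = rng.integers(0, len(reads), size=n_dup)
        for t in templates:
            src = reads[int(t)]
            dup = AlignedRead(chrom=src.chrom, pos=src.pos, strand=src.strand,
                              mapq=src.mapq, flag=src.flag, cigar=src.cigar,
                              read_length=src.read_length,
                              n_mismatch=src.n_mismatch, is_duplicate=True)
            reads.append(dup)
    return reads
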