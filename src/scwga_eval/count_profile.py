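"""Read ingestion, filtering, window counting and depth normalisation.

This module turns a stream of aligned single-end reads into per-window
unique deduplicated read counts ``R_w`` and the normalised depth ratio

    NDR_w = R_w / M,

where ``M`` is the mean count over autosomal windows, so an NDR of 1.0 is
the diploid expectation.  It also computes summary alignment statistics
(mapping, duplication, coverage and CIGAR-based error rates) in the style
of a sequencing-run QC table, where

    ErrorRate = mismatch rate + deletion rate + insertion rate.

Filtering order mirrors a low-coverage single-cell pipeline: drop
unmapped/secondary records at ingestion, apply a strict read-length floor
for variable-length (semiconductor) reads, remove duplicates on mapping
position, downsample to a fixed read budget, then count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .window_builder import WindowSet

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDS])")

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass
class AlignedRead:
    """A mapped single-end read.

    ``pos`` is the 1-based leftmost mapping position (SAM convention);
    ``start0`` exposes the 0-based coordinate used internally.  ``cigar``
    is restricted to M/I/D/S ops.  ``n_mismatch`` is the number of
    mismatched bases inside M blocks when known (from the simulator or an
    NM-style tag); None when unavailable.
    """

    chrom: str
    pos: int
    strand: str
    mapq: int = 60
    flag: int = 0
    cigar: str = ""
    read_length: int = 0
    n_mismatch: Optional[int] = None
    is_duplicate: bool = False

    @property
    def start0(self) -> int:
        return self.pos - 1

    def cigar_ops(self) -> list[tuple[int, str]]:
        ops = [(int(n), op) for n, op in _CIGAR_RE.findall(self.cigar)]
        if self.cigar and sum(len(str(n)) + 1 for n, _ in ops) != len(self.cigar):
            raise ValueError(f"malformed CIGAR: {self.cigar!r}")
        return ops

    def query_length_from_cigar(self) -> int:
        return sum(n for n, op in self.cigar_ops() if op in "MIS")

    def ref_span(self) -> int:
        span = sum(n for n, op in self.cigar_ops() if op in "MD")
        return span if span else self.read_length


@dataclass
class IngestStats:
    """Bookkeeping filled by :func:`load_alignments`."""

    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    secondary: int = 0
    non_unique: int = 0  # MAPQ 0 primaries (multi-mappers)

    @property
    def unique_mapping_rate(self) -> float:
        return 100.0 * (self.mapped - self.non_unique) / self.total if self.total else float("nan")


@dataclass
class WindowCounts:
    """Per-window unique deduplicated read counts for one sample.

    ``counts`` is aligned with ``windows``; it is integer for raw counts
    and may be float after GC correction.  ``M`` is the autosomal mean
    count over usable windows.
    """

    windows: WindowSet
    counts: np.ndarray
    sample_id: str = ""
    n_total_reads: int = 0
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.windows.n_windows:
            raise ValueError("counts length does not match window set")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative window count")

    @property
    def autosomal_usable(self) -> np.ndarray:
        return self.windows.autosomal & self.windows.usable

    @property
    def M(self) -> float:
        """Mean count over usable autosomal windows."""
        mask = self.autosomal_usable
        if not mask.any():
            raise ValueError("no usable autosomal windows")
        return float(np.mean(self.counts[mask]))


@dataclass
class NDRProfile:
    """Normalised depth ratio per window; autosomal mean is 1 by construction."""

    windows: WindowSet
    ndr: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ndr = np.asarray(self.ndr, dtype=float)

    @property
    def autosomal_usable(self) -> np.ndarray:
        return self.windows.autosomal & self.windows.usable


@dataclass
class AlignmentStats:
    """Run-level alignment summary (all values in percent).

    ``error_rate`` is by definition the sum of the mismatch, deletion and
    insertion rates; fields are None when the underlying information is
    unavailable (e.g. mismatch counts without an edit tally).
    """

    unique_mapping_rate: Optional[float] = None
    coverage: Optional[float] = None
    gc_content: Optional[float] = None
    duplication_rate: Optional[float] = None
    mismatch_rate: Optional[float] = None
    deletion_rate: Optional[float] = None
    insertion_rate: Optional[float] = None
    error_rate: Optional[float] = field(default=None)
    n_reads: int = 0
    n_skipped: int = 0

    @classmethod
    def from_component_rates(cls, mismatch_rate: float, deletion_rate: float,
                             insertion_rate: float, **kw) -> "AlignmentStats":
        """Build a summary from already-measured component rates (percent).

        The ErrorRate is computed, not supplied: it is the exact sum of the
        three components.
        """
        return cls(mismatch_rate=mismatch_rate, deletion_rate=deletion_rate,
                   insertion_rate=insertion_rate,
                   error_rate=mismatch_rate + deletion_rate + insertion_rate,
                   **kw)


# ---------------------------------------------------------------------------
# ingestion


def load_alignments(path, dialect: str = "sam",
                    stats: Optional[IngestStats] = None) -> Iterator[AlignedRead]:
    """Stream mapped primary reads from a SAM/BAM file or the 6-column BED dialect.

    Unmapped, secondary and supplementary records are dropped and tallied
    in ``stats``.  BED dialect columns: chrom, start(0-based), end,
    ``cigar:n_mismatch``, mapq, strand.
    """
    if dialect == "sam":
        yield from _load_sam(str(path), stats)
    elif dialect == "bed":
        yield from _load_bed(str(path), stats)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _load_sam(path: str, stats: Optional[IngestStats]) -> Iterator[AlignedRead]:
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if stats is not None:
                stats.total += 1
            if rec.is_unmapped:
                if stats is not None:
                    stats.unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                if stats is not None:
                    stats.secondary += 1
                continue
            if stats is not None:
                stats.mapped += 1
                if rec.mapping_quality == 0:
                    stats.non_unique += 1
            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            cigar = rec.cigarstring or ""
            n_ins = n_del = 0
            if cigar:
                for n, op in _CIGAR_RE.findall(cigar):
                    if op == "I":
                        n_ins += int(n)
                    elif op == "D":
                        n_del += int(n)
            n_mm = None if nm is None else max(0, int(nm) - n_ins - n_del)
            qlen = rec.query_length or rec.infer_query_length() or 0
            yield AlignedRead(
                chrom=rec.reference_name, pos=rec.reference_start + 1,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality, flag=rec.flag, cigar=cigar,
                read_length=qlen, n_mismatch=n_mm,
            )


def _load_bed(path: str, stats: Optional[IngestStats]) -> Iterator[AlignedRead]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                chrom, start, end, name, mapq, strand = parts[:6]
                start_i, end_i = int(start), int(end)
                cigar, _, nm = name.partition(":")
                n_mm = int(nm) if nm else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})") from exc
            if stats is not None:
                stats.total += 1
                stats.mapped += 1
            yield AlignedRead(
                chrom=chrom, pos=start_i + 1, strand=strand, mapq=int(mapq),
                flag=FLAG_REVERSE if strand == "-" else 0, cigar=cigar,
                read_length=end_i - start_i, n_mismatch=n_mm,
            )


# ---------------------------------------------------------------------------
# filters


def filter_reads(stream: Iterable[AlignedRead], min_length: int = 30,
                 platform_dialect: str = "variable") -> Iterator[AlignedRead]:
    """Length filter for variable-length platforms.

    Keeps reads strictly longer than ``min_length`` bp; the fixed-length
    dialect is a pass-through (all reads share one length by construction).
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    if platform_dialect.startswith("fixed"):
        yield from stream
        return
    for read in stream:
        if read.read_length > min_length:
            yield read


@dataclass
class DedupeResult:
    reads: list
    n_input: int
    n_removed: int

    @property
    def duplication_rate(self) -> float:
        """Removed / input, in percent."""
        return 100.0 * self.n_removed / self.n_input if self.n_input else 0.0


def dedupe_by_position(stream: Iterable[AlignedRead],
                       key: str = "pos-strand") -> DedupeResult:
    """Remove position duplicates, keeping the first-seen read per key.

    ``key`` is ``"pos-strand"`` (default: same-position opposite-strand
    reads are distinct molecules) or ``"pos"`` (position only).
    """
    if key not in ("pos", "pos-strand"):
        raise ValueError("key must be 'pos' or 'pos-strand'")
    seen: set = set()
    kept: list[AlignedRead] = []
    n = 0
    for read in stream:
        n += 1
        k = (read.chrom, read.pos, read.strand) if key == "pos-strand" else (read.chrom, read.pos)
        if k in seen:
            continue
        seen.add(k)
        kept.append(read)
    return DedupeResult(reads=kept, n_input=n, n_removed=n - len(kept))


def downsample(stream: Iterable[AlignedRead], n: int = 2_000_000,
               seed: int = 0) -> list[AlignedRead]:
    """Uniform sample of ``min(n, total)`` reads without replacement.

    Single-pass reservoir sampling (memory bounded by ``n``); the output
    preserves the original stream order.  Deterministic given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    reservoir: list[tuple[int, AlignedRead]] = []
    total = 0
    for i, read in enumerate(stream):
        total += 1
        if n == 0:
            continue
        if len(reservoir) < n:
            reservoir.append((i, read))
        else:
            j = int(rng.integers(0, i + 1))
            if j < n:
                reservoir[j] = (i, read)
    if 0 < total < n:
        logger.warning("requested %d reads but stream has only %d; returning all", n, total)
    reservoir.sort(key=lambda t: t[0])
    return [r for _, r in reservoir]


# ---------------------------------------------------------------------------
# counting and normalisation


def count_in_windows(stream: Iterable[AlignedRead], windows: WindowSet,
                     sample_id: str = "", double_count_overlap: bool = True
                     ) -> WindowCounts:
    """Count reads per window by 0-based start position.

    A read whose start falls in the overlap zone shared by two windows
    increments both (consistent with windows sharing simulated reads);
    pass ``double_count_overlap=False`` to assign such reads to the
    earlier window only.  Reads outside every window are tallied as
    unassigned.
    """
    starts_by_chrom: dict[str, list[int]] = {}
    total = 0
    for read in stream:
        starts_by_chrom.setdefault(read.chrom, []).append(read.start0)
        total += 1
    counts = np.zeros(windows.n_windows, dtype=np.int64)
    assigned = 0
    for name, starts in starts_by_chrom.items():
        arr = np.sort(np.asarray(starts, dtype=np.int64))
        m = np.nonzero(windows.chrom == name)[0]
        if len(m) == 0:
            continue
        lo = windows.start[m].copy()
        hi = windows.start_last[m]
        if not double_count_overlap:
            # each window owns only the starts not claimed by its predecessor
            lo[1:] = np.maximum(lo[1:], hi[:-1] + 1)
        counts[m] = (np.searchsorted(arr, hi, side="right")
                     - np.searchsorted(arr, lo, side="left"))
        # membership in the union of [start, start_last] intervals
        ulo, uhi = [], []
        for s, e in zip(windows.start[m], hi):
            if ulo and s <= uhi[-1] + 1:
                uhi[-1] = max(uhi[-1], e)
            else:
                ulo.append(s)
                uhi.append(e)
        ulo_a = np.asarray(ulo)
        uhi_a = np.asarray(uhi)
        inside = np.searchsorted(ulo_a, arr, side="right") - 1
        ok = (inside >= 0) & (arr <= uhi_a[np.clip(inside, 0, None)])
        assigned += int(ok.sum())
    return WindowCounts(windows=windows, counts=counts, sample_id=sample_id,
                        n_total_reads=total, n_unassigned=total - assigned)


def compute_ndr(counts: WindowCounts) -> NDRProfile:
    """NDR_w = R_w / M with M the usable-autosomal mean count."""
    M = counts.M
    if M <= 0:
        raise ValueError("empty profile: autosomal mean count is zero")
    return NDRProfile(windows=counts.windows,
                      ndr=np.asarray(counts.counts, dtype=float) / M,
                      sample_id=counts.sample_id)


# ---------------------------------------------------------------------------
# alignment statistics


def alignment_stats(raw: Iterable[AlignedRead], filtered: Iterable[AlignedRead],
                    ingest: Optional[IngestStats] = None,
                    genome_length: Optional[int] = None,
                    duplication_rate: Optional[float] = None,
                    gc_content: Optional[float] = None) -> AlignmentStats:
    """QC-table statistics from the raw and filtered read streams.

    Per-base event rates are counted over the filtered stream: mismatch,
    deletion and insertion bases divided by total aligned (M) bases, in
    percent; ErrorRate is their exact sum.  Mismatch bases require an edit
    tally (simulator bookkeeping or an NM-style tag) — without one the
    mismatch and error rates are reported as None, never guessed.
    Coverage (bases covered at least once / genome length) needs
    ``genome_length``.
    """
    raw = list(raw)
    filtered = list(filtered)
    m_bases = d_bases = i_bases = 0
    mm_bases = 0
    mm_known = True
    skipped = 0
    spans: dict[str, list[tuple[int, int]]] = {}
    for read in filtered:
        try:
            ops = read.cigar_ops()
        except ValueError:
            skipped += 1
            continue
        if not ops:
            skipped += 1
            continue
        m_bases += sum(n for n, op in ops if op == "M")
        d_bases += sum(n for n, op in ops if op == "D")
        i_bases += sum(n for n, op in ops if op == "I")
        if read.n_mismatch is None:
            mm_known = False
        else:
            mm_bases += read.n_mismatch
        spans.setdefault(read.chrom, []).append((read.start0, read.start0 + read.ref_span()))
    if skipped:
        logger.warning("alignment_stats: skipped %d read(s) with malformed/empty CIGAR", skipped)

    stats = AlignmentStats(n_reads=len(filtered), n_skipped=skipped,
                           duplication_rate=duplication_rate, gc_content=gc_content)
    if ingest is not None and ingest.total:
        stats.unique_mapping_rate = ingest.unique_mapping_rate
    if m_bases > 0:
        stats.deletion_rate = 100.0 * d_bases / m_bases
        stats.insertion_rate = 100.0 * i_bases / m_bases
        if mm_known:
            stats.mismatch_rate = 100.0 * mm_bases / m_bases
            stats.error_rate = (stats.mismatch_rate + stats.deletion_rate
                                + stats.insertion_rate)
    if genome_length:
        covered = 0
        for ivs in spans.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s > cur_e:
                    covered += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            covered += cur_e - cur_s
        stats.coverage = 100.0 * covered / genome_length
    return stats
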