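"""Equal-mappability genomic windows.

Low-coverage read-depth analysis bins the genome into windows that each
contain the same number of *uniquely mappable* simulated read starts, so
that every window carries the same information content regardless of local
repeat structure.  The construction is:

1. tile the reference into fixed-length single-end reads at a fixed step,
2. re-map every read back to the reference by exhaustive Hamming search
   (both strands, a small mismatch budget) and keep positions whose read
   has exactly one placement,
3. walk each chromosome grouping mappable read starts into windows of
   ``reads_per_window`` reads, adjacent windows sharing ``overlap_reads``
   reads,
4. annotate each window with its reference GC fraction.

The exhaustive re-mapping is O(genome^2 x read_length) by design: it is an
idealised mappability computation meant for desk-scale synthetic genomes,
not for full mammalian references.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CHROM_NAMES = frozenset({"x", "y", "chrx", "chry"})

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def is_autosome(name: str) -> bool:
    return name.lower() not in SEX_CHROM_NAMES


def _encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A,C,G,T -> 0..3; anything else 255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


@dataclass
class WindowSet:
    """Ordered genomic windows with per-window GC and simulated-read counts.

    Coordinates are 0-based half-open.  ``start_last`` is the start of the
    *last* simulated read in the window; reads are assigned to a window by
    their start position falling in ``[start, start_last]``, while
    ``end = start_last + read_length`` is the genomic span used for GC.
    """

    chrom: np.ndarray          # str per window
    start: np.ndarray          # int
    end: np.ndarray            # int
    start_last: np.ndarray     # int, start of last member read
    gc: np.ndarray             # float, NaN when undefined
    n_sim_reads: np.ndarray    # int
    flagged: np.ndarray        # bool, short/degenerate windows
    read_length: int = 50
    step: int = 1
    max_mismatches: int = 2
    reads_per_window: int = 100
    overlap_reads: int = 20

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        for name in ("start", "end", "start_last", "n_sim_reads"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self.gc = np.asarray(self.gc, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        order_ok = True
        for i in range(1, len(self.chrom)):
            if self.chrom[i] == self.chrom[i - 1] and self.start[i] < self.start[i - 1]:
                order_ok = False
        if not order_ok:
            raise ValueError("windows must be sorted by (chrom, start)")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_windows(self) -> int:
        return len(self.start)

    @property
    def autosomal(self) -> np.ndarray:
        """Boolean mask of autosomal windows."""
        return np.array([is_autosome(c) for c in self.chrom], dtype=bool)

    @property
    def usable(self) -> np.ndarray:
        """Windows with defined GC and no degeneracy flag."""
        return ~self.flagged & np.isfinite(self.gc)

    def chrom_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "start_last": self.start_last,
                "gc": self.gc,
                "n_sim_reads": self.n_sim_reads,
                "flagged": self.flagged,
            }
        )

    @classmethod
    def from_gc(cls, gc: Sequence[float], chrom: str | Sequence[str] = "chr1",
                window_size: int = 1000, read_length: int = 50) -> "WindowSet":
        """Build an abstract WindowSet from a GC vector alone.

        Convenient for simulation studies that only need per-window GC
        fractions, not a concrete reference sequence.  Windows are laid out
        contiguously (no overlap).
        """
        gc = np.asarray(gc, dtype=float)
        n = len(gc)
        if isinstance(chrom, str):
            chroms = np.array([chrom] * n, dtype=object)
            starts = np.arange(n, dtype=np.int64) * window_size
        else:
            chroms = np.asarray(chrom, dtype=object)
            starts = np.zeros(n, dtype=np.int64)
            for name in dict.fromkeys(chroms):
                m = chroms == name
                starts[m] = np.arange(m.sum(), dtype=np.int64) * window_size
        return cls(
            chrom=chroms,
            start=starts,
            end=starts + window_size,
            start_last=starts + window_size - read_length,
            gc=gc,
            n_sim_reads=np.full(n, 1, dtype=np.int64),
            flagged=np.zeros(n, dtype=bool),
            read_length=read_length,
            reads_per_window=1,
            overlap_reads=0,
        )


def tile_reads(genome, read_length: int = 50, step: int = 1
               ) -> Iterator[tuple[str, int, str]]:
    """Tile every chromosome into simulated single-end reads.

    Yields ``(chrom, start, subsequence)`` for every start position ``p``
    with ``p + read_length <= len(chrom)``, at the given step.
    """
    if read_length <= 0:
        raise ValueError(f"read_length must be positive, got {read_length}")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    for name, seq in genome.chromosomes:
        if read_length > len(seq):
            continue
        for p in range(0, len(seq) - read_length + 1, step):
            yield name, p, seq[p:p + read_length]


def _pack_kmers(codes: np.ndarray, k: int, starts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack k-mers starting at ``starts``; returns (words, valid mask)."""
    n_words = (k + 31) // 32
    idx = starts[:, None] + np.arange(k)[None, :]
    km = codes[idx]  # (n, k)
    valid = ~(km == 255).any(axis=1)
    km = np.where(km == 255, 0, km).astype(np.uint64)
    words = np.zeros((len(starts), n_words), dtype=np.uint64)
    for w in range(n_words):
        block = km[:, 32 * w:32 * (w + 1)]
        shifts = (2 * np.arange(block.shape[1], dtype=np.uint64))
        words[:, w] = (block << shifts[None, :]).sum(axis=1, dtype=np.uint64)
    return words, valid


_LOW_BITS = np.uint64(0x5555555555555555)


def _hamming_counts(query: np.ndarray, targets: np.ndarray, max_mm: int,
                    chunk: int = 128) -> np.ndarray:
    """Number of targets within Hamming distance ``max_mm`` of each query.

    ``query``/``targets`` are 2-bit packed (n, n_words) uint64 arrays.
    """
    nq = len(query)
    nt = len(targets)
    out = np.zeros(nq, dtype=np.int64)
    n_words = query.shape[1]
    for lo in range(0, nq, chunk):
        q = query[lo:lo + chunk]
        dist = np.zeros((len(q), nt), dtype=np.int64)
        for w in range(n_words):
            x = q[:, None, w] ^ targets[None, :, w]
            y = (x | (x >> np.uint64(1))) & _LOW_BITS
            dist += np.bitwise_count(y).astype(np.int64)
        out[lo:lo + chunk] = (dist <= max_mm).sum(axis=1)
    return out


_RC_CODE = {0: 3, 1: 2, 2: 1, 3: 0}


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    rc = codes[::-1].copy()
    ok = rc != 255
    rc[ok] = 3 - rc[ok]
    return rc


def unique_mappability(genome, read_length: int = 50, step: int = 1,
                       max_mismatches: int = 2) -> dict[str, np.ndarray]:
    """Exhaustive unique-mappability track for a desk-scale genome.

    A tiled read is *mappable* iff it has exactly one placement on either
    strand of the whole genome within ``max_mismatches`` Hamming distance
    (indels are not modelled).  A read placed equally well at two sites is
    unmappable.  Returns, per chromosome, a boolean array over the tiling
    grid (one entry per simulated read start).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    k = read_length
    # Candidate placements: every position (step 1) on both strands.
    target_words = []
    for name, seq in genome.chromosomes:
        codes = _encode(seq)
        if len(codes) < k:
            continue
        starts = np.arange(len(codes) - k + 1)
        w, valid = _pack_kmers(codes, k, starts)
        target_words.append(w[valid])
        rc = _revcomp_codes(codes)
        w, valid = _pack_kmers(rc, k, starts)
        target_words.append(w[valid])
    targets = np.concatenate(target_words, axis=0)

    track: dict[str, np.ndarray] = {}
    for name, seq in genome.chromosomes:
        codes = _encode(seq)
        if len(codes) < k:
            track[name] = np.zeros(0, dtype=bool)
            continue
        starts = np.arange(0, len(codes) - k + 1, step)
        words, valid = _pack_kmers(codes, k, starts)
        counts = _hamming_counts(words, targets, max_mismatches)
        track[name] = valid & (counts == 1)
    return track


def build_windows(mappability: dict[str, np.ndarray], genome=None, *,
                  reads_per_window: int = 100, overlap_reads: int = 20,
                  read_length: int = 50, step: int = 1,
                  max_mismatches: int = 2) -> WindowSet:
    """Group mappable read starts into fixed-read-budget windows.

    Each window holds ``reads_per_window`` mappable simulated reads and
    shares exactly ``overlap_reads`` of them with the next window on the
    same chromosome.  Chromosomes are processed in sorted-name order so the
    result is independent of the input dict ordering.  A chromosome whose
    tail (or entirety) cannot fill a window yields one flagged short window.
    """
    if not (0 <= overlap_reads < reads_per_window):
        raise ValueError("require 0 <= overlap_reads < reads_per_window")
    rows: list[tuple] = []
    stride = reads_per_window - overlap_reads
    for name in sorted(mappability):
        m = np.asarray(mappability[name], dtype=bool)
        pos = np.nonzero(m)[0] * step
        if len(pos) == 0:
            continue
        if len(pos) < reads_per_window:
            logger.warning("chromosome %s has only %d mappable reads (< %d); "
                           "emitting one flagged short window", name, len(pos),
                           reads_per_window)
        s = 0
        while s < len(pos):
            chunk = pos[s:s + reads_per_window]
            if s > 0 and len(chunk) <= overlap_reads:
                break  # fully contained in the previous window
            short = len(chunk) < reads_per_window
            rows.append((name, int(chunk[0]), int(chunk[-1]) + read_length,
                         int(chunk[-1]), len(chunk), short))
            s += stride
    if not rows:
        raise ValueError("no mappable positions; cannot build windows")
    chrom, start, end, start_last, nreads, flagged = map(np.array, zip(*rows))
    ws = WindowSet(
        chrom=chrom.astype(object), start=start, end=end, start_last=start_last,
        gc=np.full(len(rows), np.nan), n_sim_reads=nreads,
        flagged=flagged.astype(bool), read_length=read_length, step=step,
        max_mismatches=max_mismatches, reads_per_window=reads_per_window,
        overlap_reads=overlap_reads,
    )
    if genome is not None:
        ws = window_gc(genome, ws)
    return ws


def window_gc(genome, windows: WindowSet) -> WindowSet:
    """Fill per-window GC fraction = (#G + #C) / (window non-N length).

    All-N windows get NaN GC and are flagged (downstream stages exclude
    them).
    """
    seqs = {name: _encode(seq) for name, seq in genome.chromosomes}
    gc = np.empty(windows.n_windows)
    flagged = windows.flagged.copy()
    for name, codes in seqs.items():
        isgc = ((codes == 1) | (codes == 2)).astype(np.int64)
        isn = (codes == 255).astype(np.int64)
        cg = np.concatenate([[0], np.cumsum(isgc)])
        cn = np.concatenate([[0], np.cumsum(isn)])
        m = windows.chrom == name
        if not m.any():
            continue
        s = windows.start[m]
        e = np.minimum(windows.end[m], len(codes))
        if (windows.end[m] > len(codes)).any() or (s < 0).any():
            raise ValueError(f"window out of bounds on {name}")
        n_gc = cg[e] - cg[s]
        n_n = cn[e] - cn[s]
        denom = (e - s) - n_n
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, n_gc / np.maximum(denom, 1), np.nan)
        gc[m] = frac
        bad = np.zeros(windows.n_windows, dtype=bool)
        bad[m] = denom == 0
        if bad.any():
            warnings.warn(f"{bad.sum()} all-N window(s) on {name}: GC undefined, flagged")
            flagged |= bad
    missing = [c for c in windows.chrom_names() if c not in seqs]
    if missing:
        raise ValueError(f"windows reference chromosomes absent from genome: {missing}")
    return replace(windows, gc=gc, flagged=flagged)
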