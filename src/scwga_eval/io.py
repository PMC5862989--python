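"""Plain-text readers/writers for the pipeline's interchange formats.

FASTA for genomes (read via Bio.SeqIO), BED for truth profiles and CNV
calls, BED+2 for window sets, TSV for counts/NDR and QC tables, minimal
single-end SAM (read via pysam) or a 6-column BED dialect for reads.
All coordinates on disk are 0-based half-open except SAM POS (1-based).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .cnv_caller import Segment
from .count_profile import AlignedRead, NDRProfile, WindowCounts
from .synthetic_data import SyntheticGenome, TruthProfile
from .window_builder import WindowSet


# --- FASTA ---------------------------------------------------------------

def write_fasta(genome: SyntheticGenome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> SyntheticGenome:
    from Bio import SeqIO

    chroms = tuple((rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta"))
    if not chroms:
        raise ValueError(f"no sequences in {path}")
    return SyntheticGenome(chromosomes=chroms)


# --- truth profiles ------------------------------------------------------

def write_truth_bed(profiles: Sequence[TruthProfile], path) -> None:
    """BED+2: chrom, start, end, line_id, copy_number, label (positives only;
    a profile with no positive segments writes a single header-like comment)."""
    with open(path, "w") as fh:
        for p in profiles:
            wrote = False
            for chrom, s, e, cn in p.segments:
                fh.write(f"{chrom}\t{s}\t{e}\t{p.line_id}\t{cn}\t{p.label}\n")
                wrote = True
            if not wrote:
                fh.write(f"#\t.\t.\t{p.line_id}\t2\t{p.label}\n")


def read_truth_bed(path) -> list[TruthProfile]:
    segs: dict[str, list] = {}
    labels: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, s, e, line_id, cn, label = line.split("\t")[:6]
            if line_id not in segs:
                segs[line_id] = []
                order.append(line_id)
            labels[line_id] = label
            if not chrom.startswith("#"):
                segs[line_id].append((chrom, int(s), int(e), int(cn)))
    return [TruthProfile(line_id=lid, segments=tuple(segs[lid]), label=labels[lid])
            for lid in order]


# --- windows -------------------------------------------------------------

def write_windows_bed(windows: WindowSet, path) -> None:
    df = windows.to_dataframe()
    df.to_csv(path, sep="\t", index=False)


def read_windows_bed(path, **params) -> WindowSet:
    df = pd.read_csv(path, sep="\t")
    return WindowSet(
        chrom=df["chrom"].to_numpy(dtype=object), start=df["start"].to_numpy(),
        end=df["end"].to_numpy(), start_last=df["start_last"].to_numpy(),
        gc=df["gc"].to_numpy(), n_sim_reads=df["n_sim_reads"].to_numpy(),
        flagged=df["flagged"].to_numpy(dtype=bool), **params,
    )


# --- counts / NDR --------------------------------------------------------

def write_counts_tsv(counts: WindowCounts, path, column: str = "count") -> None:
    ws = counts.windows
    pd.DataFrame({
        "chrom": ws.chrom, "start": ws.start, "end": ws.end,
        "gc": ws.gc, column: counts.counts,
    }).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, windows: WindowSet, sample_id: str = "",
                    column: str = "count") -> WindowCounts:
    df = pd.read_csv(path, sep="\t")
    if len(df) != windows.n_windows:
        raise ValueError("counts file does not match window set")
    return WindowCounts(windows=windows, counts=df[column].to_numpy(),
                        sample_id=sample_id)


def write_ndr_tsv(profile: NDRProfile, path) -> None:
    ws = profile.windows
    pd.DataFrame({
        "chrom": ws.chrom, "start": ws.start, "end": ws.end,
        "gc": ws.gc, "ndr": profile.ndr,
    }).to_csv(path, sep="\t", index=False)


# --- reads ---------------------------------------------------------------

def write_sam(reads: Iterable[AlignedRead], genome_lengths: dict[str, int],
              path) -> None:
    """Minimal single-end SAM: FLAG/POS/MAPQ/CIGAR populated, '*' sequence,
    NM tag carrying mismatch+indel bases when the edit tally is known."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.4\tSO:unknown\n")
        for name, length in genome_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for i, r in enumerate(reads):
            nm = ""
            if r.n_mismatch is not None:
                ops = r.cigar_ops()
                indel = sum(n for n, op in ops if op in "ID")
                nm = f"\tNM:i:{r.n_mismatch + indel}"
            cigar = r.cigar or f"{r.read_length}M"
            fh.write(f"r{i}\t{r.flag}\t{r.chrom}\t{r.pos}\t{r.mapq}\t{cigar}"
                     f"\t*\t0\t0\t*\t*{nm}\n")


def write_reads_bed(reads: Iterable[AlignedRead], path) -> None:
    """6-column dialect: chrom, start, end, cigar:n_mismatch, mapq, strand."""
    with open(path, "w") as fh:
        for r in reads:
            nm = "" if r.n_mismatch is None else str(r.n_mismatch)
            cigar = r.cigar or f"{r.read_length}M"
            fh.write(f"{r.chrom}\t{r.start0}\t{r.start0 + r.read_length}"
                     f"\t{cigar}:{nm}\t{r.mapq}\t{r.strand}\n")


# --- calls / results -----------------------------------------------------

def write_calls_bed(segments: Sequence[Segment], path,
                    non_neutral_only: bool = True) -> None:
    """BED+3: chrom, start, end, call, copy_number, mean_ndr[, flag]."""
    with open(path, "w") as fh:
        for seg in segments:
            if non_neutral_only and seg.call == "neutral":
                continue
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.call}"
                     f"\t{seg.copy_number}\t{seg.mean_ndr:.6g}\t{seg.flag}\n")


def read_calls_bed(path) -> list[Segment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, s, e, call, cn, ndr = parts[:6]
            flag = parts[6] if len(parts) > 6 else ""
            out.append(Segment(chrom=chrom, start=int(s), end=int(e),
                               mean_ndr=float(ndr), n_windows=0,
                               copy_number=int(cn), call=call, flag=flag))
    return out
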