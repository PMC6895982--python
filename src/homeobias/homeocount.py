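"""Assign RNA-seq reads to subgenomes at diagnostic homoeo-SNPs.

Reads mapped to a homoeolog cDNA reference are interrogated at each
diagnostic SNP; a read carrying the maternal allele increments the maternal
(H) count, the paternal allele the paternal (C) count, anything else the
``other`` bucket, and bases below the quality cutoff ``low_quality``.  Per
replicate and per SNP the table mirrors the study design: H subtotal,
C subtotal and Total = maternal + paternal (third-allele and low-quality
reads are tracked but excluded from the total and from the bias test).

Also provides a deterministic exact-match k-mer anchor aligner for
single-gene synthetic data (a stand-in for a genome mapper at this scale),
SAM ingestion via pysam, and FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .seqvar import DiagnosticSNP, GeneSequence, InputError


class ParameterError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Read alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadAlignment:
    """An ungapped placement of a read (or the matched bases of a SAM record).

    ``pairs`` holds (1-based reference position, read base, quality) for
    every aligned base, positions strictly increasing.  ``strand`` is '-'
    when the read aligned as its reverse complement.
    """

    read_id: str
    ref_id: str
    ref_start: int
    pairs: tuple[tuple[int, str, int], ...]
    strand: str = "+"
    n_mismatches: int = 0

    def __post_init__(self):
        positions = [p for p, _, _ in self.pairs]
        if any(q >= p for p, q in zip(positions[1:], positions)):
            raise CoordinateError(f"{self.read_id}: reference positions not increasing")

    def base_at(self, ref_pos: int) -> tuple[str, int] | None:
        """(base, quality) of the read at a reference position, if covered."""
        lo, hi = 0, len(self.pairs)
        while lo < hi:
            mid = (lo + hi) // 2
            if self.pairs[mid][0] < ref_pos:
                lo = mid + 1
            else:
                hi = mid
        if lo < len(self.pairs) and self.pairs[lo][0] == ref_pos:
            return self.pairs[lo][1], self.pairs[lo][2]
        return None


def simple_align_reads(reads: Iterable, reference: GeneSequence | str,
                       k: int = 15, max_mismatch_frac: float = 0.2,
                       ) -> list[ReadAlignment]:
    """Place reads on an ungapped reference by exact k-mer anchor + extension.

    Each read is anchored by exact k-mer lookup (both orientations), extended
    without gaps over its full length, and kept at the placement with the
    fewest mismatches (ties: forward strand, then smallest offset).  Reads
    with no anchor, extending past the reference, or with more than
    ``max_mismatch_frac`` mismatching bases are dropped.  Deterministic.

    ``reads`` may be Bio.SeqIO FASTQ records or (id, seq, qualities) tuples.
    """
    if isinstance(reference, GeneSequence):
        ref_id, ref = reference.id, reference.seq
    else:
        ref_id, ref = "ref", str(reference).upper()

    index: dict[str, list[int]] = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i : i + k], []).append(i)

    def normalize(rec):
        if hasattr(rec, "letter_annotations"):
            quals = rec.letter_annotations.get("phred_quality") or [40] * len(rec.seq)
            return rec.id, str(rec.seq).upper(), list(quals)
        rid, seq, quals = rec
        return rid, seq.upper(), list(quals) if quals else [40] * len(seq)

    out: list[ReadAlignment] = []
    for rec in reads:
        rid, seq, quals = normalize(rec)
        if k > len(seq):
            raise ParameterError(f"anchor length k={k} exceeds read length {len(seq)}")
        best = None  # (mismatches, strand_rank, start, oriented_seq, oriented_quals)
        for strand, oseq, oquals in (
            ("+", seq, quals),
            ("-", str(Seq(seq).reverse_complement()), quals[::-1]),
        ):
            starts = set()
            offsets = list(range(0, len(oseq) - k + 1, k))
            if offsets[-1] != len(oseq) - k:
                offsets.append(len(oseq) - k)
            for off in offsets:
                for hit in index.get(oseq[off : off + k], ()):
                    start = hit - off
                    if 0 <= start <= len(ref) - len(oseq):
                        starts.add(start)
            for start in sorted(starts):
                mm = sum(a != b for a, b in zip(oseq, ref[start : start + len(oseq)]))
                cand = (mm, 0 if strand == "+" else 1, start, oseq, oquals)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        if best is None:
            continue
        mm, srank, start, oseq, oquals = best
        if mm > max_mismatch_frac * len(oseq):
            continue
        pairs = tuple((start + i + 1, oseq[i], oquals[i]) for i in range(len(oseq)))
        out.append(ReadAlignment(
            read_id=rid, ref_id=ref_id, ref_start=start + 1, pairs=pairs,
            strand="+" if srank == 0 else "-", n_mismatches=mm))
    return out


def read_sam(path: str | Path, ref_id: str | None = None) -> list[ReadAlignment]:
    """Load read placements from SAM/BAM, one per primary mapped record.

    Secondary and supplementary alignments are skipped and soft-clipped
    bases are ignored, so each fragment contributes once.
    """
    import pysam

    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if ref_id is not None and rec.reference_name != ref_id:
                continue
            seq = rec.query_sequence
            quals = rec.query_qualities
            pairs = []
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                q = quals[qpos] if quals is not None else 40
                pairs.append((rpos + 1, seq[qpos].upper(), q))
            if not pairs:
                continue
            out.append(ReadAlignment(
                read_id=rec.query_name,
                ref_id=rec.reference_name or "ref",
                ref_start=pairs[0][0],
                pairs=tuple(pairs),
                strand="-" if rec.is_reverse else "+"))
    return out


# ---------------------------------------------------------------------------
# Allele counting
# ---------------------------------------------------------------------------


@dataclass
class SnpCounts:
    maternal: int = 0
    paternal: int = 0
    other: int = 0
    low_quality: int = 0

    @property
    def total(self) -> int:
        """Reads informative for the bias test: parental alleles only."""
        return self.maternal + self.paternal

    @property
    def overlaps(self) -> int:
        return self.maternal + self.paternal + self.other + self.low_quality


@dataclass
class AlleleCountTable:
    """Per-replicate, per-SNP allele counts (the study's count-table shape).

    ``counts[replicate][cdna_pos]`` is a :class:`SnpCounts`.  H subtotal is
    the maternal count, C subtotal the paternal count, and Total their sum.
    """

    counts: dict[str, dict[int, SnpCounts]] = field(default_factory=dict)

    def add_replicate(self, replicate: str, per_snp: dict[int, SnpCounts]) -> None:
        self.counts[replicate] = per_snp

    @property
    def replicates(self) -> list[str]:
        return list(self.counts)

    @property
    def snp_positions(self) -> list[int]:
        pos = {p for per_snp in self.counts.values() for p in per_snp}
        return sorted(pos)

    def pooled(self, replicate: str) -> SnpCounts:
        """Counts summed over SNPs within a replicate."""
        c = SnpCounts()
        for s in self.counts[replicate].values():
            c.maternal += s.maternal
            c.paternal += s.paternal
            c.other += s.other
            c.low_quality += s.low_quality
        return c

    def paternal_fraction(self, replicate: str | None = None) -> float:
        """Estimate of the paternal read fraction θ (pooled if no replicate)."""
        reps = [replicate] if replicate else self.replicates
        m = sum(self.pooled(r).maternal for r in reps)
        p = sum(self.pooled(r).paternal for r in reps)
        if m + p == 0:
            raise InputError("no informative reads")
        return p / (m + p)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rep, per_snp in self.counts.items():
            for pos in sorted(per_snp):
                s = per_snp[pos]
                rows.append({"replicate": rep, "snp": pos,
                             "h_subtotal": s.maternal, "c_subtotal": s.paternal,
                             "total": s.total, "other": s.other,
                             "low_quality": s.low_quality})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AlleleCountTable":
        table = cls()
        for rep, sub in df.groupby("replicate", sort=False):
            table.add_replicate(str(rep), {
                int(r.snp): SnpCounts(
                    maternal=int(r.h_subtotal), paternal=int(r.c_subtotal),
                    other=int(getattr(r, "other", 0)),
                    low_quality=int(getattr(r, "low_quality", 0)))
                for r in sub.itertuples()})
        return table

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleCountTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))


def count_alleles(alignments: Sequence[ReadAlignment],
                  snps: Sequence[DiagnosticSNP],
                  min_base_quality: int = 20,
                  retained_only: bool = True,
                  ref_length: int | None = None) -> dict[int, SnpCounts]:
    """Count maternal/paternal alleles at each diagnostic SNP for one library.

    Counting is per SNP: a read spanning several SNPs contributes to each
    SNP's column independently.  Mates sharing a read id are collapsed so a
    fragment is counted once per SNP.  Bases below ``min_base_quality`` go
    to ``low_quality``; non-parental bases to ``other``.
    """
    use = [s for s in snps if s.retained or not retained_only]
    for s in use:
        if s.cdna_pos < 1 or (ref_length is not None and s.cdna_pos > ref_length):
            raise CoordinateError(f"SNP cDNA position {s.cdna_pos} outside reference")
    out = {s.cdna_pos: SnpCounts() for s in use}
    seen: set[tuple[int, str]] = set()
    for aln in alignments:
        for s in use:
            hit = aln.base_at(s.cdna_pos)
            if hit is None:
                continue
            if (s.cdna_pos, aln.read_id) in seen:
                continue
            seen.add((s.cdna_pos, aln.read_id))
            base, qual = hit
            c = out[s.cdna_pos]
            if qual < min_base_quality:
                c.low_quality += 1
            elif base == s.maternal_allele:
                c.maternal += 1
            elif base == s.paternal_allele:
                c.paternal += 1
            else:
                c.other += 1
    return out


def count_alleles_per_replicate(reads_by_replicate: dict[str, Sequence],
                                reference: GeneSequence | str,
                                snps: Sequence[DiagnosticSNP],
                                min_base_quality: int = 20,
                                k: int = 15) -> AlleleCountTable:
    """Align FASTQ reads per replicate and build the full count table.

    A :class:`GeneSequence` reference is collapsed to its cDNA, matching the
    coordinate system of diagnostic-SNP positions.
    """
    table = AlleleCountTable()
    ref = (reference.cdna if isinstance(reference, GeneSequence)
           else str(reference))
    ref_len = len(ref)
    for rep, reads in reads_by_replicate.items():
        alns = simple_align_reads(reads, ref, k=k)
        table.add_replicate(rep, count_alleles(
            alns, snps, min_base_quality=min_base_quality, ref_length=ref_len))
    return table


def load_fastq(path: str | Path) -> list:
    return list(SeqIO.parse(str(path), "fastq"))


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------


def fpkm(fragments: int, length_bp: int, total_fragments: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if length_bp <= 0:
        raise ParameterError("transcript length must be positive")
    if total_fragments <= 0:
        raise ParameterError("library size must be positive")
    if fragments < 0:
        raise ParameterError("fragment count must be non-negative")
    return fragments * 1e9 / (length_bp * total_fragments)


@dataclass(frozen=True)
class ExpressionRecord:
    """FPKM expression summary for one gene in one sample."""

    gene_id: str
    sample_id: str
    fragments: int
    length_bp: int
    library_fragments: int

    @property
    def fpkm(self) -> float:
        return fpkm(self.fragments, self.length_bp, self.library_fragments)
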