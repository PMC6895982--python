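"""Sequence variation between parental orthologs and allopolyploid homoeologs.

This module covers the sequence side of a homoeolog-expression study of an
allopolyploid and its two diploid progenitors: global pairwise alignment of
gene copies, SNP/indel calling with exon/intron annotation, coding-effect
classification, identification of species-diagnostic homoeo-SNPs (sites
where the parents carry different fixed alleles and each polyploid homoeolog
matches its own parent), classification of post-polyploidization mutations
as convergent (toward the other parent) or free, and the clone-support
filter used to accept gene copies sequenced from independent PCRs.

All reported coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")

ROLES = ("maternal_parent", "paternal_parent", "polyploid_H", "polyploid_C")


class InputError(ValueError):
    """Invalid user-supplied sequence or parameter."""


class StructureError(ValueError):
    """Gene structure (exons / frame) inconsistent with the sequence."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSequence:
    """A DNA sequence with its role in the polyploid system and exon structure.

    Parameters
    ----------
    id : str
        Sequence identifier (e.g. a GenBank accession).
    role : str
        One of ``maternal_parent``, ``paternal_parent``, ``polyploid_H``,
        ``polyploid_C``.
    seq : str
        DNA over ``{A, C, G, T, N}`` (upper-cased on construction).
    exons : tuple of (start, end)
        1-based inclusive exon intervals, strictly increasing and
        non-overlapping.  An empty tuple means the whole sequence is a
        single exon (e.g. a CDS clone).
    cds_frame : int
        Offset (0..2) of the first codon within the concatenated exons.
    complete_cds : bool
        If true, the concatenated exon length minus ``cds_frame`` must be
        divisible by 3 and coding-effect classification is permitted.
    """

    id: str
    role: str
    seq: str
    exons: tuple[tuple[int, int], ...] = ()
    cds_frame: int = 0
    complete_cds: bool = False

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise InputError(f"{self.id}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise InputError(f"{self.id}: non-DNA characters {sorted(bad)}")
        if self.role not in ROLES:
            raise InputError(f"{self.id}: unknown role {self.role!r}")
        exons = tuple(tuple(iv) for iv in self.exons) or ((1, len(self.seq)),)
        object.__setattr__(self, "exons", exons)
        prev_end = 0
        for start, end in exons:
            if not (1 <= start <= end <= len(self.seq)):
                raise StructureError(f"{self.id}: exon ({start},{end}) out of bounds")
            if start <= prev_end:
                raise StructureError(f"{self.id}: exons overlap or are unsorted")
            prev_end = end
        if not 0 <= self.cds_frame <= 2:
            raise StructureError(f"{self.id}: cds_frame must be 0..2")
        if self.complete_cds and (self.cdna_length - self.cds_frame) % 3:
            raise StructureError(
                f"{self.id}: exonic length {self.cdna_length} minus frame "
                f"{self.cds_frame} not divisible by 3 for a complete CDS"
            )

    # -- coordinate helpers -------------------------------------------------

    @property
    def cdna_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def cdna(self) -> str:
        return "".join(self.seq[s - 1 : e] for s, e in self.exons)

    @property
    def cds(self) -> str:
        return self.cdna[self.cds_frame :]

    def protein(self) -> str:
        """Translate the CDS (standard code), dropping a terminal stop."""
        cds = self.cds
        aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
        return aa[:-1] if aa.endswith("*") else aa

    def genomic_to_cdna(self, pos: int) -> int | None:
        """Map a 1-based genomic position to 1-based cDNA, None if intronic."""
        offset = 0
        for start, end in self.exons:
            if start <= pos <= end:
                return offset + pos - start + 1
            offset += end - start + 1
        return None

    def cdna_to_genomic(self, cdna_pos: int) -> int:
        offset = 0
        for start, end in self.exons:
            length = end - start + 1
            if cdna_pos <= offset + length:
                return start + cdna_pos - offset - 1
            offset += length
        raise StructureError(f"{self.id}: cDNA position {cdna_pos} out of range")

    def region_of(self, pos: int) -> str:
        """Label a genomic position as ``exon k`` or ``intron k`` (1-based k).

        Positions upstream of the first exon are ``intron 0``; positions
        after exon k and before exon k+1 (or downstream of the last) are
        ``intron k``.
        """
        for k, (start, end) in enumerate(self.exons, start=1):
            if pos < start:
                return f"intron {k - 1}"
            if pos <= end:
                return f"exon {k}"
        return f"intron {len(self.exons)}"


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring for global alignment.

    A gap of length L costs ``gap_open + L * gap_extend`` (both negative).
    Defaults are adequate for ~95%-identical orthologs.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


class PairwiseAlignment:
    """A global pairwise alignment with genomic and cDNA coordinate maps.

    ``rows`` are the two gapped sequences (equal length); per-row maps
    translate alignment columns to 1-based genomic positions (None at gaps)
    and, through each :class:`GeneSequence`'s exon structure, to 1-based
    cDNA positions.
    """

    def __init__(self, a: GeneSequence, b: GeneSequence, row_a: str, row_b: str,
                 score: float = 0.0):
        if len(row_a) != len(row_b):
            raise InputError("alignment rows differ in length")
        if row_a.replace("-", "") != a.seq or row_b.replace("-", "") != b.seq:
            raise InputError("alignment rows do not recover the input sequences")
        self.a, self.b = a, b
        self.rows = (row_a, row_b)
        self.score = score
        self.col_to_pos: tuple[list[int | None], list[int | None]] = (
            self._positions(row_a),
            self._positions(row_b),
        )
        self._pos_to_col = (
            {p: c for c, p in enumerate(self.col_to_pos[0]) if p is not None},
            {p: c for c, p in enumerate(self.col_to_pos[1]) if p is not None},
        )

    @staticmethod
    def _positions(row: str) -> list[int | None]:
        out, p = [], 0
        for ch in row:
            if ch == "-":
                out.append(None)
            else:
                p += 1
                out.append(p)
        return out

    def __len__(self) -> int:
        return len(self.rows[0])

    def column_of(self, row: int, pos: int) -> int:
        """Alignment column (0-based) of 1-based position ``pos`` in a row."""
        return self._pos_to_col[row][pos]

    def base_in_other(self, row: int, pos: int) -> str | None:
        """Base of the *other* row at the column of ``pos``; None if gapped."""
        col = self.column_of(row, pos)
        ch = self.rows[1 - row][col]
        return None if ch == "-" else ch

    def cdna_pos(self, row: int, col: int) -> int | None:
        """1-based cDNA position of a column in the given row, if exonic."""
        gpos = self.col_to_pos[row][col]
        if gpos is None:
            return None
        gene = self.a if row == 0 else self.b
        return gene.genomic_to_cdna(gpos)

    def identity(self) -> float:
        same = sum(x == y and x != "-" for x, y in zip(*self.rows))
        return same / len(self)


@dataclass(frozen=True)
class VariantRecord:
    """One SNP or indel between two aligned sequences.

    For indels, ``pos_a``/``pos_b`` anchor to the last aligned base before
    the gap run (left anchoring) and ``alleles`` holds the gapped-out run
    and its length.  ``gapped_row`` names the row carrying the gap
    (``'a'`` means sequence *b* has extra bases relative to *a*).
    """

    column: int
    pos_a: int
    pos_b: int
    kind: str  # "SNP" | "indel"
    alleles: tuple
    region: str
    effect: str = "not_applicable"
    gapped_row: str | None = None


@dataclass(frozen=True)
class DiagnosticSNP:
    """A homoeo-SNP usable to assign reads to a subgenome.

    The parents carry different alleles and each polyploid homoeolog matches
    its own parent.  ``retained`` is False when another called SNP lies
    within the minimum cDNA distance.
    """

    cdna_pos: int
    genomic_pos_maternal: int
    genomic_pos_paternal: int
    maternal_allele: str
    paternal_allele: str
    retained: bool = True


@dataclass(frozen=True)
class HomoeologMutation:
    pos: int  # 1-based on own_parent
    own_base: str
    poly_base: str
    other_base: str | None
    label: str  # "directional" | "nondirectional"
    gap_flag: bool = False


@dataclass(frozen=True)
class MutationClassification:
    """Directional vs non-directional post-polyploidization mutations."""

    mutations: tuple[HomoeologMutation, ...]
    n_directional: int
    n_nondirectional: int

    @property
    def total(self) -> int:
        return self.n_directional + self.n_nondirectional


@dataclass(frozen=True)
class CloneSet:
    """Clones sequenced from one independent PCR experiment."""

    experiment_id: str
    clones: tuple[str, ...]
    threshold: float = 0.25

    def __post_init__(self):
        if not self.clones:
            raise InputError(f"{self.experiment_id}: empty clone set")
        if not 0 < self.threshold <= 1:
            raise InputError(f"{self.experiment_id}: threshold must be in (0,1]")
        object.__setattr__(self, "clones", tuple(c.upper() for c in self.clones))

    def support(self, seq: str) -> float:
        return self.clones.count(seq.upper()) / len(self.clones)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython charges open for the first gap base and extend thereafter;
    # fold our "open + L*extend" convention into that parameterisation.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_pair(a: GeneSequence, b: GeneSequence,
               scoring: Scoring | None = None) -> PairwiseAlignment:
    """Globally align two gene copies with affine gap penalties.

    Deterministic for fixed scoring: among co-optimal alignments the first
    traceback reported by the aligner is used, so repeated calls give
    identical variant coordinates.
    """
    scoring = scoring or Scoring()
    aln = _make_aligner(scoring).align(a.seq, b.seq)[0]
    return PairwiseAlignment(a, b, str(aln[0]), str(aln[1]), score=aln.score)


# ---------------------------------------------------------------------------
# Variant calling and classification
# ---------------------------------------------------------------------------


def call_variants(aln: PairwiseAlignment,
                  gene_a: GeneSequence | None = None,
                  classify: bool = False) -> list[VariantRecord]:
    """Call SNPs and indels from an alignment, annotated on sequence *a*.

    Every mismatching non-gap column yields one SNP; every maximal gap run
    yields a single indel record anchored to the last aligned base before
    the run.  Columns containing N are not called.  Region labels come from
    ``gene_a``'s exon structure (default: the alignment's own sequence *a*).
    With ``classify=True``, exonic SNPs of complete-CDS genes get a
    synonymous / nonsynonymous effect.
    """
    gene_a = gene_a or aln.a
    if len(gene_a.seq) != len(aln.a.seq):
        raise StructureError("gene_a structure does not match aligned sequence a")
    row_a, row_b = aln.rows
    variants: list[VariantRecord] = []
    last_a = last_b = 0
    col = 0
    n = len(aln)
    while col < n:
        ca, cb = row_a[col], row_b[col]
        if ca != "-" and cb != "-":
            pa, pb = aln.col_to_pos[0][col], aln.col_to_pos[1][col]
            if ca != cb and "N" not in (ca, cb):
                variants.append(VariantRecord(
                    column=col, pos_a=pa, pos_b=pb, kind="SNP",
                    alleles=(ca, cb), region=gene_a.region_of(pa)))
            last_a, last_b = pa, pb
            col += 1
        else:
            gap_row = 0 if ca == "-" else 1
            run_start = col
            while col < n and aln.rows[gap_row][col] == "-":
                col += 1
            run = aln.rows[1 - gap_row][run_start:col]
            anchor_a, anchor_b = max(last_a, 1), max(last_b, 1)
            variants.append(VariantRecord(
                column=run_start, pos_a=anchor_a, pos_b=anchor_b,
                kind="indel", alleles=(run, len(run)),
                region=gene_a.region_of(anchor_a),
                gapped_row="a" if gap_row == 0 else "b"))
            # positions inside the run advance only on the ungapped row
            for c in range(run_start, col):
                pa = aln.col_to_pos[0][c]
                pb = aln.col_to_pos[1][c]
                last_a = pa if pa is not None else last_a
                last_b = pb if pb is not None else last_b
    if classify:
        variants = [
            replace(v, effect=classify_coding_effect(v, aln, aln.a, aln.b))
            if v.kind == "SNP" and v.region.startswith("exon")
            and aln.a.complete_cds and aln.b.complete_cds else v
            for v in variants
        ]
    return variants


def classify_coding_effect(v: VariantRecord, aln: PairwiseAlignment,
                           gene_a: GeneSequence, gene_b: GeneSequence) -> str:
    """Classify an exonic SNP as synonymous or nonsynonymous.

    The codon containing the site is translated in each sequence with the
    standard genetic code; the SNP is synonymous iff the amino acids are
    equal.  Codons containing N, falling outside a complete codon, or
    disrupted by an alignment gap return ``not_applicable``.
    """
    if v.kind != "SNP":
        raise InputError("coding effect is defined for SNPs only")
    if not (gene_a.complete_cds and gene_b.complete_cds):
        raise StructureError("coding effect requires complete-CDS genes")
    codons = []
    for gene, row, pos in ((gene_a, 0, v.pos_a), (gene_b, 1, v.pos_b)):
        cdna_pos = gene.genomic_to_cdna(pos)
        if cdna_pos is None or cdna_pos <= gene.cds_frame:
            return "not_applicable"
        idx = (cdna_pos - 1 - gene.cds_frame) // 3
        codon = gene.cds[3 * idx : 3 * idx + 3]
        if len(codon) < 3 or "N" in codon:
            return "not_applicable"
        # an indel through the codon (other row gapped) voids the comparison
        for off in range(3):
            gpos = gene.cdna_to_genomic(gene.cds_frame + 3 * idx + off + 1)
            if aln.rows[1 - row][aln.column_of(row, gpos)] == "-":
                return "not_applicable"
        codons.append(codon)
    aa = [str(Seq(c).translate()) for c in codons]
    return "synonymous" if aa[0] == aa[1] else "nonsynonymous"


def translate_and_diff(a: GeneSequence, b: GeneSequence,
                       aln: PairwiseAlignment | None = None) -> int:
    """Count amino-acid differences between two complete-CDS genes.

    The proteins are compared through the nucleotide alignment: residues
    whose codons co-align are compared directly, and a residue aligned to a
    gap counts as one difference.  An internal stop codon raises a warning
    but the count is still returned.
    """
    if not (a.complete_cds and b.complete_cds):
        raise StructureError("translate_and_diff requires complete-CDS genes")
    aln = aln or align_pair(a, b)
    prot_a, prot_b = a.protein(), b.protein()
    for gene, prot in ((a, prot_a), (b, prot_b)):
        if "*" in prot:
            warnings.warn(f"{gene.id}: internal stop codon in CDS")

    def residue(gene: GeneSequence, cdna_pos: int) -> int | None:
        idx = (cdna_pos - 1 - gene.cds_frame) // 3
        if cdna_pos <= gene.cds_frame or idx >= len(gene.protein()):
            return None
        return idx

    # count codon-position co-alignments between residue indices
    pair_votes: dict[tuple[int, int], int] = {}
    for col in range(len(aln)):
        ca = aln.cdna_pos(0, col)
        cb = aln.cdna_pos(1, col)
        if ca is None or cb is None:
            continue
        ra, rb = residue(a, ca), residue(b, cb)
        if ra is None or rb is None:
            continue
        pair_votes[(ra, rb)] = pair_votes.get((ra, rb), 0) + 1
    # a residue pair is matched when at least two of three codon bases co-align
    matched = {pair for pair, votes in pair_votes.items() if votes >= 2}
    used_a = {ra for ra, _ in matched}
    used_b = {rb for _, rb in matched}
    diffs = sum(prot_a[ra] != prot_b[rb] for ra, rb in matched)
    diffs += len(prot_a) - len(used_a)  # residues of a aligned to gaps
    diffs += len(prot_b) - len(used_b)
    return diffs


# ---------------------------------------------------------------------------
# Diagnostic homoeo-SNPs
# ---------------------------------------------------------------------------


def find_diagnostic_snps(maternal: GeneSequence, paternal: GeneSequence,
                         poly_h: GeneSequence, poly_c: GeneSequence,
                         min_distance: int = 5,
                         scoring: Scoring | None = None) -> list[DiagnosticSNP]:
    """Identify species-diagnostic homoeo-SNPs from the four-sequence quartet.

    A position is diagnostic iff the parents differ, the polyploid H copy
    carries the maternal allele, the polyploid C copy carries the paternal
    allele, and the site is exonic (cDNA-mappable on the maternal
    reference).  The ``retained`` flag is cleared for any diagnostic SNP
    whose nearest neighbouring called SNP lies within ``min_distance`` bp in
    cDNA coordinates (strictly greater distances are retained) — mirroring
    the density filter applied to read-mapping SNP calls.
    """
    aln_mp = align_pair(maternal, paternal, scoring)
    aln_mh = align_pair(maternal, poly_h, scoring)
    aln_mc = align_pair(maternal, poly_c, scoring)
    snps = [v for v in call_variants(aln_mp, maternal) if v.kind == "SNP"]
    exonic = [(v, maternal.genomic_to_cdna(v.pos_a)) for v in snps]
    exonic = [(v, c) for v, c in exonic if c is not None]
    cdna_positions = sorted(c for _, c in exonic)

    out: list[DiagnosticSNP] = []
    for v, cdna_pos in exonic:
        m_allele, p_allele = v.alleles
        h_base = aln_mh.base_in_other(0, v.pos_a)
        c_base = aln_mc.base_in_other(0, v.pos_a)
        if h_base != m_allele or c_base != p_allele:
            continue
        nearest = min((abs(cdna_pos - c) for c in cdna_positions if c != cdna_pos),
                      default=None)
        retained = nearest is None or nearest > min_distance
        out.append(DiagnosticSNP(
            cdna_pos=cdna_pos,
            genomic_pos_maternal=v.pos_a,
            genomic_pos_paternal=v.pos_b,
            maternal_allele=m_allele,
            paternal_allele=p_allele,
            retained=retained))
    return sorted(out, key=lambda d: d.cdna_pos)


def classify_homoeolog_mutations(poly_allele: GeneSequence,
                                 own_parent: GeneSequence,
                                 other_parent: GeneSequence,
                                 scoring: Scoring | None = None,
                                 ) -> MutationClassification:
    """Label each substitution of a polyploid allele vs its own parent.

    A mutation is *directional* (convergent) when the polyploid base equals
    the other parent's allele at the homologous position, else
    *nondirectional*; positions falling in an alignment gap of the other
    parent are nondirectional with a gap flag.  Both pairwise alignments are
    anchored on the own-parent coordinate system.
    """
    aln_po = align_pair(own_parent, poly_allele, scoring)
    aln_oo = align_pair(own_parent, other_parent, scoring)
    muts = []
    n_dir = n_nondir = 0
    for v in call_variants(aln_po, own_parent):
        if v.kind != "SNP":
            continue
        own_base, poly_base = v.alleles
        other_base = aln_oo.base_in_other(0, v.pos_a)
        gap = other_base is None
        if not gap and poly_base == other_base:
            label = "directional"
            n_dir += 1
        else:
            label = "nondirectional"
            n_nondir += 1
        muts.append(HomoeologMutation(
            pos=v.pos_a, own_base=own_base, poly_base=poly_base,
            other_base=other_base, label=label, gap_flag=gap))
    return MutationClassification(tuple(muts), n_dir, n_nondir)


# ---------------------------------------------------------------------------
# Clone-support filter
# ---------------------------------------------------------------------------


def accept_clone_copies(clone_sets: Sequence[CloneSet]) -> list[str]:
    """Accept gene copies supported by enough clones in every experiment.

    A distinct clone sequence is accepted iff its support fraction is at
    least the threshold in *every* independent PCR experiment (a copy absent
    from any experiment has support 0 there and is rejected).  The boundary
    is closed: support exactly equal to the threshold is accepted.
    """
    if not clone_sets:
        return []
    seen: list[str] = []
    for cs in clone_sets:
        for clone in cs.clones:
            if clone not in seen:
                seen.append(clone)
    return [s for s in seen
            if all(cs.support(s) >= cs.threshold for cs in clone_sets)]


# ---------------------------------------------------------------------------
# Quartet accounting
# ---------------------------------------------------------------------------


def summarize_quartet(maternal: GeneSequence, paternal: GeneSequence,
                      poly_h: GeneSequence, poly_c: GeneSequence,
                      min_distance: int = 5,
                      scoring: Scoring | None = None) -> dict:
    """Full sequence-variation accounting for a parental/polyploid quartet.

    Returns SNP/indel totals and their exon/intron split, the coding-effect
    tally, the amino-acid difference count, the diagnostic homoeo-SNP table,
    and the directional/non-directional mutation split of the polyploid H
    allele relative to its maternal parent.
    """
    aln = align_pair(maternal, paternal, scoring)
    classify = maternal.complete_cds and paternal.complete_cds
    variants = call_variants(aln, maternal, classify=classify)
    snps = [v for v in variants if v.kind == "SNP"]
    indels = [v for v in variants if v.kind == "indel"]
    diagnostic = find_diagnostic_snps(maternal, paternal, poly_h, poly_c,
                                      min_distance=min_distance, scoring=scoring)
    h_muts = classify_homoeolog_mutations(poly_h, maternal, paternal, scoring)
    c_muts = classify_homoeolog_mutations(poly_c, paternal, maternal, scoring)
    summary = {
        "n_snps": len(snps),
        "n_indels": len(indels),
        "n_intronic_snps": sum(v.region.startswith("intron") for v in snps),
        "n_intronic_indels": sum(v.region.startswith("intron") for v in indels),
        "n_synonymous": sum(v.effect == "synonymous" for v in snps),
        "n_nonsynonymous": sum(v.effect == "nonsynonymous" for v in snps),
        "aa_differences": translate_and_diff(maternal, paternal, aln)
        if classify else None,
        "diagnostic_snps": diagnostic,
        "h_allele_mutations": h_muts,
        "c_allele_mutations": c_muts,
        "variants": variants,
    }
    return summary


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_gene_structure(path: str | Path) -> dict:
    """Read an exon-structure sidecar: JSON with ``exons`` and ``cds_frame``."""
    data = json.loads(Path(path).read_text())
    exons = tuple(tuple(iv) for iv in data.get("exons", []))
    return {"exons": exons,
            "cds_frame": int(data.get("cds_frame", 0)),
            "complete_cds": bool(data.get("complete_cds", False))}


def read_gene_fasta(path: str | Path,
                    roles: Mapping[str, str] | None = None,
                    structure: Mapping[str, dict] | None = None,
                    ) -> dict[str, GeneSequence]:
    """Read gene copies from FASTA.

    ``roles`` maps record id to role; without it, the role is parsed from
    the record description (a token equal to one of the role names).
    ``structure`` maps record id to a gene-structure dict as returned by
    :func:`load_gene_structure`.
    """
    out: dict[str, GeneSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        role = None
        if roles and rec.id in roles:
            role = roles[rec.id]
        else:
            tokens = rec.description.split()
            role = next((t for t in tokens if t in ROLES), None)
        if role is None:
            raise InputError(f"{rec.id}: no role given or found in description")
        extra = dict(structure.get(rec.id, {})) if structure else {}
        out[rec.id] = GeneSequence(id=rec.id, role=role, seq=str(rec.seq), **extra)
    return out


def write_gene_fasta(genes: Iterable[GeneSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.id} {g.role}\n")
            for i in range(0, len(g.seq), 70):
                fh.write(g.seq[i : i + 70] + "\n")


def variants_to_rows(variants: Iterable[VariantRecord]) -> list[dict]:
    return [
        {"column": v.column, "pos_a": v.pos_a, "pos_b": v.pos_b,
         "kind": v.kind, "allele_a": v.alleles[0], "allele_b": v.alleles[1],
         "region": v.region, "effect": v.effect}
        for v in variants
    ]


def write_variants_tsv(variants: Iterable[VariantRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(variants_to_rows(variants)).to_csv(path, sep="\t", index=False)


def write_variants_vcf(variants: Iterable[VariantRecord], chrom: str,
                       seq_a: str, path: str | Path) -> None:
    """Minimal VCF (SNPs and left-anchored indels vs sequence *a*)."""
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={chrom},length={len(seq_a)}>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for v in variants:
        if v.kind == "SNP":
            ref, alt = v.alleles
            pos = v.pos_a
        else:
            run, _ = v.alleles
            pos = v.pos_a
            anchor = seq_a[pos - 1]
            if v.gapped_row == "a":  # insertion relative to a
                ref, alt = anchor, anchor + run
            else:  # deletion relative to a
                ref, alt = anchor + run, anchor
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def write_diagnostic_tsv(snps: Iterable[DiagnosticSNP], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([
        {"cdna_pos": s.cdna_pos,
         "genomic_pos_maternal": s.genomic_pos_maternal,
         "genomic_pos_paternal": s.genomic_pos_paternal,
         "maternal_allele": s.maternal_allele,
         "paternal_allele": s.paternal_allele,
         "retained": s.retained}
        for s in snps
    ]).to_csv(path, sep="\t", index=False)


def read_diagnostic_tsv(path: str | Path) -> list[DiagnosticSNP]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [DiagnosticSNP(
        cdna_pos=int(r.cdna_pos),
        genomic_pos_maternal=int(r.genomic_pos_maternal),
        genomic_pos_paternal=int(r.genomic_pos_paternal),
        maternal_allele=str(r.maternal_allele),
        paternal_allele=str(r.paternal_allele),
        retained=bool(r.retained)) for r in df.itertuples()]
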