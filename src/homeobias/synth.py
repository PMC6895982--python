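"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates a two-parent allopolyploid system for a single
nuclear gene: a maternal-parent gene with a three-exon / two-intron
structure and complete CDS; a paternal ortholog derived from it by planted
SNPs and intron-restricted indels; the two polyploid homoeolog alleles (the
C allele identical to the paternal parent, the H allele carrying planted
mutations that are either convergent toward the paternal allele or free);
error-bearing single-end cDNA reads drawn from the two homoeologs with a
specified paternal fraction θ; and qPCR Ct / trait-replicate / clone-set
fixtures for the downstream statistics.

Defaults mirror the study regime: an ~850 bp gene with 33 parental SNPs
(8 intronic) and 3 intronic indels, a 12 convergent + 8 free mutation load
on the H allele, exactly two retained diagnostic homoeo-SNPs (all other
exonic parental SNPs are planted in clusters within the 5 bp density filter,
as observed for real read-mapping SNP calls), θ = 0.58 and ~1500 reads per
replicate over 3 replicates.

A single global seed fans out to four independent substreams (parental
sequences, polyploid alleles, reads, tables) so each stage can be
regenerated on its own; identical seed + config gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqvar import CloneSet, GeneSequence, write_gene_fasta

BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitSpec:
    """One measured trait: parental means and the heterosis to plant."""

    name: str
    maternal_mean: float
    paternal_mean: float
    target_mph_percent: float
    noise_sd: float
    units: str = ""

    @property
    def polyploid_mean(self) -> float:
        mid = (self.maternal_mean + self.paternal_mean) / 2
        return mid * (1 + self.target_mph_percent / 100)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic system.

    ``n_snps`` counts all parental SNPs, of which ``n_intronic_snps`` fall in
    introns and ``n_diagnostic`` exonic sites are reserved as retained
    diagnostic homoeo-SNPs; the remaining exonic SNPs are planted in
    clusters tighter than ``min_snp_distance`` so the density filter removes
    them, leaving exactly the reserved sites retained.
    """

    seed: int = 0
    gene_length: int = 850
    exons: tuple[tuple[int, int], ...] = ((1, 171), (301, 552), (641, 850))
    cds_frame: int = 0
    n_snps: int = 33
    n_intronic_snps: int = 8
    n_indels: int = 3
    indel_length_range: tuple[int, int] = (1, 5)
    n_directional: int = 12
    n_nondirectional: int = 8
    n_diagnostic: int = 2
    diagnostic_min_separation: int = 200  # cDNA bp between reserved sites
    min_snp_distance: int = 5  # the read-mapping SNP density filter
    theta_paternal: float = 0.58
    read_length: int = 100
    depth: int = 1500  # expected reads overlapping each diagnostic site
    error_rate: float = 0.005
    n_replicates: int = 3
    base_quality: int = 40
    # fixture tables
    trait_specs: tuple[TraitSpec, ...] = (
        TraitSpec("rubisco_content", 1.41, 1.77, 6.90, 0.05, "ng/g FW"),
        TraitSpec("rubisco_activity", 7.24, 4.76, 14.32, 0.25, "umol/min/g FW"),
    )
    ct_target_baseline: float = 20.0
    ct_condition_effects: tuple[tuple[str, float], ...] = (
        ("maternal", 0.0), ("polyploid", -0.3), ("paternal", 1.2))
    ct_reference_baselines: tuple[float, ...] = (18.0, 21.0)
    ct_noise_sd: float = 0.08
    clone_support: tuple[float, ...] = (0.7, 0.3)
    clones_per_experiment: int = 10
    n_clone_experiments: int = 3

    def __post_init__(self):
        if not 0 <= self.theta_paternal <= 1:
            raise ConfigError("theta_paternal must be in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")
        cdna_len = sum(e - s + 1 for s, e in self.exons)
        if self.read_length > cdna_len:
            raise ConfigError("read length exceeds cDNA length")
        if (cdna_len - self.cds_frame) % 3:
            raise ConfigError("exonic length minus frame must be divisible by 3")
        if self.exons[-1][1] > self.gene_length:
            raise ConfigError("exons exceed gene length")
        n_exonic = self.n_snps - self.n_intronic_snps
        if n_exonic < self.n_diagnostic:
            raise ConfigError("fewer exonic SNPs than requested diagnostic sites")
        if self.n_directional > self.n_snps - self.n_diagnostic:
            raise ConfigError(
                "directional mutations exceed available parental-SNP sites")

    @property
    def cdna_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def reads_per_replicate(self) -> int:
        """Library size per replicate yielding ``depth`` reads over each SNP.

        Read starts are uniform over the valid cDNA positions, so a site away
        from the ends is covered by ``read_length`` of the possible starts;
        ``depth`` is therefore the expected per-SNP count-table total, the
        quantity the study reports per replicate.
        """
        n_starts = self.cdna_length - self.read_length + 1
        return -(-self.depth * n_starts // self.read_length)  # ceil

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)


@dataclass(frozen=True)
class PlantedSNP:
    genomic_pos: int  # on the maternal sequence
    cdna_pos: int | None  # None for intronic sites
    maternal_base: str
    paternal_base: str


@dataclass(frozen=True)
class PlantedIndel:
    anchor_pos: int  # last maternal base before the run (left anchor)
    length: int
    kind: str  # "ins" (extra bases in paternal) | "del" (missing in paternal)
    run: str


@dataclass
class SyntheticTruth:
    """Ground truth of everything the generator planted."""

    snps: tuple[PlantedSNP, ...] = ()
    indels: tuple[PlantedIndel, ...] = ()
    diagnostic: tuple[tuple[int, int], ...] = ()  # (genomic, cdna) reserved sites
    h_mutations: tuple[tuple[int, str], ...] = ()  # (maternal pos, label)
    read_origins: dict = field(default_factory=dict)  # replicate -> tuple of 'H'/'C'

    def realized_paternal_fraction(self, replicate: str) -> float:
        origins = self.read_origins[replicate]
        return sum(o == "C" for o in origins) / len(origins)


def _streams(cfg: SimulationConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


# ---------------------------------------------------------------------------
# Parental pair
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_CODONS[i] for i in body) + "TAA"


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def gen_parental_pair(cfg: SimulationConfig,
                      ) -> tuple[GeneSequence, GeneSequence, SyntheticTruth]:
    """Generate the diverged parental ortholog pair and its planted truth.

    The paternal sequence derives from the maternal one by ``n_snps``
    substitutions and ``n_indels`` intron-restricted indels; exonic SNPs are
    laid out so exactly ``n_diagnostic`` reserved sites survive the SNP
    density filter.  Deterministic per seed.
    """
    rng = _streams(cfg)[0]
    cdna_len = cfg.cdna_length
    cdna = _random_cds(rng, cdna_len // 3)

    # assemble the genomic maternal sequence: exon contents from the CDS,
    # intron contents random
    seq = [""] * cfg.gene_length
    offset = 0
    exon_set = set()
    for s, e in cfg.exons:
        for i, pos in enumerate(range(s, e + 1)):
            seq[pos - 1] = cdna[offset + i]
            exon_set.add(pos)
        offset += e - s + 1
    for pos in range(1, cfg.gene_length + 1):
        if pos not in exon_set:
            seq[pos - 1] = BASES[rng.integers(4)]
    maternal_seq = "".join(seq)

    def cdna_to_genomic(cpos: int) -> int:
        off = 0
        for s, e in cfg.exons:
            if cpos <= off + e - s + 1:
                return s + cpos - off - 1
            off += e - s + 1
        raise ConfigError("cDNA position out of range")

    # --- reserved diagnostic sites (cDNA coordinates) ---
    margin = 30
    sep = cfg.diagnostic_min_separation
    if cfg.n_diagnostic > 0:
        span = cdna_len - 2 * margin - (cfg.n_diagnostic - 1) * sep
        if span <= 0:
            raise ConfigError("cannot fit diagnostic sites with this separation")
        first = int(rng.integers(margin, margin + span))
        diag_cdna = [first + i * sep for i in range(cfg.n_diagnostic)]
    else:
        diag_cdna = []

    taken = set(diag_cdna)

    def far_from_diag(cpos: int) -> bool:
        return all(abs(cpos - d) > cfg.min_snp_distance + 2 for d in diag_cdna)

    # --- clustered non-diagnostic exonic SNPs (fail the density filter) ---
    n_cluster = cfg.n_snps - cfg.n_intronic_snps - cfg.n_diagnostic
    cluster_cdna: list[int] = []
    attempts = 0
    while len(cluster_cdna) < n_cluster:
        attempts += 1
        if attempts > 10000:
            raise ConfigError("could not place clustered exonic SNPs")
        size = 3 if (n_cluster - len(cluster_cdna)) % 2 else 2
        size = min(size, n_cluster - len(cluster_cdna))
        if size == 1:
            size = 2  # a singleton would be retained; extend the cluster
        anchor = int(rng.integers(5, cdna_len - 15))
        positions = [anchor]
        for _ in range(size - 1):
            positions.append(positions[-1] + int(rng.integers(1, cfg.min_snp_distance + 1)))
        if len(set(positions)) != len(positions):
            continue
        if not all(1 <= p <= cdna_len and far_from_diag(p) and p not in taken
                   and all(abs(p - q) > cfg.min_snp_distance + 2 for q in cluster_cdna
                           if q not in positions)
                   for p in positions):
            continue
        # keep clusters clear of each other only enough to avoid collisions
        if any(p in taken for p in positions):
            continue
        cluster_cdna.extend(positions[: n_cluster - len(cluster_cdna)])
        taken.update(positions)

    exonic_cdna = sorted(diag_cdna + cluster_cdna)
    exonic_genomic = {c: cdna_to_genomic(c) for c in exonic_cdna}

    # --- intronic SNPs ---
    intron_positions = [p for s, e in cfg.introns for p in range(s + 3, e - 2)]
    if len(intron_positions) < cfg.n_intronic_snps:
        raise ConfigError("introns too short for requested intronic SNPs")
    intronic = sorted(int(intron_positions[i]) for i in rng.choice(
        len(intron_positions), size=cfg.n_intronic_snps, replace=False))

    # --- indels (introns only, kept clear of SNPs and boundaries) ---
    lo, hi = cfg.indel_length_range
    snp_genomic = set(exonic_genomic.values()) | set(intronic)
    indels: list[PlantedIndel] = []
    occupied: set[int] = set()
    attempts = 0
    while len(indels) < cfg.n_indels:
        attempts += 1
        if attempts > 10000:
            raise ConfigError("could not place indels in introns")
        length = int(rng.integers(lo, hi + 1))
        intron = cfg.introns[int(rng.integers(len(cfg.introns)))]
        s, e = intron
        if e - s + 1 < length + 10:
            continue
        start = int(rng.integers(s + 5, e - length - 4))
        span = set(range(start - 2, start + length + 2))
        if span & snp_genomic or span & occupied:
            continue
        kind = "del" if rng.random() < 0.5 else "ins"
        if kind == "del":
            run = maternal_seq[start - 1 : start - 1 + length]
            # forbid one-step slides so the left anchor is unambiguous:
            # left slide iff base before the run equals its last base,
            # right slide iff its first base equals the base after it
            if maternal_seq[start - 2] == run[-1]:
                continue
            if run[0] == maternal_seq[start - 1 + length]:
                continue
            anchor = start - 1
        else:
            run = "".join(BASES[rng.integers(4)] for _ in range(length))
            if maternal_seq[start - 1] == run[-1] or run[0] == maternal_seq[start]:
                continue
            anchor = start
        indels.append(PlantedIndel(anchor_pos=anchor, length=length,
                                   kind=kind, run=run))
        occupied |= span

    # --- build the paternal sequence ---
    pat = list(maternal_seq)

    def codon_safe_alts(cpos: int) -> list[str]:
        """Alternative bases that keep the paternal codon from becoming a stop."""
        ref = pat[exonic_genomic[cpos] - 1]
        alts = [b for b in "ACGT" if b != ref]
        if cpos <= cfg.cds_frame:
            return alts
        idx = (cpos - 1 - cfg.cds_frame) // 3
        codon_cdna = [cfg.cds_frame + 3 * idx + o + 1 for o in range(3)]
        if codon_cdna[-1] > cdna_len:
            return alts
        safe = []
        for alt in alts:
            codon = "".join(
                alt if cp == cpos else pat[cdna_to_genomic(cp) - 1]
                for cp in codon_cdna)
            if codon not in _STOPS:
                safe.append(alt)
        return safe or alts

    snps: list[PlantedSNP] = []
    for cpos in exonic_cdna:
        g = exonic_genomic[cpos]
        alts = codon_safe_alts(cpos)
        alt = alts[rng.integers(len(alts))]
        snps.append(PlantedSNP(g, cpos, pat[g - 1], alt))
        pat[g - 1] = alt
    for g in intronic:
        alt = _other_base(rng, pat[g - 1])
        snps.append(PlantedSNP(g, None, pat[g - 1], alt))
        pat[g - 1] = alt

    pat_exons = [list(iv) for iv in cfg.exons]
    for indel in sorted(indels, key=lambda x: -x.anchor_pos):
        if indel.kind == "del":
            start = indel.anchor_pos + 1
            del pat[start - 1 : start - 1 + indel.length]
            shift = -indel.length
            boundary = start
        else:
            pat[indel.anchor_pos : indel.anchor_pos] = list(indel.run)
            shift = indel.length
            boundary = indel.anchor_pos
        for iv in pat_exons:
            if iv[0] > boundary:
                iv[0] += shift
                iv[1] += shift

    maternal = GeneSequence(id="synthetic_maternal", role="maternal_parent",
                            seq=maternal_seq, exons=cfg.exons,
                            cds_frame=cfg.cds_frame, complete_cds=True)
    paternal = GeneSequence(id="synthetic_paternal", role="paternal_parent",
                            seq="".join(pat),
                            exons=tuple(tuple(iv) for iv in pat_exons),
                            cds_frame=cfg.cds_frame, complete_cds=True)
    truth = SyntheticTruth(
        snps=tuple(sorted(snps, key=lambda s: s.genomic_pos)),
        indels=tuple(sorted(indels, key=lambda i: i.anchor_pos)),
        diagnostic=tuple((exonic_genomic[c], c) for c in sorted(diag_cdna)))
    return maternal, paternal, truth


# ---------------------------------------------------------------------------
# Polyploid alleles
# ---------------------------------------------------------------------------


def gen_polyploid_alleles(maternal: GeneSequence, paternal: GeneSequence,
                          cfg: SimulationConfig, truth: SyntheticTruth,
                          ) -> tuple[GeneSequence, GeneSequence, SyntheticTruth]:
    """Derive the polyploid H and C alleles from the parental pair.

    The C allele is the paternal sequence verbatim (the observed pattern in
    the study system); the H allele is the maternal sequence plus
    ``n_directional`` convergent mutations (the paternal allele copied in at
    a parental-SNP site) and ``n_nondirectional`` free mutations (a novel
    base at a previously invariant site).  Reserved diagnostic sites are
    never mutated.  Mutation labels are appended to the truth record.
    """
    rng = _streams(cfg)[1]
    diag_genomic = {g for g, _ in truth.diagnostic}
    candidates = [s for s in truth.snps if s.genomic_pos not in diag_genomic]
    if cfg.n_directional > len(candidates):
        raise ConfigError("directional mutations exceed available parental-SNP sites")
    idx = sorted(rng.choice(len(candidates), size=cfg.n_directional, replace=False))
    h_seq = list(maternal.seq)
    labels: list[tuple[int, str]] = []
    for i in idx:
        s = candidates[i]
        h_seq[s.genomic_pos - 1] = s.paternal_base
        labels.append((s.genomic_pos, "directional"))

    snp_positions = {s.genomic_pos for s in truth.snps}
    deleted = {p for ind in truth.indels if ind.kind == "del"
               for p in range(ind.anchor_pos + 1, ind.anchor_pos + 1 + ind.length)}
    blocked = snp_positions | deleted | diag_genomic
    for ind in truth.indels:
        blocked |= set(range(ind.anchor_pos - 1, ind.anchor_pos + ind.length + 2))
    free_sites = [p for p in range(3, len(maternal.seq) - 2) if p not in blocked]
    idx = sorted(rng.choice(len(free_sites), size=cfg.n_nondirectional, replace=False))
    for i in idx:
        pos = free_sites[i]
        h_seq[pos - 1] = _other_base(rng, h_seq[pos - 1])
        labels.append((pos, "nondirectional"))

    poly_h = GeneSequence(id="synthetic_polyploid_H", role="polyploid_H",
                          seq="".join(h_seq), exons=maternal.exons,
                          cds_frame=maternal.cds_frame,
                          complete_cds=maternal.complete_cds)
    poly_c = GeneSequence(id="synthetic_polyploid_C", role="polyploid_C",
                          seq=paternal.seq, exons=paternal.exons,
                          cds_frame=paternal.cds_frame,
                          complete_cds=paternal.complete_cds)
    truth.h_mutations = tuple(sorted(labels))
    return poly_h, poly_c, truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def gen_reads(poly_h: GeneSequence, poly_c: GeneSequence,
              cfg: SimulationConfig, truth: SyntheticTruth | None = None,
              ) -> tuple[dict[str, list[tuple[str, str, list[int]]]], SyntheticTruth]:
    """Simulate single-end cDNA reads from the two homoeolog templates.

    Each read draws its origin from Bernoulli(θ_paternal), its start
    uniformly over valid cDNA positions, and flips each base to a uniformly
    chosen different base with probability ε.  The number of reads per
    replicate is sized so each diagnostic site receives ``cfg.depth``
    overlapping reads in expectation.  Returns per-replicate lists of
    (read id, sequence, phred qualities) plus per-read origin labels in the
    truth record.  Deterministic per seed.
    """
    rng = _streams(cfg)[2]
    truth = truth if truth is not None else SyntheticTruth()
    templates = {"H": poly_h.cdna, "C": poly_c.cdna}
    reads_by_rep: dict[str, list[tuple[str, str, list[int]]]] = {}
    for r in range(1, cfg.n_replicates + 1):
        rep = f"rep{r}"
        reads: list[tuple[str, str, list[int]]] = []
        origins: list[str] = []
        for i in range(cfg.reads_per_replicate):
            origin = "C" if rng.random() < cfg.theta_paternal else "H"
            origins.append(origin)
            template = templates[origin]
            start = int(rng.integers(0, len(template) - cfg.read_length + 1))
            bases = list(template[start : start + cfg.read_length])
            if cfg.error_rate > 0:
                flips = np.nonzero(rng.random(cfg.read_length) < cfg.error_rate)[0]
                for j in flips:
                    bases[j] = _other_base(rng, bases[j])
            reads.append((f"{rep}_read{i}", "".join(bases),
                          [cfg.base_quality] * cfg.read_length))
        reads_by_rep[rep] = reads
        truth.read_origins[rep] = tuple(origins)
    return reads_by_rep, truth


def write_fastq(reads: Sequence[tuple[str, str, Sequence[int]]],
                path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, quals in reads:
            qual_str = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qual_str}\n")


# ---------------------------------------------------------------------------
# Fixture tables
# ---------------------------------------------------------------------------


def gen_tables(cfg: SimulationConfig):
    """Generate qPCR Ct, trait-replicate and clone-set fixtures.

    Ct values are baseline + genotype effect + Gaussian noise; trait
    replicates are Gaussian around genotype means chosen to hit each trait's
    target mid-parent heterosis; clone sets realise the configured support
    fractions.  Returns (ct DataFrame, trait DataFrame, clone sets).
    """
    import pandas as pd

    rng = _streams(cfg)[3]

    ct_rows = []
    for genotype, effect in cfg.ct_condition_effects:
        for r in range(1, cfg.n_replicates + 1):
            row = {"sample": f"{genotype}_{r}", "genotype": genotype,
                   "replicate": r,
                   "target_ct": cfg.ct_target_baseline + effect
                   + rng.normal(0, cfg.ct_noise_sd)}
            for j, ref in enumerate(cfg.ct_reference_baselines, start=1):
                row[f"ref{j}_ct"] = ref + rng.normal(0, cfg.ct_noise_sd)
            ct_rows.append(row)
    ct_df = pd.DataFrame(ct_rows)

    trait_rows = []
    for spec in cfg.trait_specs:
        means = {"maternal": spec.maternal_mean,
                 "polyploid": spec.polyploid_mean,
                 "paternal": spec.paternal_mean}
        for genotype, mean in means.items():
            for r in range(1, cfg.n_replicates + 1):
                trait_rows.append({
                    "trait": spec.name, "genotype": genotype, "replicate": r,
                    "value": mean + rng.normal(0, spec.noise_sd),
                    "units": spec.units})
    trait_df = pd.DataFrame(trait_rows)

    copies = ["".join(BASES[rng.integers(4)] for _ in range(60))
              for _ in cfg.clone_support]
    clone_sets = []
    for e in range(1, cfg.n_clone_experiments + 1):
        clones: list[str] = []
        for seqstr, frac in zip(copies, cfg.clone_support):
            clones.extend([seqstr] * round(frac * cfg.clones_per_experiment))
        clone_sets.append(CloneSet(experiment_id=f"pcr{e}", clones=tuple(clones)))
    return ct_df, trait_df, clone_sets


# ---------------------------------------------------------------------------
# One-call simulation and file output
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    config: SimulationConfig
    maternal: GeneSequence
    paternal: GeneSequence
    poly_h: GeneSequence
    poly_c: GeneSequence
    truth: SyntheticTruth
    reads_by_replicate: dict
    ct_table: "object"
    trait_table: "object"
    clone_sets: list

    @property
    def genes(self) -> tuple[GeneSequence, ...]:
        return (self.maternal, self.paternal, self.poly_h, self.poly_c)


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Run every generator stage with the configured seed."""
    maternal, paternal, truth = gen_parental_pair(cfg)
    poly_h, poly_c, truth = gen_polyploid_alleles(maternal, paternal, cfg, truth)
    reads, truth = gen_reads(poly_h, poly_c, cfg, truth)
    ct_df, trait_df, clone_sets = gen_tables(cfg)
    return SimulationResult(cfg, maternal, paternal, poly_h, poly_c, truth,
                            reads, ct_df, trait_df, clone_sets)


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, structure JSON, FASTQ, fixture TSVs and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / "genes.fasta"
    write_gene_fasta(result.genes, paths["fasta"])

    structure = {g.id: {"exons": [list(iv) for iv in g.exons],
                        "cds_frame": g.cds_frame,
                        "complete_cds": g.complete_cds}
                 for g in result.genes}
    paths["structure"] = outdir / "gene_structure.json"
    paths["structure"].write_text(json.dumps(structure, indent=1))

    for rep, reads in result.reads_by_replicate.items():
        p = outdir / f"reads_{rep}.fastq"
        write_fastq(reads, p)
        paths[f"fastq_{rep}"] = p

    paths["ct"] = outdir / "ct_values.tsv"
    result.ct_table.to_csv(paths["ct"], sep="\t", index=False)
    paths["traits"] = outdir / "traits.tsv"
    result.trait_table.to_csv(paths["traits"], sep="\t", index=False)

    paths["clones"] = outdir / "clones.tsv"
    with open(paths["clones"], "w") as fh:
        fh.write("experiment\tclone_seq\n")
        for cs in result.clone_sets:
            for clone in cs.clones:
                fh.write(f"{cs.experiment_id}\t{clone}\n")

    truth = result.truth
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps({
        "snps": [asdict(s) for s in truth.snps],
        "indels": [asdict(i) for i in truth.indels],
        "diagnostic": [list(d) for d in truth.diagnostic],
        "h_mutations": [list(m) for m in truth.h_mutations],
        "realized_paternal_fraction": {
            rep: truth.realized_paternal_fraction(rep)
            for rep in truth.read_origins},
    }, indent=1))
    return paths
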