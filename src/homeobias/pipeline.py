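"""End-to-end orchestration: sequences → diagnostic SNPs → counts → statistics.

``run_all`` chains the stages on either synthetic data (seeded, fully
reproducible) or user-supplied FASTA/FASTQ/SAM/TSV inputs, writes every
stage table as TSV, renders a Markdown report, and records a run manifest
(config snapshot, input checksums, per-stage status and timings, output
checksums).  Re-running an unchanged config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .seqvar import (read_gene_fasta, summarize_quartet, write_diagnostic_tsv,
                     write_variants_tsv)
from .homeocount import (AlleleCountTable, count_alleles,
                         count_alleles_per_replicate, load_fastq, read_sam)
from .biasstats import (CtRecord, aggregate_bias, ddct_expression,
                        heterosis_from_tidy, heterosis_to_dataframe)
from .synth import SimulationConfig, TraitSpec, simulate, write_simulation

log = logging.getLogger("homeobias")


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StageRecord:
    name: str
    status: str  # "ok" | "skipped" | "failed"
    seconds: float
    outputs: dict = field(default_factory=dict)  # path -> sha256
    message: str = ""


@dataclass
class RunManifest:
    """Provenance record: everything needed to reproduce a run."""

    config: dict
    version: str = __version__
    inputs: dict = field(default_factory=dict)  # path -> sha256
    stages: list = field(default_factory=list)

    def add_stage(self, record: StageRecord) -> None:
        self.stages.append(record)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _build_sim_config(section: dict) -> SimulationConfig:
    section = dict(section)
    if "trait_specs" in section:
        section["trait_specs"] = tuple(
            TraitSpec(**spec) if isinstance(spec, dict) else spec
            for spec in section["trait_specs"])
    if "exons" in section:
        section["exons"] = tuple(tuple(iv) for iv in section["exons"])
    return SimulationConfig(**section)


def run_all(config: dict, outdir: str | Path) -> tuple[RunManifest, Path]:
    """Execute the full analysis described by ``config``.

    ``config["mode"]`` is ``"synthetic"`` (with optional ``synthetic``
    overrides and ``seed``) or ``"files"`` with an ``inputs`` section naming
    FASTA/structure/roles, FASTQ-per-replicate or SAM alignments, and
    optional trait/Ct TSVs.  Returns the manifest and the report path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config)
    mode = config.get("mode", "synthetic")
    min_distance = int(config.get("min_distance", 5))
    min_baseq = int(config.get("min_base_quality", 20))
    report_sections: list[str] = ["# Homoeolog expression analysis report", ""]

    def finish_stage(name: str, t0: float, outputs: dict[str, Path],
                     status: str = "ok", message: str = "") -> None:
        rec = StageRecord(name=name, status=status,
                         seconds=round(time.perf_counter() - t0, 3),
                         outputs={str(p): _sha256(p) for p in outputs.values()},
                         message=message)
        manifest.add_stage(rec)
        if message:
            log.warning("[%s] %s", name, message)
        else:
            log.info("[%s] %s (%.2fs)", name, status, rec.seconds)

    # ----- stage: inputs -------------------------------------------------
    t0 = time.perf_counter()
    reads_by_rep: dict | None = None
    sam_path = None
    trait_df = ct_df = None
    if mode == "synthetic":
        section = dict(config.get("synthetic", {}))
        if "seed" in config:
            section.setdefault("seed", int(config["seed"]))
        sim_cfg = _build_sim_config(section)
        sim = simulate(sim_cfg)
        sim_paths = write_simulation(sim, outdir / "synthetic")
        genes = {g.role: g for g in sim.genes}
        reads_by_rep = sim.reads_by_replicate
        trait_df = sim.trait_table
        ct_df = sim.ct_table
        finish_stage("inputs", t0, sim_paths)
    elif mode == "files":
        inputs = config.get("inputs", {})
        if "fasta" not in inputs:
            raise PipelineError("inputs.fasta is required in files mode")
        fasta = Path(inputs["fasta"])
        if not fasta.exists():
            raise PipelineError(f"input FASTA not found: {fasta}")
        structure = None
        if inputs.get("structure"):
            raw = json.loads(Path(inputs["structure"]).read_text())
            structure = {k: {"exons": tuple(tuple(iv) for iv in v.get("exons", [])),
                             "cds_frame": v.get("cds_frame", 0),
                             "complete_cds": v.get("complete_cds", False)}
                         for k, v in raw.items()}
        by_id = read_gene_fasta(fasta, roles=inputs.get("roles"),
                                structure=structure)
        genes = {g.role: g for g in by_id.values()}
        missing = {"maternal_parent", "paternal_parent",
                   "polyploid_H", "polyploid_C"} - set(genes)
        if missing:
            raise PipelineError(f"FASTA lacks roles: {sorted(missing)}")
        checksums = {str(fasta): _sha256(fasta)}
        if inputs.get("fastq"):
            reads_by_rep = {rep: load_fastq(p)
                            for rep, p in inputs["fastq"].items()}
            checksums.update({str(p): _sha256(Path(p))
                              for p in inputs["fastq"].values()})
        if inputs.get("sam"):
            sam_path = Path(inputs["sam"])
            checksums[str(sam_path)] = _sha256(sam_path)
        if inputs.get("traits"):
            trait_df = pd.read_csv(inputs["traits"], sep="\t")
            checksums[str(inputs["traits"])] = _sha256(Path(inputs["traits"]))
        if inputs.get("ct"):
            ct_df = pd.read_csv(inputs["ct"], sep="\t")
            checksums[str(inputs["ct"])] = _sha256(Path(inputs["ct"]))
        manifest.inputs = checksums
        finish_stage("inputs", t0, {})
    else:
        raise PipelineError(f"unknown mode {mode!r}")

    maternal = genes["maternal_parent"]
    paternal = genes["paternal_parent"]
    poly_h = genes["polyploid_H"]
    poly_c = genes["polyploid_C"]

    # ----- stage: seqvar -------------------------------------------------
    t0 = time.perf_counter()
    summary = summarize_quartet(maternal, paternal, poly_h, poly_c,
                                min_distance=min_distance)
    variants_path = outdir / "variants.tsv"
    write_variants_tsv(summary["variants"], variants_path)
    diag_path = outdir / "diagnostic_snps.tsv"
    write_diagnostic_tsv(summary["diagnostic_snps"], diag_path)
    finish_stage("seqvar", t0, {"variants": variants_path, "diagnostic": diag_path})

    h_muts = summary["h_allele_mutations"]
    report_sections += [
        "## Sequence variation", "",
        f"- parental SNPs: {summary['n_snps']} "
        f"({summary['n_intronic_snps']} intronic); "
        f"indels: {summary['n_indels']} ({summary['n_intronic_indels']} intronic)",
        f"- coding effects: {summary['n_synonymous']} synonymous, "
        f"{summary['n_nonsynonymous']} nonsynonymous; "
        f"amino-acid differences: {summary['aa_differences']}",
        f"- polyploid H-allele mutations: {h_muts.n_directional} directional, "
        f"{h_muts.n_nondirectional} nondirectional",
        "- retained diagnostic homoeo-SNPs (cDNA): "
        + ", ".join(str(d.cdna_pos) for d in summary["diagnostic_snps"]
                    if d.retained),
        "",
    ]

    retained = [d for d in summary["diagnostic_snps"] if d.retained]

    # ----- stage: homeocount --------------------------------------------
    t0 = time.perf_counter()
    count_table = None
    count_outputs: dict[str, Path] = {}
    if reads_by_rep is not None or sam_path is not None:
        if sam_path is not None:
            alns = read_sam(sam_path)
            per_snp = count_alleles(alns, retained, min_base_quality=min_baseq,
                                    ref_length=maternal.cdna_length)
            count_table = AlleleCountTable()
            count_table.add_replicate("sam", per_snp)
        else:
            count_table = count_alleles_per_replicate(
                reads_by_rep, maternal, retained, min_base_quality=min_baseq)
        counts_path = outdir / "allele_counts.tsv"
        count_table.to_tsv(counts_path)
        count_outputs["counts"] = counts_path
        finish_stage("homeocount", t0, count_outputs)
        df = count_table.to_dataframe()
        report_sections += ["## Homoeolog read counts", "", "```",
                            df.to_string(index=False) if not df.empty
                            else "(no reads)", "```", ""]
    else:
        finish_stage("homeocount", t0, {}, status="skipped",
                     message="no reads supplied")

    # ----- stage: biasstats ---------------------------------------------
    t0 = time.perf_counter()
    bias_outputs: dict[str, Path] = {}
    status, message = "ok", ""
    if count_table is not None:
        total = sum(count_table.pooled(rep).total
                    for rep in count_table.replicates)
        if total == 0:
            status, message = "skipped", "count table empty; bias test skipped"
        else:
            bias_df = aggregate_bias(count_table)
            bias_path = outdir / "bias_tests.tsv"
            bias_df.to_csv(bias_path, sep="\t", index=False)
            bias_outputs["bias"] = bias_path
            report_sections += ["## Subgenome bias tests", "", "```",
                                bias_df.to_string(index=False), "```", ""]
            theta = count_table.paternal_fraction()
            report_sections += [f"Pooled paternal read fraction: {theta:.4f}", ""]
    if ct_df is not None and not ct_df.empty:
        ref_cols = [c for c in ct_df.columns
                    if c.startswith("ref") and c.endswith("_ct")]

        def _record(row) -> CtRecord:
            return CtRecord(sample_id=str(row["sample"]),
                            target_ct=float(row["target_ct"]),
                            reference_cts={c: float(row[c]) for c in ref_cols})

        calibrator = _record(ct_df.iloc[0])
        ddct_df = pd.DataFrame([
            {"sample": row["sample"], "calibrator": calibrator.sample_id,
             "relative_expression": ddct_expression(_record(row), calibrator)}
            for _, row in ct_df.iterrows()])
        ddct_path = outdir / "relative_expression.tsv"
        ddct_df.to_csv(ddct_path, sep="\t", index=False)
        bias_outputs["ddct"] = ddct_path
    if trait_df is not None:
        results = heterosis_from_tidy(trait_df)
        het_df = heterosis_to_dataframe(results)
        het_path = outdir / "heterosis.tsv"
        het_df.to_csv(het_path, sep="\t", index=False)
        bias_outputs["heterosis"] = het_path
        report_sections += ["## Mid-parent heterosis", "", "```",
                            het_df.to_string(index=False), "```", ""]
    finish_stage("biasstats", t0, bias_outputs, status=status, message=message)

    # ----- report + manifest --------------------------------------------
    report_path = outdir / "report.md"
    report_path.write_text("\n".join(report_sections))
    manifest.add_stage(StageRecord(
        name="report", status="ok", seconds=0.0,
        outputs={str(report_path): _sha256(report_path)}))
    manifest.write(outdir / "manifest.json")
    return manifest, report_path
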