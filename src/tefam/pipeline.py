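"""End-to-end orchestration: simulate → scan → enrich → chimera → synteny.

One global seed feeds fixed per-stage offsets, so a (config, seed) pair
reproduces the whole run; the JSON report aggregates each stage's
parameters, outputs and — in simulation mode — comparisons against the
planted truth table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from tefam import io as tio
from tefam.chimera import (
    ColumnAlignment,
    bootstrap_support,
    find_signature_stretches,
    infer_parents,
)
from tefam.enrichment import enrichment_test, permutation_null
from tefam.records import GeneRecord, TERecord
from tefam.scan import calibrate_min_score, reciprocal_validate, scan_genome
from tefam.simulate import config_from_dict, simulate_genomes
from tefam.synteny import block_span, identity_matrix

logger = logging.getLogger("tefam")

# fixed per-stage seed offsets, keeping every derived seed below 2**31
_STAGE_SEED = {"simulate": 11, "scan": 23, "enrich": 37, "chimera": 53}


class ConfigurationError(ValueError):
    """The run configuration is inconsistent (caught before any stage runs)."""


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {
        "simulate": True, "scan": True, "enrich": True,
        "chimera": True, "synteny": True})
    sim: dict[str, Any] = field(default_factory=dict)
    scan: dict[str, Any] = field(default_factory=dict)
    enrich: dict[str, Any] = field(default_factory=dict)
    chimera: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def validate(self) -> None:
        on = {k for k, v in self.stages.items() if v}
        if "scan" in on and not self.stages.get("simulate") \
                and "genome_fasta" not in self.inputs:
            raise ConfigurationError("scan enabled without simulate needs inputs.genome_fasta")
        if "scan" in on and not self.stages.get("simulate") \
                and "library_fasta" not in self.inputs:
            raise ConfigurationError("scan enabled without simulate needs inputs.library_fasta")
        if "enrich" in on and not self.stages.get("simulate") \
                and "genes_gff" not in self.inputs:
            raise ConfigurationError("enrich enabled without simulate needs inputs.genes_gff")
        if "enrich" in on and not self.stages.get("scan") \
                and not self.stages.get("simulate") and "tes_bed" not in self.inputs:
            raise ConfigurationError(
                "enrich enabled without a scan stage or simulated TEs needs inputs.tes_bed")
        if "chimera" in on and not self.stages.get("simulate") \
                and "aln_fasta" not in self.inputs:
            raise ConfigurationError("chimera enabled without simulate needs inputs.aln_fasta")
        for key in ("genome_fasta", "library_fasta", "genes_gff", "tes_bed", "aln_fasta"):
            if key in self.inputs and not Path(self.inputs[key]).exists():
                raise ConfigurationError(f"inputs.{key} does not exist: {self.inputs[key]}")
        if self.stages.get("simulate"):
            try:
                config_from_dict({**self.sim, "seed": 0}).validate()
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(f"invalid sim config: {exc}") from exc


def _derived_seed(seed: int, stage: str) -> int:
    return (seed * 1000003 + _STAGE_SEED[stage]) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order and write
    ``report.json`` into the output directory."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}}

    sim_result = None
    genomes_seqs: dict[str, dict[str, str]] = {}
    library = None
    genes: list[GeneRecord] = []
    tes: list[TERecord] = []

    if config.stages.get("simulate"):
        t0 = time.monotonic()
        sim_cfg = config_from_dict({**config.sim,
                                    "seed": _derived_seed(config.seed, "simulate")})
        logger.info("simulate: %d species, contig %d bp", sim_cfg.n_species,
                    sim_cfg.contig_length)
        sim_result = simulate_genomes(sim_cfg)
        paths = tio.write_simulation(sim_result, out / "sim")
        genomes_seqs = {s: g.sequences for s, g in sim_result.genomes.items()}
        library = [sim_result.consensus]
        genes = sim_result.truth.genes
        report["stages"]["simulate"] = {
            "seed": sim_cfg.seed,
            "n_genes": len(sim_result.truth.genes),
            "n_tes": len(sim_result.truth.tes),
            "n_species": sim_cfg.n_species,
            "outputs": paths,
            "wall_time_s": round(time.monotonic() - t0, 3),
        }
    else:
        if "genome_fasta" in config.inputs:
            genomes_seqs = {"genome": tio.read_fasta(config.inputs["genome_fasta"])}
        if "library_fasta" in config.inputs:
            library = tio.read_repeat_library(config.inputs["library_fasta"])
        if "genes_gff" in config.inputs:
            genes, gff_tes = tio.read_gff3(config.inputs["genes_gff"])
            tes.extend(gff_tes)
        if "tes_bed" in config.inputs:
            tes.extend(tio.read_bed_tes(config.inputs["tes_bed"]))

    if config.stages.get("scan"):
        t0 = time.monotonic()
        sc = dict(config.scan)
        min_score = sc.get("min_score")
        merged_seqs: dict[str, str] = {}
        for seqs in genomes_seqs.values():
            merged_seqs.update(seqs)
        if min_score is None:
            min_score = calibrate_min_score(
                merged_seqs, library,
                n_shuffles=int(sc.get("n_shuffles", 10)),
                quantile=float(sc.get("quantile", 0.999)),
                seed=_derived_seed(config.seed, "scan"))
            logger.info("scan: calibrated min_score=%.1f", min_score)
        hits = scan_genome(merged_seqs, library, min_score=float(min_score),
                           min_fragment_bp=int(sc.get("min_fragment_bp", 30)),
                           max_gap_bp=int(sc.get("max_gap_bp", 1000)))
        hits = [reciprocal_validate(h, merged_seqs, library) for h in hits]
        hits = [h for h in hits if h.reciprocal_valid]
        tio.write_bed(hits, out / "remnant_hits.bed")
        tio.write_hits_tsv(hits, out / "remnant_hits.tsv")
        stage = {"min_score": float(min_score), "n_hits": len(hits),
                 "outputs": {"bed": str(out / "remnant_hits.bed"),
                             "tsv": str(out / "remnant_hits.tsv")},
                 "wall_time_s": round(time.monotonic() - t0, 3)}
        if sim_result is not None:
            recall, precision = hit_recovery(hits, sim_result.truth.tes)
            stage["truth_comparison"] = {"recall": round(recall, 4),
                                         "precision": round(precision, 4),
                                         "n_planted": len(sim_result.truth.tes)}
        report["stages"]["scan"] = stage
        tes = list(hits)
    elif sim_result is not None and not tes:
        tes = sim_result.truth.tes

    if config.stages.get("enrich"):
        t0 = time.monotonic()
        en = dict(config.enrich)
        contig_lengths = None
        if genomes_seqs:
            contig_lengths = {c: len(s) for seqs in genomes_seqs.values()
                              for c, s in seqs.items()}
        w = int(en.get("w", 3000))
        result, table = enrichment_test(
            genes, tes, w=w, null_mode=en.get("null_mode", "per-gene-rate"),
            contig_lengths=contig_lengths,
            include_body=bool(en.get("include_body", True)),
            excluded_contigs=en.get("excluded_contigs", ()))
        perm = permutation_null(
            genes, tes, w=w, n_perm=int(en.get("n_perm", 1000)),
            seed=_derived_seed(config.seed, "enrich"),
            contig_lengths=contig_lengths,
            include_body=bool(en.get("include_body", True)),
            excluded_contigs=en.get("excluded_contigs", ()))
        result.permutation_p = perm["permutation_p"]
        table.to_csv(out / "gene_te_table.tsv", sep="\t", index=False)
        (out / "enrichment.json").write_text(
            json.dumps(result.to_dict(), indent=2) + "\n")
        report["stages"]["enrich"] = {
            **result.to_dict(), "permutation": perm,
            "wall_time_s": round(time.monotonic() - t0, 3)}

    if config.stages.get("chimera"):
        t0 = time.monotonic()
        ch = dict(config.chimera)
        stage: dict[str, Any] = {}
        if sim_result is not None and sim_result.truth.chimera is not None:
            truth_ch = sim_result.truth.chimera
            species = next(s for s, g in sim_result.genomes.items()
                           if any(x.is_chimera for x in g.genes))
            genome = sim_result.genomes[species]
            chim_seq = genome.gene_sequence(truth_ch.gene_id)
            fam_orf = next(g.family_id for g in genome.genes
                           if g.id == truth_ch.parent_orf_id)
            fam_prom = next(g.family_id for g in genome.genes
                            if g.id == truth_ch.parent_promoter_id)
            candidates = {g.id: genome.gene_sequence(g.id) for g in genome.genes
                          if g.family_id in (fam_orf, fam_prom) and not g.is_chimera}
            call = infer_parents(chim_seq, candidates)
            lengths = {len(s) for s in candidates.values()} | {len(chim_seq)}
            aln = None
            if len(lengths) == 1:
                ids = [truth_ch.gene_id] + sorted(candidates)
                rows = [chim_seq] + [candidates[i] for i in sorted(candidates)]
                aln = ColumnAlignment(ids, rows, truth_ch.gene_id, sorted(candidates))
        else:
            aln = ColumnAlignment.from_fasta(
                config.inputs["aln_fasta"], config.inputs.get("chimera_id"),
                (config.inputs.get("parent_ids") or "").split(",") or None)
            gapless = {i: aln.row(i).replace("-", "") for i in aln.parent_ids}
            call = infer_parents(aln.row(aln.chimera_id).replace("-", ""), gapless)
        stage["fusion_call"] = call.to_dict()
        if aln is not None:
            tree = bootstrap_support(aln, n_iter=int(ch.get("boot", 500)),
                                     collapse=float(ch.get("collapse", 50.0)),
                                     seed=_derived_seed(config.seed, "chimera"))
            newick = tree.to_newick()
            (out / "chimera_tree.nwk").write_text(newick + "\n")
            stretches = find_signature_stretches(
                aln, min_len_bp=int(ch.get("min_len_bp", 10)),
                max_mismatch=int(ch.get("max_mismatch", 0)))
            stage["tree_newick"] = newick
            stage["n_signature_stretches"] = len(stretches)
            stage["signature_stretches"] = [
                {"span": list(s.span), "parents": sorted(s.supporting_parents),
                 "identity": round(s.identity, 2), "length_bp": s.length_bp}
                for s in stretches]
        if sim_result is not None and sim_result.truth.chimera is not None:
            truth_ch = sim_result.truth.chimera
            stage["truth_comparison"] = {
                "true_breakpoint": truth_ch.true_breakpoint,
                "breakpoint_error": abs(call.breakpoint - truth_ch.true_breakpoint),
                "parents_match": call.promoter_parent == truth_ch.parent_promoter_id
                and call.orf_parent == truth_ch.parent_orf_id,
            }
        (out / "fusion_call.json").write_text(
            json.dumps(stage["fusion_call"], indent=2) + "\n")
        stage["wall_time_s"] = round(time.monotonic() - t0, 3)
        report["stages"]["chimera"] = stage

    if config.stages.get("synteny") and sim_result is not None:
        t0 = time.monotonic()
        blocks = []
        for species, genome in sim_result.genomes.items():
            for contig in genome.sequences:
                cg = [g for g in genome.genes if g.contig == contig]
                if not cg:
                    continue
                start1 = min(g.start for g in cg) + 1
                end1 = max(g.end for g in cg)
                span, label = block_span(start1, end1)
                blocks.append({"species": species, "contig": contig,
                               "start": start1, "end": end1,
                               "span_bp": span, "label": label})
        # ortholog identity is measured on a background anchor gene, which
        # diverges between species only at the interspecific rate; paralog
        # family members additionally carry per-species paralog divergence
        anchor_fam = next((g.family_id for g in sim_result.truth.genes
                           if not g.is_paralog), None)
        ortho = {}
        if anchor_fam is not None:
            for species, genome in sim_result.genomes.items():
                for g in genome.genes:
                    if g.family_id == anchor_fam:
                        ortho[g.id] = genome.gene_sequence(g.id)
                        break
        stage = {"blocks": blocks, "wall_time_s": None}
        if len(ortho) >= 2:
            mat = identity_matrix(ortho)
            vals = [mat.iloc[i, j] for i in range(len(mat))
                    for j in range(i + 1, len(mat))]
            stage["ortholog_identity_mean"] = round(float(np.mean(vals)), 2)
        stage["wall_time_s"] = round(time.monotonic() - t0, 3)
        report["stages"]["synteny"] = stage

    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def small_run_config(outdir: str, seed: int = 0) -> RunConfig:
    """The packaged small end-to-end configuration: two 70 kb species, four
    paralog families, a planted chimera, calibrated scan threshold, 200
    permutations and 100 bootstrap iterations. Runs every stage in seconds
    on one CPU while exercising the full simulate → scan → enrich →
    chimera → synteny path."""
    return RunConfig(
        outdir=outdir, seed=seed,
        sim={"n_species": 2, "contig_length": 70_000, "n_background_genes": 8,
             "n_paralog_families": 4, "genes_per_family": [2, 3],
             "chimera": {"postfusion_rate": 0.02}},
        scan={"n_shuffles": 5},
        enrich={"n_perm": 200},
        chimera={"boot": 100})


def hit_recovery(hits, truth_tes, min_overlap_frac: float = 0.3) -> tuple[float, float]:
    """Recall and precision of scan hits against planted TE intervals.

    A planted TE is recovered if some hit on the same contig overlaps it by
    at least ``min_overlap_frac`` of the TE's length; a hit is a true
    positive if it overlaps any planted TE that way.
    """
    def frac(a, b):
        ov = min(a[1], b[1]) - max(a[0], b[0])
        return max(0, ov) / (b[1] - b[0])

    recovered = 0
    for t in truth_tes:
        if any(h.contig == t.contig and frac((h.start, h.end), (t.start, t.end))
               >= min_overlap_frac for h in hits):
            recovered += 1
    tp = 0
    for h in hits:
        if any(h.contig == t.contig and frac((h.start, h.end), (t.start, t.end))
               >= min_overlap_frac for t in truth_tes):
            tp += 1
    recall = recovered / len(truth_tes) if truth_tes else 0.0
    precision = tp / len(hits) if hits else 0.0
    return recall, precision
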