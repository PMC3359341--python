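"""File-format boundary: FASTA, GFF3, BED6, TSV tables.

Internal coordinates are 0-based half-open; GFF3 is written/read 1-based
inclusive and BED6 0-based half-open, converted here and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tefam.records import (
    AnnotatedGenome,
    ChimeraRecord,
    ConsensusRepeat,
    GeneRecord,
    RemnantHit,
    TERecord,
    TruthTable,
)


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_repeat_library(path: str | Path) -> list[ConsensusRepeat]:
    return [ConsensusRepeat(name, seq) for name, seq in read_fasta(path).items()]


# ---------------------------------------------------------------- GFF3

def _gff_attrs(pairs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs.items())


def write_gff3(genes: Iterable[GeneRecord], tes: Iterable[TERecord],
               path: str | Path, source: str = "tefam") -> None:
    """Genes as ``gene`` features, TE remnants as ``transposable_element``;
    family membership and chimera/paralog flags live in column 9."""
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = {"ID": g.id, "family_id": g.family_id or ".",
                 "is_paralog": str(int(g.is_paralog)),
                 "is_chimera": str(int(g.is_chimera))}
        lines.append("\t".join([g.contig, source, "gene", str(g.start + 1), str(g.end),
                                ".", g.strand, ".", _gff_attrs(attrs)]))
    for t in tes:
        attrs = {"ID": t.id, "source_consensus": t.source_consensus,
                 "near_gene": t.planted_near_gene_id or "."}
        lines.append("\t".join([t.contig, source, "transposable_element",
                                str(t.start + 1), str(t.end), ".", t.strand, ".",
                                _gff_attrs(attrs)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> tuple[list[GeneRecord], list[TERecord]]:
    genes: list[GeneRecord] = []
    tes: list[TERecord] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        contig, _src, ftype, start, end, _score, strand, _phase, attr_str = f
        attrs = dict(kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv)
        start0, end0 = int(start) - 1, int(end)
        strand = strand if strand in "+-" else "+"
        if ftype == "gene":
            fam = attrs.get("family_id")
            genes.append(GeneRecord(attrs.get("ID", f"{contig}:{start}"), contig,
                                    start0, end0, strand,
                                    None if fam in (None, ".") else fam,
                                    attrs.get("is_paralog", "0") == "1",
                                    attrs.get("is_chimera", "0") == "1"))
        elif ftype in ("transposable_element", "repeat_region", "dispersed_repeat"):
            near = attrs.get("near_gene")
            tes.append(TERecord(attrs.get("ID", f"{contig}:{start}"), contig,
                                start0, end0, strand,
                                attrs.get("source_consensus", "."),
                                planted_near_gene_id=None if near in (None, ".") else near))
    return genes, tes


# ---------------------------------------------------------------- BED6

def write_bed(hits: Iterable[RemnantHit], path: str | Path) -> None:
    """BED6: score column carries the alignment score, name the consensus."""
    lines = []
    for h in hits:
        lines.append("\t".join([h.contig, str(h.start), str(h.end), h.consensus,
                                str(int(round(h.score))), h.strand]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed_tes(path: str | Path) -> list[TERecord]:
    tes = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        name = f[3] if len(f) > 3 else f"te{i}"
        strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
        tes.append(TERecord(f"te{i}", f[0], int(f[1]), int(f[2]), strand, name))
    return tes


# ---------------------------------------------------------------- TSV tables

def hits_to_frame(hits: Iterable[RemnantHit]) -> pd.DataFrame:
    rows = [{
        "contig": h.contig, "start": h.start, "end": h.end, "strand": h.strand,
        "consensus": h.consensus, "consensus_start": h.consensus_start,
        "consensus_end": h.consensus_end, "score": h.score,
        "identity": round(h.identity, 2),
        "fragments": ",".join(h.fragment_ids) or ".",
        "reciprocal_valid": "." if h.reciprocal_valid is None else str(h.reciprocal_valid),
    } for h in hits]
    return pd.DataFrame(rows, columns=["contig", "start", "end", "strand", "consensus",
                                       "consensus_start", "consensus_end", "score",
                                       "identity", "fragments", "reciprocal_valid"])


def write_hits_tsv(hits: Iterable[RemnantHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


TRUTH_GENE_COLUMNS = ["id", "species_contig", "start", "end", "strand",
                      "family_id", "is_paralog", "is_chimera"]
TRUTH_TE_COLUMNS = ["id", "species_contig", "start", "end", "strand",
                    "source_consensus", "decay_applied", "truncation_applied",
                    "planted_near_gene_id"]


def write_truth(truth: TruthTable, genes_path: str | Path, tes_path: str | Path,
                chimera_path: Optional[str | Path] = None) -> None:
    gdf = pd.DataFrame([{
        "id": g.id, "species_contig": g.contig, "start": g.start, "end": g.end,
        "strand": g.strand, "family_id": g.family_id or ".",
        "is_paralog": int(g.is_paralog), "is_chimera": int(g.is_chimera),
    } for g in truth.genes], columns=TRUTH_GENE_COLUMNS)
    gdf.to_csv(genes_path, sep="\t", index=False)
    tdf = pd.DataFrame([{
        "id": t.id, "species_contig": t.contig, "start": t.start, "end": t.end,
        "strand": t.strand, "source_consensus": t.source_consensus,
        "decay_applied": t.decay_applied, "truncation_applied": round(t.truncation_applied, 4),
        "planted_near_gene_id": t.planted_near_gene_id or ".",
    } for t in truth.tes], columns=TRUTH_TE_COLUMNS)
    tdf.to_csv(tes_path, sep="\t", index=False)
    if chimera_path is not None and truth.chimera is not None:
        Path(chimera_path).write_text(json.dumps({
            "gene_id": truth.chimera.gene_id,
            "parent_promoter_id": truth.chimera.parent_promoter_id,
            "parent_orf_id": truth.chimera.parent_orf_id,
            "true_breakpoint": truth.chimera.true_breakpoint,
        }, indent=2) + "\n")


def read_truth(genes_path: str | Path, tes_path: str | Path,
               chimera_path: Optional[str | Path] = None) -> TruthTable:
    gdf = pd.read_csv(genes_path, sep="\t")
    tdf = pd.read_csv(tes_path, sep="\t")
    truth = TruthTable()
    for _, r in gdf.iterrows():
        fam = None if r["family_id"] == "." else r["family_id"]
        truth.genes.append(GeneRecord(r["id"], r["species_contig"], int(r["start"]),
                                      int(r["end"]), r["strand"], fam,
                                      bool(r["is_paralog"]), bool(r["is_chimera"])))
    for _, r in tdf.iterrows():
        near = None if r["planted_near_gene_id"] == "." else r["planted_near_gene_id"]
        truth.tes.append(TERecord(r["id"], r["species_contig"], int(r["start"]),
                                  int(r["end"]), r["strand"], r["source_consensus"],
                                  float(r["decay_applied"]),
                                  float(r["truncation_applied"]), near))
    if chimera_path is not None and Path(chimera_path).exists():
        d = json.loads(Path(chimera_path).read_text())
        truth.chimera = ChimeraRecord(d["gene_id"], d["parent_promoter_id"],
                                      d["parent_orf_id"], int(d["true_breakpoint"]))
    return truth


def read_paralog_table(path: str | Path) -> dict[str, str]:
    """TSV with columns gene_id, family_id → mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "family_id"} <= set(df.columns):
        raise ValueError("paralog table needs columns gene_id, family_id")
    return dict(zip(df["gene_id"].astype(str), df["family_id"].astype(str)))


# ---------------------------------------------------------------- bundles

def write_simulation(result, outdir: str | Path) -> dict[str, str]:
    """Write a full simulation: per-species FASTA + GFF3, consensus FASTA,
    truth tables, and the config. Returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for species, genome in result.genomes.items():
        fa = out / f"{species}.fasta"
        gff = out / f"{species}.gff3"
        write_fasta(genome.sequences, fa)
        write_gff3(genome.genes, genome.tes, gff)
        paths[f"fasta_{species}"] = str(fa)
        paths[f"gff3_{species}"] = str(gff)
    cfa = out / "te_consensus.fasta"
    write_fasta({result.consensus.name: result.consensus.sequence}, cfa)
    paths["consensus"] = str(cfa)
    gt, tt, ct = out / "truth_genes.tsv", out / "truth_tes.tsv", out / "truth_chimera.json"
    write_truth(result.truth, gt, tt, ct)
    paths.update(truth_genes=str(gt), truth_tes=str(tt))
    if result.truth.chimera is not None:
        paths["truth_chimera"] = str(ct)
    from tefam.simulate import config_to_dict
    cfg = out / "sim_config.json"
    cfg.write_text(json.dumps(config_to_dict(result.config), indent=2) + "\n")
    paths["config"] = str(cfg)
    return paths
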