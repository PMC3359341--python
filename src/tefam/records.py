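"""Shared domain records.

All internal coordinates are 0-based half-open on a per-contig axis.
Conversion to 1-based inclusive (GFF3) or 0-based half-open (BED) happens
only at the I/O boundary (see :mod:`tefam.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass
class GeneRecord:
    """A gene feature on a contig, with family membership flags."""

    id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    family_id: Optional[str] = None
    is_paralog: bool = False
    is_chimera: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.id}: invalid span [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TERecord:
    """A planted (truth-table) TE remnant."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    source_consensus: str
    decay_applied: float = 0.0
    truncation_applied: float = 0.0  # fraction of the consensus removed
    planted_near_gene_id: Optional[str] = None


@dataclass
class ChimeraRecord:
    """Truth record for the planted chimeric gene."""

    gene_id: str
    parent_promoter_id: str
    parent_orf_id: str
    true_breakpoint: int  # chimera coordinate: prefix length from the promoter donor


@dataclass
class TruthTable:
    """Ground truth emitted by the simulator for parameter-recovery tests."""

    genes: list[GeneRecord] = field(default_factory=list)
    tes: list[TERecord] = field(default_factory=list)
    chimera: Optional[ChimeraRecord] = None


@dataclass
class AnnotatedGenome:
    """One species' sequences plus gene and TE annotations."""

    species: str
    sequences: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)
    tes: list[TERecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.contig not in self.sequences:
                raise ValueError(f"gene {g.id} on unknown contig {g.contig}")
            if g.end > len(self.sequences[g.contig]):
                raise ValueError(f"gene {g.id} extends past contig {g.contig}")

    def gene_sequence(self, gene_id: str) -> str:
        for g in self.genes:
            if g.id == gene_id:
                seq = self.sequences[g.contig][g.start : g.end]
                return seq if g.strand == "+" else revcomp(seq)
        raise KeyError(gene_id)


@dataclass
class ConsensusRepeat:
    """A TE consensus sequence, optionally with labelled sub-regions.

    ``annotated_regions`` maps a label (e.g. "5p_TIR", "core", "3p_stem_loop")
    to a half-open span within the consensus.
    """

    name: str
    sequence: str
    annotated_regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"consensus {self.name}: empty sequence")
        for label, (s, e) in self.annotated_regions.items():
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"consensus {self.name}: region {label} out of bounds")


@dataclass
class RemnantHit:
    """A scored, stranded, possibly chained local-alignment hit to a consensus."""

    contig: str
    start: int
    end: int
    strand: str
    consensus: str
    consensus_start: int
    consensus_end: int
    score: float
    identity: float  # percent, 0..100
    fragment_ids: list[str] = field(default_factory=list)
    reciprocal_valid: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit start must be < end")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("percent identity must lie in [0, 100]")


@dataclass
class EnrichmentResult:
    """Observed vs expected paralog–TE association, with the χ² test."""

    flank_window: int
    n_genes_total: int
    n_genes_with_te: int
    n_paralogs: int
    observed: int
    expected: float
    chi_square: float
    df: int
    p_value: float
    null_mode: str
    permutation_p: Optional[float] = None
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SignatureStretch:
    """A diagnostic alignment-column run shared by the chimera and a parent subset."""

    span: tuple[int, int]  # half-open alignment-column span
    supporting_parents: frozenset[str]
    identity: float  # chimera-vs-supporting-set identity over the span, percent
    length_bp: int  # ungapped chimera bases in the span
    n_diagnostic: int  # columns where exactly the supporting set matches


@dataclass
class FusionCall:
    """Inferred parental origin and fusion point of a chimeric gene."""

    promoter_parent: str
    orf_parent: str
    breakpoint: int
    ambiguity: tuple[int, int]  # inclusive span of tied breakpoints
    split_score: float
    identifiable: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.ambiguity
        if not (lo <= self.breakpoint <= hi):
            raise ValueError("breakpoint must lie inside its ambiguity interval")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ambiguity"] = list(self.ambiguity)
        return d


_COMP = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def revcomp(seq: str) -> str:
    """Reverse complement; N and gaps are preserved."""
    return seq.translate(_COMP)[::-1]
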