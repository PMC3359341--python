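"""Multi-species synthetic genome simulator with a planted truth table.

Emulates the genomic situation the downstream modules analyse: syntenic
regions carrying ortholog anchor genes, X-linked multigene families that
expanded by duplication, decayed Helitron-like TE remnants preferentially
planted in gene flanks, and one chimeric gene formed by fusing one family's
promoter onto a specific polymorphic variant of another family's ORF.

Every stochastic operation draws from one seeded ``numpy`` generator, so a
given (seed, config) pair reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from tefam.records import (
    AnnotatedGenome,
    ChimeraRecord,
    ConsensusRepeat,
    GeneRecord,
    TERecord,
    TruthTable,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class CapacityError(ValueError):
    """A contig is too short to place the requested features."""


@dataclass(frozen=True)
class ChimeraSpec:
    """Which families donate the promoter and the ORF of the planted chimera.

    The ORF donor is one designated polymorphic variant of ``orf_family``
    (``orf_variant``-th member), so the chimera inherits that variant's
    private substitutions — the diagnostic signal the inference module
    looks for.
    """

    promoter_family: int = 0
    orf_family: int = 1
    orf_variant: int = 0
    promoter_length: int = 150
    species_index: int = 0
    postfusion_rate: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_species: int = 3
    contig_length: int = 120_000
    n_background_genes: int = 20
    n_paralog_families: int = 8
    genes_per_family: tuple[int, int] = (2, 4)
    gene_length: int = 600
    paralog_divergence: float = 0.05
    species_divergence: float = 0.035
    te_consensus_length: int = 400
    te_decay_rate: float = 0.25
    te_indel_rate: float = 0.02
    te_truncation_fraction: float = 0.5
    p_te_near_paralog: float = 0.8
    p_te_background: float = 0.1
    flank_window: int = 3000
    te_exclude_gene_body: bool = True
    chimera: Optional[ChimeraSpec] = field(default_factory=ChimeraSpec)

    def validate(self) -> None:
        probs = {
            "paralog_divergence": self.paralog_divergence,
            "species_divergence": self.species_divergence,
            "te_decay_rate": self.te_decay_rate,
            "te_indel_rate": self.te_indel_rate,
            "te_truncation_fraction": self.te_truncation_fraction,
            "p_te_near_paralog": self.p_te_near_paralog,
            "p_te_background": self.p_te_background,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        lengths = {
            "contig_length": self.contig_length,
            "gene_length": self.gene_length,
            "te_consensus_length": self.te_consensus_length,
        }
        for name, v in lengths.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.flank_window < 0:
            raise ValueError("flank_window must be >= 0")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        lo, hi = self.genes_per_family
        if not (2 <= lo <= hi):
            raise ValueError("genes_per_family bounds must satisfy 2 <= min <= max")
        if self.chimera is not None:
            c = self.chimera
            if not (0.0 <= c.postfusion_rate <= 1.0):
                raise ValueError("postfusion_rate must lie in [0, 1]")
            if self.n_paralog_families >= 1 and not (0 <= c.species_index < self.n_species):
                raise ValueError("chimera species_index out of range")


@dataclass
class EditLog:
    """Record of the edits applied by :func:`decay_te`.

    Substitutions always replace a base with one of the 3 other bases
    (Jukes–Cantor-like uniform choice), so the expected identity of the
    retained, indel-free portion is ``1 - decay_rate`` exactly.
    """

    model: str = "uniform-other-base"
    retained_span: tuple[int, int] = (0, 0)  # half-open span of the consensus kept
    truncated: bool = False
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    insertions: list[tuple[int, str]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)
    decay_rate: float = 0.0

    def expected_identity(self) -> float:
        """Analytic expected per-base identity of retained positions, percent."""
        return 100.0 * (1.0 - self.decay_rate)

    def realized_identity(self) -> float:
        """Fraction of retained positions left unsubstituted, percent."""
        n = self.retained_span[1] - self.retained_span[0]
        if n == 0:
            return 0.0
        return 100.0 * (1.0 - len(self.substitutions) / n)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``rate`` to one of the
    3 other bases (never silently back to itself)."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def decay_te(
    consensus: str,
    decay_rate: float,
    indel_rate: float,
    truncation_fraction: float,
    rng: np.random.Generator,
    truncate_to: Optional[float] = None,
) -> tuple[str, EditLog]:
    """Produce a degraded TE copy from its consensus, with a full edit log.

    Order of edits: truncation (a Bernoulli(``truncation_fraction``) event
    retaining a contiguous block anchored at a random end, of uniform extent;
    ``truncate_to`` forces a specific retained fraction), then substitutions,
    then short (1–3 bp) insertions/deletions at per-site rate ``indel_rate``.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    for name, r in (("decay_rate", decay_rate), ("indel_rate", indel_rate),
                    ("truncation_fraction", truncation_fraction)):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {r}")
    log = EditLog(decay_rate=decay_rate)
    n = len(consensus)
    # truncation
    if truncate_to is not None:
        keep_frac = truncate_to
        do_truncate = truncate_to < 1.0
    else:
        do_truncate = bool(rng.random() < truncation_fraction)
        keep_frac = float(rng.uniform(0.1, 0.9)) if do_truncate else 1.0
    if do_truncate:
        keep = max(1, int(round(keep_frac * n)))
        if rng.random() < 0.5:
            span = (0, keep)
        else:
            span = (n - keep, n)
        log.truncated = True
    else:
        span = (0, n)
    log.retained_span = span
    seq = list(consensus[span[0] : span[1]])
    # substitutions
    for i in range(len(seq)):
        if rng.random() < decay_rate:
            old = seq[i]
            new = str(rng.choice(_BASES[_BASES != old.encode()]).decode())
            seq[i] = new
            log.substitutions.append((i, old, new))
    # indels, right to left so recorded positions stay valid
    for i in range(len(seq) - 1, -1, -1):
        if rng.random() < indel_rate:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                ins = random_sequence(size, rng)
                seq[i:i] = list(ins)
                log.insertions.append((i, ins))
            else:
                del seq[i : i + size]
                log.deletions.append((i, size))
    return "".join(seq), log


@dataclass
class ChimeraResult:
    sequence: str
    breakpoint: int
    ambiguity: tuple[int, int]  # inclusive span of offsets yielding the same string


def make_chimera(
    promoter_donor: str,
    promoter_span: tuple[int, int],
    orf_donor: str,
    orf_span: tuple[int, int],
) -> ChimeraResult:
    """Fuse a promoter-donor prefix to an ORF-donor suffix.

    The chimera is ``promoter_donor[p0:p1] + orf_donor[o0:o1]`` and the true
    breakpoint is the prefix length. When the donors are locally identical
    around the junction several offsets produce the same string; the
    inclusive ambiguity interval reports that shared-stretch span.
    """
    p0, p1 = promoter_span
    o0, o1 = orf_span
    if not (0 <= p0 <= p1 <= len(promoter_donor)):
        raise ValueError(f"promoter span {promoter_span} out of range")
    if not (0 <= o0 <= o1 <= len(orf_donor)):
        raise ValueError(f"ORF span {orf_span} out of range")
    prefix = promoter_donor[p0:p1]
    suffix = orf_donor[o0:o1]
    chimera = prefix + suffix
    b = len(prefix)
    # shift left while the base left of the junction also occurs in the ORF donor
    left = 0
    while left < b and o0 - left - 1 >= 0 and chimera[b - left - 1] == orf_donor[o0 - left - 1]:
        left += 1
    right = 0
    while (b + right < len(chimera) and p1 + right < len(promoter_donor)
           and chimera[b + right] == promoter_donor[p1 + right]):
        right += 1
    return ChimeraResult(chimera, b, (b - left, b + right))


@dataclass
class SimResult:
    genomes: dict[str, AnnotatedGenome]
    truth: TruthTable
    consensus: ConsensusRepeat
    config: SimConfig


def _place_intervals(lengths: list[int], contig_length: int, min_gap: int,
                     rng: np.random.Generator) -> list[int]:
    """Left coordinates for features of the given lengths, in order, separated
    by at least ``min_gap`` and fitting in ``contig_length``."""
    n = len(lengths)
    total = sum(lengths) + (n + 1) * min_gap
    if total > contig_length:
        raise CapacityError(
            f"contig of {contig_length} bp cannot hold {n} features totalling "
            f"{sum(lengths)} bp with {min_gap} bp minimum gaps (need {total} bp)"
        )
    slack = contig_length - total
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    starts = []
    pos = 0
    for i, ln in enumerate(lengths):
        pos += min_gap + int(extra[i])
        starts.append(pos)
        pos += ln
    return starts


def _overlaps(a: tuple[int, int], intervals: list[tuple[int, int]]) -> bool:
    return any(a[0] < e and s < a[1] for s, e in intervals)


def simulate_genomes(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimResult:
    """Generate one annotated genome per species plus the ground truth.

    Ortholog anchors share family ids across species; paralog family members
    diverge independently from a per-species family sequence; TE remnants
    decay from a single simulated consensus and land in paralog flanks with
    probability ``p_te_near_paralog`` and elsewhere at the background rate.
    The chimera (if configured) is planted in exactly one species.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    consensus_seq = random_sequence(config.te_consensus_length, rng)
    consensus = ConsensusRepeat("DINE1_sim", consensus_seq)

    # ancestral sequences, shared across species
    bg_ancestors = [random_sequence(config.gene_length, rng)
                    for _ in range(config.n_background_genes)]
    fam_ancestors = [random_sequence(config.gene_length, rng)
                     for _ in range(config.n_paralog_families)]
    lo, hi = config.genes_per_family
    fam_sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_paralog_families)]

    want_chimera = config.chimera is not None and config.n_paralog_families >= 2
    cspec = config.chimera

    genomes: dict[str, AnnotatedGenome] = {}
    truth = TruthTable()
    te_counter = 0

    for s in range(config.n_species):
        species = f"sp{s + 1}"
        contig = f"{species}_contig1"

        gene_seqs: list[str] = []
        gene_meta: list[dict] = []
        for b, anc in enumerate(bg_ancestors):
            gene_seqs.append(mutate(anc, config.species_divergence, rng))
            gene_meta.append(dict(id=f"{species}_bg{b}", family_id=f"anchor{b}",
                                  is_paralog=False, is_chimera=False))
        member_ids: dict[tuple[int, int], str] = {}
        member_seqs: dict[tuple[int, int], str] = {}
        for f, anc in enumerate(fam_ancestors):
            fam_seq = mutate(anc, config.species_divergence, rng)
            for k in range(fam_sizes[f]):
                gid = f"{species}_fam{f}_p{k}"
                seq = mutate(fam_seq, config.paralog_divergence, rng)
                gene_seqs.append(seq)
                gene_meta.append(dict(id=gid, family_id=f"fam{f}",
                                      is_paralog=True, is_chimera=False))
                member_ids[(f, k)] = gid
                member_seqs[(f, k)] = seq

        chim_truth = None
        if want_chimera and s == cspec.species_index:
            pid = member_ids[(cspec.promoter_family, 0)]
            if cspec.orf_variant >= fam_sizes[cspec.orf_family]:
                raise ValueError("chimera orf_variant exceeds family size")
            oid = member_ids[(cspec.orf_family, cspec.orf_variant)]
            pseq = member_seqs[(cspec.promoter_family, 0)]
            oseq = member_seqs[(cspec.orf_family, cspec.orf_variant)]
            plen = min(cspec.promoter_length, len(pseq), len(oseq))
            res = make_chimera(pseq, (0, plen), oseq, (plen, len(oseq)))
            chim_seq = mutate(res.sequence, cspec.postfusion_rate, rng)
            gid = f"{species}_chimera"
            gene_seqs.append(chim_seq)
            gene_meta.append(dict(id=gid, family_id=f"fam{cspec.orf_family}",
                                  is_paralog=True, is_chimera=True))
            chim_truth = ChimeraRecord(gid, pid, oid, res.breakpoint)

        # layout: random gene order, minimum gap leaves room for flank-planted TEs
        order = rng.permutation(len(gene_seqs))
        min_gap = 2 * config.te_consensus_length + 100
        lengths = [len(gene_seqs[i]) for i in order]
        starts = _place_intervals(lengths, config.contig_length, min_gap, rng)

        contig_arr = np.frombuffer(random_sequence(config.contig_length, rng).encode(),
                                   dtype="S1").copy()
        genes: list[GeneRecord] = []
        occupied: list[tuple[int, int]] = []
        for pos, i in zip(starts, order):
            seq = gene_seqs[i]
            meta = gene_meta[i]
            end = pos + len(seq)
            strand = "+" if rng.random() < 0.5 else "-"
            body = seq if strand == "+" else _rc(seq)
            contig_arr[pos:end] = np.frombuffer(body.encode(), dtype="S1")
            genes.append(GeneRecord(meta["id"], contig, pos, end, strand,
                                    meta["family_id"], meta["is_paralog"],
                                    meta["is_chimera"]))
            occupied.append((pos, end))
        genes.sort(key=lambda g: g.start)
        occupied.sort()

        tes: list[TERecord] = []

        def plant_te(lo_: int, hi_: int, near: Optional[str]) -> bool:
            nonlocal te_counter
            decayed, log = decay_te(consensus_seq, config.te_decay_rate,
                                    config.te_indel_rate,
                                    config.te_truncation_fraction, rng)
            tlen = len(decayed)
            lo_c = max(0, lo_)
            hi_c = min(config.contig_length, hi_) - tlen
            if hi_c < lo_c:
                return False
            for _ in range(200):
                p = int(rng.integers(lo_c, hi_c + 1))
                iv = (p, p + tlen)
                if _overlaps(iv, occupied):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                body = decayed if strand == "+" else _rc(decayed)
                contig_arr[iv[0] : iv[1]] = np.frombuffer(body.encode(), dtype="S1")
                occupied.append(iv)
                trunc = 1.0 - (log.retained_span[1] - log.retained_span[0]) / len(consensus_seq)
                tes.append(TERecord(f"te{te_counter}", contig, iv[0], iv[1], strand,
                                    consensus.name, config.te_decay_rate, trunc, near))
                te_counter += 1
                return True
            return False

        for g in genes:
            if g.is_paralog and rng.random() < config.p_te_near_paralog:
                placed = False
                if config.te_exclude_gene_body:
                    sides = [(g.start - config.flank_window, g.start),
                             (g.end, g.end + config.flank_window)]
                    for lo_, hi_ in (sides if rng.random() < 0.5 else sides[::-1]):
                        if plant_te(lo_, hi_, g.id):
                            placed = True
                            break
                else:
                    placed = plant_te(g.start - config.flank_window,
                                      g.end + config.flank_window, g.id)
                if not placed:
                    raise CapacityError(
                        f"could not place a TE in the flank window of {g.id}; "
                        f"increase contig_length or reduce feature density")
        n_bg_te = int(rng.binomial(len(genes), config.p_te_background))
        for _ in range(n_bg_te):
            plant_te(0, config.contig_length, None)

        tes.sort(key=lambda t: t.start)
        genome = AnnotatedGenome(species, {contig: contig_arr.tobytes().decode()},
                                 genes, tes)
        genomes[species] = genome
        truth.genes.extend(genes)
        truth.tes.extend(tes)
        if chim_truth is not None:
            truth.chimera = chim_truth

    return SimResult(genomes, truth, consensus, config)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["genes_per_family"] = list(config.genes_per_family)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "genes_per_family" in d:
        d["genes_per_family"] = tuple(d["genes_per_family"])
    if d.get("chimera") is not None and not isinstance(d["chimera"], ChimeraSpec):
        d["chimera"] = ChimeraSpec(**d["chimera"])
    return SimConfig(**d)
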