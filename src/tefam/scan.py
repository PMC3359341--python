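"""Annotation of decayed TE remnants by consensus alignment.

A seed-and-extend scan: exact k-mer seed matches between a consensus and the
genome delimit candidate windows, each window is searched exhaustively with
affine-gap local alignment (iterating with masking so several fragments per
window are found), collinear fragments are chained, and every surviving hit
is validated by a reciprocal best-hit search against the full repeat
library. The score threshold is calibrated empirically from shuffled
genomes rather than from a fixed E-value.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np

from tefam.align import DEFAULT_SCORING, Scoring, local_align
from tefam.records import ConsensusRepeat, RemnantHit, revcomp

DEFAULT_SEED_K = 11


def _seed_positions(consensus: str, contig: str, k: int) -> list[tuple[int, int]]:
    """(genome_pos, consensus_pos) pairs of exact k-mer matches."""
    index: dict[str, list[int]] = {}
    for i in range(len(consensus) - k + 1):
        index.setdefault(consensus[i : i + k], []).append(i)
    out = []
    for g in range(len(contig) - k + 1):
        kmer = contig[g : g + k]
        for c in index.get(kmer, ()):
            out.append((g, c))
    return out


def _cluster_windows(seeds: list[tuple[int, int]], pad: int, contig_len: int,
                     k: int) -> list[tuple[int, int]]:
    if not seeds:
        return []
    positions = sorted({g for g, _ in seeds})
    windows = []
    start = prev = positions[0]
    for g in positions[1:]:
        if g - prev > pad:
            windows.append((max(0, start - pad), min(contig_len, prev + k + pad)))
            start = g
        prev = g
    windows.append((max(0, start - pad), min(contig_len, prev + k + pad)))
    # merge windows that overlap after padding
    merged = [windows[0]]
    for s, e in windows[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _window_fragments(window_seq: str, window_start: int, contig: str,
                      consensus: ConsensusRepeat, strand: str,
                      fragment_min_score: float, min_fragment_bp: int,
                      scoring: Scoring, max_iter: int = 25) -> list[RemnantHit]:
    """Iterative best-local-alignment with masking inside one window."""
    query = consensus.sequence if strand == "+" else revcomp(consensus.sequence)
    clen = len(consensus.sequence)
    work = list(window_seq)
    hits: list[RemnantHit] = []
    for _ in range(max_iter):
        aln = local_align(query, "".join(work), scoring)
        if aln.is_empty or aln.score < fragment_min_score:
            break
        ts, te = aln.target_span
        qs, qe = aln.query_span
        for i in range(ts, te):
            work[i] = "N"
        if te - ts < min_fragment_bp:
            continue
        if strand == "+":
            cspan = (qs, qe)
        else:
            cspan = (clen - qe, clen - qs)
        hits.append(RemnantHit(contig, window_start + ts, window_start + te, strand,
                               consensus.name, cspan[0], cspan[1],
                               aln.score, aln.identity))
    return hits


def scan_genome(sequences: dict[str, str], library: Sequence[ConsensusRepeat],
                min_score: float, min_fragment_bp: int = 30,
                max_gap_bp: int = 1000, scoring: Scoring = DEFAULT_SCORING,
                seed_k: int = DEFAULT_SEED_K,
                fragment_min_score: float = 24.0,
                chain: bool = True) -> list[RemnantHit]:
    """Scan every contig on both strands against every library consensus.

    Fragments shorter than ``min_fragment_bp`` are dropped, collinear
    same-strand fragments within ``max_gap_bp`` are chained, overlapping
    same-consensus hits are merged, and only (chained) hits scoring at least
    ``min_score`` are returned, sorted by (contig, start).
    """
    if min_score <= 0 or min_fragment_bp <= 0:
        raise ValueError("thresholds must be positive")
    if not library:
        raise ValueError("repeat library is empty")
    all_hits: list[RemnantHit] = []
    for contig_name, contig_seq in sequences.items():
        contig_seq = contig_seq.upper()
        for consensus in library:
            pad = len(consensus.sequence)
            for strand in "+-":
                query = consensus.sequence if strand == "+" else revcomp(consensus.sequence)
                seeds = _seed_positions(query, contig_seq, seed_k)
                for ws, we in _cluster_windows(seeds, pad, len(contig_seq), seed_k):
                    all_hits.extend(_window_fragments(
                        contig_seq[ws:we], ws, contig_name, consensus, strand,
                        fragment_min_score, min_fragment_bp, scoring))
    # chain per (contig, consensus, strand), then threshold and merge overlaps
    out: list[RemnantHit] = []
    keyfn = lambda h: (h.contig, h.consensus, h.strand)
    for _, group in itertools.groupby(sorted(all_hits, key=keyfn), key=keyfn):
        group = list(group)
        chained = chain_fragments(group, max_gap_bp) if chain else group
        chained = [h for h in chained if h.score >= min_score]
        out.extend(_merge_overlaps(chained))
    out.sort(key=lambda h: (h.contig, h.start, h.end))
    return out


def _merge_overlaps(hits: list[RemnantHit]) -> list[RemnantHit]:
    """Merge genomically overlapping hits to the same consensus/strand."""
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    merged = [hits[0]]
    for h in hits[1:]:
        last = merged[-1]
        if h.start < last.end:
            total = (last.end - last.start) + (h.end - h.start)
            ident = (last.identity * (last.end - last.start)
                     + h.identity * (h.end - h.start)) / total
            merged[-1] = RemnantHit(
                last.contig, last.start, max(last.end, h.end), last.strand,
                last.consensus, min(last.consensus_start, h.consensus_start),
                max(last.consensus_end, h.consensus_end),
                max(last.score, h.score), ident,
                sorted(set(last.fragment_ids) | set(h.fragment_ids)))
        else:
            merged.append(h)
    return merged


def _chainable(a: RemnantHit, b: RemnantHit, max_gap_bp: int,
               overlap_tol: int = 20) -> bool:
    """May fragment ``b`` (genomically downstream) extend a chain ending in ``a``?"""
    if (a.contig, a.consensus, a.strand) != (b.contig, b.consensus, b.strand):
        return False
    if b.start < a.end or b.start - a.end > max_gap_bp:
        return False
    if a.strand == "+":
        return b.consensus_start >= a.consensus_end - overlap_tol
    return b.consensus_end <= a.consensus_start + overlap_tol


def chain_fragments(hits: list[RemnantHit], max_gap_bp: int) -> list[RemnantHit]:
    """Merge collinear same-strand fragments within ``max_gap_bp`` into single
    hits carrying fragment ids; non-collinear hits pass through untouched.

    Chains are extracted by dynamic programming maximizing total fragment
    score, best chain first, each fragment used once.
    """
    if not hits:
        return []
    order = sorted(range(len(hits)), key=lambda i: (hits[i].start, hits[i].end))
    hs = [hits[i] for i in order]
    n = len(hs)
    used = [False] * n
    out: list[RemnantHit] = []
    while not all(used):
        best_score = [hs[i].score if not used[i] else -np.inf for i in range(n)]
        pred: list[Optional[int]] = [None] * n
        for j in range(n):
            if used[j]:
                continue
            for i in range(j):
                if used[i]:
                    continue
                if _chainable(hs[i], hs[j], max_gap_bp):
                    cand = best_score[i] + hs[j].score
                    if cand > best_score[j]:
                        best_score[j] = cand
                        pred[j] = i
        end = int(np.argmax(best_score))
        chain_idx = [end]
        while pred[chain_idx[-1]] is not None:
            chain_idx.append(pred[chain_idx[-1]])
        chain_idx.reverse()
        for i in chain_idx:
            used[i] = True
        members = [hs[i] for i in chain_idx]
        if len(members) == 1:
            out.append(members[0])
        else:
            total = sum(m.end - m.start for m in members)
            ident = sum(m.identity * (m.end - m.start) for m in members) / total
            frag_ids = [f"{m.contig}:{m.start}-{m.end}" for m in members]
            out.append(RemnantHit(
                members[0].contig, members[0].start, members[-1].end,
                members[0].strand, members[0].consensus,
                min(m.consensus_start for m in members),
                max(m.consensus_end for m in members),
                sum(m.score for m in members), ident, frag_ids))
    out.sort(key=lambda h: (h.contig, h.start))
    return out


def reciprocal_validate(hit: RemnantHit, sequences: dict[str, str],
                        library: Sequence[ConsensusRepeat],
                        scoring: Scoring = DEFAULT_SCORING,
                        margin: float = 1.2) -> RemnantHit:
    """Reciprocal best-hit check: the hit's genomic sequence must align best
    to its originating consensus, beating every other library entry by at
    least ``margin``-fold in score."""
    if hit.contig not in sequences:
        raise ValueError(f"hit contig {hit.contig} absent from genome")
    contig = sequences[hit.contig]
    if hit.end > len(contig):
        raise ValueError(f"hit {hit.start}-{hit.end} outside contig bounds")
    seq = contig[hit.start : hit.end]
    if hit.strand == "-":
        seq = revcomp(seq)
    best_self = 0.0
    best_other = 0.0
    for entry in library:
        score = local_align(entry.sequence, seq, scoring).score
        if entry.name == hit.consensus:
            best_self = max(best_self, score)
        else:
            best_other = max(best_other, score)
    valid = best_self > 0 and (best_other <= 0 or best_self >= margin * best_other)
    return RemnantHit(hit.contig, hit.start, hit.end, hit.strand, hit.consensus,
                      hit.consensus_start, hit.consensus_end, hit.score,
                      hit.identity, list(hit.fragment_ids), valid)


def calibrate_min_score(sequences: dict[str, str], library: Sequence[ConsensusRepeat],
                        n_shuffles: int = 20, quantile: float = 0.999,
                        seed: int = 0, scoring: Scoring = DEFAULT_SCORING,
                        seed_k: int = DEFAULT_SEED_K) -> float:
    """Empirical null score threshold.

    Best-hit scores are collected from base-shuffled copies of the input
    genome (matched length and composition) and the requested quantile is
    returned; scanning the real genome with this threshold keeps the
    per-genome false-hit probability near ``1 - quantile``.
    """
    rng = np.random.default_rng(seed)
    best_scores = []
    for _ in range(n_shuffles):
        shuffled = {}
        for name, seq in sequences.items():
            arr = np.frombuffer(seq.upper().encode(), dtype="S1")
            shuffled[name] = rng.permutation(arr).tobytes().decode()
        best = 0.0
        for contig_name, contig_seq in shuffled.items():
            for consensus in library:
                for strand in "+-":
                    query = (consensus.sequence if strand == "+"
                             else revcomp(consensus.sequence))
                    seeds = _seed_positions(query, contig_seq, seed_k)
                    for ws, we in _cluster_windows(seeds, len(consensus.sequence),
                                                   len(contig_seq), seed_k):
                        aln = local_align(query, contig_seq[ws:we], scoring)
                        best = max(best, aln.score)
        best_scores.append(best)
    return float(np.quantile(best_scores, quantile))
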