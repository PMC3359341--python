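"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity by the most literal method available —
exhaustive dynamic programming, double loops, subset enumeration — without
sharing code paths with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

NEG = float("-inf")


def sw_affine_score(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                    gap_open: float = -5.0, gap_extend: float = -2.0) -> float:
    """Exhaustive Gotoh local-alignment score; a gap of length k costs
    |gap_open| + k·|gap_extend|. N scores as a mismatch to everything."""
    n, m = len(a), len(b)

    def sub(x, y):
        return match if (x == y and x != "N") else mismatch

    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # alignment ending with a gap in `a`
    F = np.full((n + 1, m + 1), NEG)  # alignment ending with a gap in `b`
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend,
                          E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend,
                          F[i - 1][j] + gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return float(best)


def pairwise_overlap_counts(genes, tes, w, contig_lengths, include_body=True):
    """All-pairs half-open overlap check of gene flank windows vs TE spans."""
    flags = {}
    for g in genes:
        clen = contig_lengths[g.contig]
        if include_body:
            spans = [(max(0, g.start - w), min(clen, g.end + w))]
        else:
            spans = [(max(0, g.start - w), g.start), (g.end, min(clen, g.end + w))]
        spans = [(s, e) for s, e in spans if s < e]
        hit = False
        for t in tes:
            if t.contig != g.contig:
                continue
            for s, e in spans:
                if t.start < e and t.end > s:
                    hit = True
        flags[g.id] = hit
    return flags


def binomial_upper_tail_two_sided(observed: int, n: int, p: float) -> float:
    """Exact two-sided tail of Binomial(n, p) by summing point probabilities
    no larger than that of the observed count — the small-sample analogue of
    the two-cell χ² p-value."""
    from scipy.stats import binom

    probs = binom.pmf(np.arange(n + 1), n, p)
    return float(probs[probs <= probs[observed] + 1e-12].sum())


def base_diff_double_loop(rows: list[str]) -> np.ndarray:
    """Per-column double loop with pairwise deletion of gap/N columns."""
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = 0
            usable = 0
            for a, b in zip(rows[i], rows[j]):
                if a in "-N" or b in "-N":
                    continue
                usable += 1
                if a != b:
                    d += 1
            D[i, j] = d
    return D


def naive_upgma_cophenetic(D: np.ndarray) -> np.ndarray:
    """Cophenetic matrix from a literal UPGMA agglomeration over explicit
    member lists (no linkage recurrences)."""
    n = D.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros((n, n))

    def cdist(A, B):
        return float(np.mean([D[a, b] for a in A for b in B]))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdist(clusters[i], clusters[j])
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = d
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return coph


def enumerate_chains(fragments, max_gap_bp, overlap_tol=20):
    """Best total score over all subsets of fragments forming a valid
    collinear chain (same contig/consensus/strand, genomic order, gap bound,
    consensus-coordinate advance)."""

    def valid(chain):
        for x, y in zip(chain, chain[1:]):
            if (x.contig, x.consensus, x.strand) != (y.contig, y.consensus, y.strand):
                return False
            if y.start < x.end or y.start - x.end > max_gap_bp:
                return False
            if x.strand == "+" and y.consensus_start < x.consensus_end - overlap_tol:
                return False
            if x.strand == "-" and y.consensus_end > x.consensus_start + overlap_tol:
                return False
        return True

    frags = sorted(fragments, key=lambda h: h.start)
    best = 0.0
    best_chain = []
    for r in range(1, len(frags) + 1):
        for combo in itertools.combinations(frags, r):
            if valid(list(combo)):
                s = sum(f.score for f in combo)
                if s > best:
                    best = s
                    best_chain = list(combo)
    return best, best_chain


def enumerate_signature_runs(chim: str, parents: dict[str, str], min_len_bp: int):
    """All (subset S, maximal interval) pairs where the chimera matches every
    parent in S at each column (no mismatch budget), at least one column is
    matched by exactly S, S is a proper non-empty subset, and the interval
    covers >= min_len_bp ungapped chimera bases."""
    names = sorted(parents)
    ncol = len(chim)
    results = set()
    for r in range(1, len(names)):
        for S in itertools.combinations(names, r):
            Sset = frozenset(S)
            ok = []
            for c in range(ncol):
                base = chim[c]
                good = base not in "-N" and all(parents[p][c] == base for p in S)
                ok.append(good)
            c = 0
            while c < ncol:
                if not ok[c]:
                    c += 1
                    continue
                start = c
                while c < ncol and ok[c]:
                    c += 1
                end = c
                exact = any(
                    frozenset(p for p in names if parents[p][x] == chim[x]) == Sset
                    for x in range(start, end))
                ungapped = sum(1 for x in range(start, end) if chim[x] not in "-N")
                if exact and ungapped >= min_len_bp:
                    results.add((start, end, Sset))
    return results
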