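"""Pairwise alignment primitives shared by the scanner and the chimera tools.

Backed by :class:`Bio.Align.PairwiseAligner` (exhaustive affine-gap dynamic
programming). Default scoring is BLASTN-like: match +2, mismatch −3,
gap of length k costs 5 + 2k. ``N`` scores as a mismatch against everything,
including itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring; a gap of length k costs ``gap_open + k * gap_extend``."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_SCORING = Scoring()

_ALPHABET = "ACGTN"
_VALID = frozenset(_ALPHABET)


@dataclass
class LocalAlignment:
    """Best local alignment of ``query`` against ``target``."""

    score: float
    target_span: tuple[int, int]
    query_span: tuple[int, int]
    aligned_target: str
    aligned_query: str

    @property
    def is_empty(self) -> bool:
        return self.score <= 0

    @property
    def identity(self) -> float:
        """Percent of alignment columns (gaps included) with identical bases."""
        if not self.aligned_target:
            return 0.0
        n = sum(a == b and a != "-" for a, b in zip(self.aligned_target, self.aligned_query))
        return 100.0 * n / len(self.aligned_target)


def _substitution_matrix(scoring: Scoring) -> substitution_matrices.Array:
    mat = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == b and a != "N":
                mat[a, b] = scoring.match
            else:
                mat[a, b] = scoring.mismatch
    return mat


def make_aligner(scoring: Scoring = DEFAULT_SCORING, mode: str = "local",
                 free_end_gaps: bool = False) -> Align.PairwiseAligner:
    """Configure a PairwiseAligner for the shared scoring scheme.

    Biopython charges ``open_gap_score`` for the first gapped position and
    ``extend_gap_score`` for each further one, so the BLAST-style
    ``open + k*extend`` cost maps to ``open+extend`` / ``extend``.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local" if mode == "local" else "global"
    aligner.substitution_matrix = _substitution_matrix(scoring)
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    if mode == "global" and free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.86
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def check_sequence(seq: str, mask_invalid: bool = False) -> str:
    """Validate an ACGTN nucleotide string; optionally mask other symbols to N."""
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    if mask_invalid:
        return "".join(c if c in _VALID else "N" for c in s)
    bad = sorted(set(s) - _VALID)
    raise ValueError(f"non-ACGTN characters in sequence: {bad}")


def _render(alignment) -> tuple[str, str]:
    """Aligned target/query strings over the aligned region only."""
    t, q = alignment.target, alignment.query
    blocks = alignment.aligned  # shape (2, n_blocks, 2): [target, query]
    tb, qb = blocks[0], blocks[1]
    out_t, out_q = [], []
    for i in range(len(tb)):
        if i > 0:
            # unaligned stretch between consecutive blocks = gap in one sequence
            gap_t = tb[i][0] - tb[i - 1][1]
            gap_q = qb[i][0] - qb[i - 1][1]
            out_t.append(str(t[tb[i - 1][1] : tb[i][0]]) + "-" * gap_q)
            out_q.append("-" * gap_t + str(q[qb[i - 1][1] : qb[i][0]]))
        out_t.append(str(t[tb[i][0] : tb[i][1]]))
        out_q.append(str(q[qb[i][0] : qb[i][1]]))
    return "".join(out_t), "".join(out_q)


def local_align(query: str, target: str, scoring: Scoring = DEFAULT_SCORING,
                mask_invalid: bool = False) -> LocalAlignment:
    """Best affine-gap Smith–Waterman local alignment of query vs target.

    Returns an empty alignment (score 0) when no positively scoring local
    alignment exists.
    """
    if not query or not target:
        raise ValueError("both sequences must be non-empty")
    q = check_sequence(query, mask_invalid)
    t = check_sequence(target, mask_invalid)
    aligner = make_aligner(scoring, mode="local")
    score = aligner.score(t, q)
    if score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0), "", "")
    aln = next(iter(aligner.align(t, q)))
    blocks = aln.aligned
    tspan = (int(blocks[0][0][0]), int(blocks[0][-1][1]))
    qspan = (int(blocks[1][0][0]), int(blocks[1][-1][1]))
    at, aq = _render(aln)
    return LocalAlignment(float(score), tspan, qspan, at, aq)


def global_identity(seq_a: str, seq_b: str, scoring: Scoring = DEFAULT_SCORING,
                    count_gaps: bool = True) -> float:
    """Percent identity under global alignment with the shared scoring.

    With ``count_gaps`` (default) the denominator is every alignment column,
    gap columns included; otherwise only columns where both sequences hold a
    base.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    a = check_sequence(seq_a)
    b = check_sequence(seq_b)
    aligner = make_aligner(scoring, mode="global")
    aln = next(iter(aligner.align(a, b)))
    at, aq = _render_global(aln)
    matches = sum(x == y and x != "-" for x, y in zip(at, aq))
    if count_gaps:
        denom = len(at)
    else:
        denom = sum(x != "-" and y != "-" for x, y in zip(at, aq))
    return 100.0 * matches / denom if denom else 0.0


def _render_global(aln) -> tuple[str, str]:
    t, q = str(aln.target), str(aln.query)
    blocks = aln.aligned
    tb, qb = blocks[0], blocks[1]
    if len(tb) == 0:
        return t + "-" * len(q), "-" * len(t) + q
    out_t = [t[: tb[0][0]] + "-" * qb[0][0]]
    out_q = ["-" * tb[0][0] + q[: qb[0][0]]]
    for i in range(len(tb)):
        if i > 0:
            out_t.append(t[tb[i - 1][1] : tb[i][0]] + "-" * (qb[i][0] - qb[i - 1][1]))
            out_q.append("-" * (tb[i][0] - tb[i - 1][1]) + q[qb[i - 1][1] : qb[i][0]])
        out_t.append(t[tb[i][0] : tb[i][1]])
        out_q.append(q[qb[i][0] : qb[i][1]])
    out_t.append(t[tb[-1][1] :] + "-" * (len(q) - qb[-1][1]))
    out_q.append("-" * (len(t) - tb[-1][1]) + q[qb[-1][1] :])
    return "".join(out_t), "".join(out_q)


def match_profile(reference: str, sequence: str, scoring: Scoring = DEFAULT_SCORING) -> np.ndarray:
    """Boolean array over ``reference`` positions matched in a global
    alignment of ``sequence`` against it.

    Used by breakpoint localization: position i is True iff the alignment
    pairs reference[i] with an identical base of ``sequence``. End gaps are
    penalized so the two sequences stay in register over their whole length;
    a dovetail (free-end-gap) alignment would slide a partially matching
    parent off to one side and blank out the profile.
    """
    r = check_sequence(reference)
    s = check_sequence(sequence)
    aligner = make_aligner(scoring, mode="global")
    aln = next(iter(aligner.align(r, s)))
    blocks = aln.aligned
    profile = np.zeros(len(r), dtype=bool)
    for (ts, te), (qs, qe) in zip(blocks[0], blocks[1]):
        for k in range(te - ts):
            if r[ts + k] == s[qs + k] and r[ts + k] != "N":
                profile[ts + k] = True
    return profile
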