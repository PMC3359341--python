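"""Syntenic-block span bookkeeping and pairwise sequence identity.

Block coordinates are reported 1-based inclusive (FlyBase style), so a
block's span is end − start + 1. Identity is computed from a global
alignment with the package-wide scoring defaults; by default gap columns
count in the denominator (the conservative convention), with a flag to
exclude them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from tefam.align import DEFAULT_SCORING, Scoring, global_identity


@dataclass
class SyntenyBlock:
    """A conserved region delimited by ortholog anchors, 1-based inclusive."""

    species: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    member_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"invalid 1-based block {self.start}..{self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def block_span(start: int, end: int, granularity: int = 10_000) -> tuple[int, str]:
    """Span in bp of a 1-based inclusive interval, plus a rounded kb label.

    The label rounds the span to the nearest multiple of ``granularity``
    (e.g. X:8186055..8516953 at 10 kb granularity → 330,899 bp, "~330 kb").
    """
    if start < 1:
        raise ValueError("coordinates are 1-based: start must be >= 1")
    if start > end:
        raise ValueError("start must be <= end")
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    span = end - start + 1
    rounded = int(round(span / granularity)) * granularity
    label = f"~{rounded // 1000} kb"
    return span, label


def pairwise_identity(seq_a: str, seq_b: str, scoring: Scoring = DEFAULT_SCORING,
                      count_gaps: bool = True) -> float:
    """Percent identity between two sequences under global alignment.

    Symmetric in its arguments; 100.0 for identical sequences.
    """
    return global_identity(seq_a, seq_b, scoring, count_gaps)


def cluster_divergence(sequences: Sequence[str], scoring: Scoring = DEFAULT_SCORING,
                       count_gaps: bool = True) -> float:
    """Mean pairwise divergence (100 − identity) over all unordered pairs.

    For tandem repeats mutated independently from a common template at rate
    p this approaches the star-phylogeny expectation of ≈ 2p·100 percent.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    divs = [100.0 - pairwise_identity(a, b, scoring, count_gaps)
            for a, b in itertools.combinations(sequences, 2)]
    return sum(divs) / len(divs)


def identity_matrix(named_seqs: dict[str, str], scoring: Scoring = DEFAULT_SCORING,
                    count_gaps: bool = True) -> "object":
    """Symmetric DataFrame of percent identities between named sequences."""
    import pandas as pd

    names = list(named_seqs)
    mat = pd.DataFrame(100.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        v = pairwise_identity(named_seqs[a], named_seqs[b], scoring, count_gaps)
        mat.loc[a, b] = mat.loc[b, a] = round(v, 2)
    return mat
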