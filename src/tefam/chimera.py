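"""Chimeric-gene origin inference.

Given a column alignment of a chimera with candidate parent copies this
module (i) computes base-difference distance matrices, (ii) builds rooted
ultrametric UPGMA trees with column-bootstrap support and sub-threshold
collapse, (iii) finds diagnostic signature stretches — alignment-column
runs where the chimera matches a specific proper subset of the candidates
and differs from all others — and (iv) localizes the fusion breakpoint as
the split maximizing prefix agreement with the promoter parent plus suffix
agreement with the ORF parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from tefam.align import DEFAULT_SCORING, Scoring, match_profile
from tefam.records import FusionCall, SignatureStretch

_GAPLIKE = frozenset("-N")


@dataclass
class ColumnAlignment:
    """A multiple alignment with designated chimera and candidate-parent rows."""

    ids: list[str]
    rows: list[str]
    chimera_id: Optional[str] = None
    parent_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must all have equal length")
        self.rows = [r.upper() for r in self.rows]
        allowed = set("ACGT-N")
        for i, r in zip(self.ids, self.rows):
            if set(r) - allowed:
                raise ValueError(f"row {i} contains non-ACGT-N characters")
        if self.chimera_id is not None and self.chimera_id not in self.ids:
            raise ValueError(f"chimera id {self.chimera_id} not in alignment")
        for p in self.parent_ids:
            if p not in self.ids:
                raise ValueError(f"parent id {p} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def subsample_columns(self, columns: Sequence[int]) -> "ColumnAlignment":
        rows = ["".join(r[c] for c in columns) for r in self.rows]
        return ColumnAlignment(list(self.ids), rows, self.chimera_id,
                               list(self.parent_ids))

    @classmethod
    def from_fasta(cls, path, chimera_id: Optional[str] = None,
                   parent_ids: Optional[list[str]] = None) -> "ColumnAlignment":
        from Bio import AlignIO
        aln = AlignIO.read(str(path), "fasta")
        ids = [rec.id for rec in aln]
        rows = [str(rec.seq) for rec in aln]
        if chimera_id is not None and parent_ids is None:
            parent_ids = [i for i in ids if i != chimera_id]
        return cls(ids, rows, chimera_id, parent_ids or [])


# ------------------------------------------------------------- distances

def base_difference_matrix(aln: ColumnAlignment, gap_mode: str = "pairwise") -> np.ndarray:
    """Pairwise number of base differences between alignment rows.

    ``pairwise`` (default): for each pair, columns holding a gap or N in
    either row are skipped. ``complete``: columns holding a gap or N in
    *any* row are removed first. Raises if a pair retains zero usable
    columns.
    """
    if len(aln.rows) < 2:
        raise ValueError("need at least two sequences")
    mat = np.array([list(r) for r in aln.rows])
    usable = ~np.isin(mat, list(_GAPLIKE))
    if gap_mode == "complete":
        keep = usable.all(axis=0)
        mat = mat[:, keep]
        usable = usable[:, keep]
    elif gap_mode != "pairwise":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    n = len(aln.rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = usable[i] & usable[j]
            if not both.any():
                raise ValueError(
                    f"no usable columns between {aln.ids[i]} and {aln.ids[j]}")
            d = int(np.sum(mat[i, both] != mat[j, both]))
            D[i, j] = D[j, i] = d
    return D


# ------------------------------------------------------------- UPGMA trees

@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; ``height`` is the distance from the
    node down to any of its leaves (leaves sit at height 0)."""

    name: Optional[str] = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes below (and excluding) the root."""
        out = []

        def walk(node, is_root):
            if node.is_leaf:
                return
            if not is_root:
                out.append(frozenset(node.leaves()))
            for c in node.children:
                walk(c, False)

        walk(self, True)
        return out

    def supported_clades(self, eps: float = 1e-9) -> list[frozenset[str]]:
        """Clades subtended by an edge of positive length. A zero-length
        internal edge is an unresolved polytomy in disguise and carries no
        grouping signal (identical sequences must not support any clade)."""
        out = []

        def walk(node, parent_height, is_root):
            if node.is_leaf:
                return
            if not is_root and parent_height - node.height > eps:
                out.append(frozenset(node.leaves()))
            for c in node.children:
                walk(c, node.height, False)

        walk(self, self.height, True)
        return out

    def cophenetic(self, labels: list[str]) -> np.ndarray:
        """Matrix of 2×(merge height) for each leaf pair — the tree distance."""
        n = len(labels)
        idx = {l: i for i, l in enumerate(labels)}
        D = np.zeros((n, n))

        def walk(node):
            if node.is_leaf:
                return [node.name]
            groups = [walk(c) for c in node.children]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for x in groups[a]:
                        for y in groups[b]:
                            D[idx[x], idx[y]] = D[idx[y], idx[x]] = 2 * node.height
            return [x for g in groups for x in g]

        walk(self)
        return D

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node, parent_height):
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            sup = ""
            if with_support and node.support is not None:
                sup = f"{node.support:g}"
            return f"({inner}){sup}:{bl:g}"

        if self.is_leaf:
            return f"{self.name};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


def upgma(dist: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Unweighted pair-group agglomeration with arithmetic-mean distances.

    Ties in the minimum distance are broken toward the lowest (row, column)
    index pair, making the topology deterministic for any input.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] != len(labels):
        raise ValueError("labels must match matrix dimension")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if (D < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = [TreeNode(name=l) for l in labels]
    sizes = [1] * len(labels)
    D = D.copy()
    active = list(range(len(labels)))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = D[i, j]
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        parent = TreeNode(height=d / 2.0, children=[nodes[i], nodes[j]])
        # merged cluster reuses slot i; distances are size-weighted means
        for k in active:
            if k in (i, j):
                continue
            dk = (sizes[i] * D[i, k] + sizes[j] * D[j, k]) / (sizes[i] + sizes[j])
            D[i, k] = D[k, i] = dk
        nodes[i] = parent
        sizes[i] += sizes[j]
        active.remove(j)
    return nodes[active[0]]


def collapse_tree(root: TreeNode, threshold: float) -> TreeNode:
    """Collapse internal edges with support below ``threshold`` (percent),
    promoting their children — the tree becomes multifurcating."""

    def walk(node: TreeNode) -> list[TreeNode]:
        if node.is_leaf:
            return [node]
        new_children: list[TreeNode] = []
        for c in node.children:
            kept = walk(c)
            new_children.extend(kept)
        node.children = new_children
        if node.support is not None and node.support < threshold:
            return node.children
        return [node]

    kept = walk(root)
    if len(kept) == 1 and kept[0] is root:
        return root
    return TreeNode(height=root.height, children=kept)


def bootstrap_support(aln: ColumnAlignment, n_iter: int = 500,
                      collapse: float = 50.0, seed: int = 0,
                      gap_mode: str = "pairwise") -> TreeNode:
    """UPGMA tree on base differences with column-bootstrap support.

    Columns are resampled with replacement ``n_iter`` times; each internal
    node's support is the percentage of replicate trees containing its leaf
    set as a clade. Supports are assigned on the full tree first, then
    branches below ``collapse`` percent are collapsed into polytomies.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    D = base_difference_matrix(aln, gap_mode)
    tree = upgma(D, aln.ids)
    counts = {clade: 0 for clade in tree.clades()}
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    for _ in range(n_iter):
        cols = rng.integers(0, ncol, size=ncol)
        rep = aln.subsample_columns(cols.tolist())
        try:
            Dr = base_difference_matrix(rep, gap_mode)
        except ValueError:
            continue  # a pair lost all usable columns in this replicate
        rep_clades = set(upgma(Dr, rep.ids).supported_clades())
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1

    def assign(node: TreeNode, is_root: bool):
        if node.is_leaf:
            return
        if not is_root:
            node.support = 100.0 * counts[frozenset(node.leaves())] / n_iter
        for c in node.children:
            assign(c, False)

    assign(tree, True)
    return collapse_tree(tree, collapse)


# ------------------------------------------------------------- signatures

def find_signature_stretches(aln: ColumnAlignment, min_len_bp: int = 10,
                             max_mismatch: int = 0) -> list[SignatureStretch]:
    """Diagnostic column runs identifying the chimera's parent subset.

    A stretch is a maximal run of columns over which the chimera matches a
    fixed non-empty *proper* subset S of the candidate parents (at most
    ``max_mismatch`` columns may violate this), with at least one diagnostic
    column where exactly the parents in S match. Runs covering fewer than
    ``min_len_bp`` ungapped chimera bases are dropped.
    """
    if aln.chimera_id is None:
        raise ValueError("alignment has no designated chimera")
    if len(aln.parent_ids) < 2:
        raise ValueError("need at least two candidate parents")
    chim = aln.row(aln.chimera_id)
    if all(c in _GAPLIKE for c in chim):
        raise ValueError("chimera row is entirely gaps")
    parents = {p: aln.row(p) for p in aln.parent_ids}
    all_parents = frozenset(aln.parent_ids)
    ncol = aln.n_columns

    def match_set(c: int) -> frozenset[str]:
        base = chim[c]
        if base in _GAPLIKE:
            return frozenset()
        return frozenset(p for p, row in parents.items() if row[c] == base)

    msets = [match_set(c) for c in range(ncol)]
    stretches: list[SignatureStretch] = []
    start = 0
    while start < ncol:
        if not msets[start]:
            start += 1
            continue
        # greedy extension: S = running intersection of per-column match sets
        S = msets[start]
        mismatches = 0
        end = start
        c = start
        while c < ncol:
            ms = msets[c]
            if ms and S & ms:
                S = S & ms
                end = c
            else:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
            c += 1
        span = (start, end + 1)
        _record_stretch(stretches, span, S, msets, chim, all_parents, min_len_bp)
        start = end + 1
    return sorted(stretches, key=lambda s: s.span)


def _record_stretch(stretches, span, S, msets, chim, all_parents, min_len_bp):
    if not S or S == all_parents:
        return
    s, e = span
    n_diag = sum(1 for c in range(s, e) if msets[c] == S)
    if n_diag == 0:
        return
    ungapped = sum(1 for c in range(s, e) if chim[c] not in _GAPLIKE)
    if ungapped < min_len_bp:
        return
    informative = [c for c in range(s, e) if chim[c] not in _GAPLIKE]
    matched = sum(1 for c in informative if S <= msets[c])
    identity = 100.0 * matched / len(informative) if informative else 0.0
    stretches.append(SignatureStretch((s, e), S, identity, ungapped, n_diag))


# ------------------------------------------------------------- fusion point

def localize_fusion(chimera: str, promoter_parent: str, orf_parent: str,
                    scoring: Scoring = DEFAULT_SCORING,
                    promoter_id: str = "promoter_parent",
                    orf_id: str = "orf_parent") -> FusionCall:
    """Locate the recombination breakpoint of a chimera between two parents.

    Each parent is globally aligned (free end gaps) to the whole chimera,
    yielding a per-position match profile; the breakpoint b maximizes
    (matches of the promoter parent in ``chimera[0:b)``) + (matches of the
    ORF parent in ``chimera[b:L)``). Tied maxima form the ambiguity
    interval and the midpoint is reported; a tie spanning the entire
    sequence (identical parents) is flagged unidentifiable.
    """
    if not chimera or not promoter_parent or not orf_parent:
        raise ValueError("all sequences must be non-empty")
    L = len(chimera)
    pa = match_profile(chimera, promoter_parent, scoring).astype(np.int64)
    pb = match_profile(chimera, orf_parent, scoring).astype(np.int64)
    prefix_a = np.concatenate([[0], np.cumsum(pa)])  # matches in chimera[0:b)
    prefix_b = np.concatenate([[0], np.cumsum(pb)])
    total_b = prefix_b[-1]
    score = prefix_a + (total_b - prefix_b)  # indexed by b = 0..L
    best = score.max()
    ties = np.flatnonzero(score == best)
    lo, hi = int(ties[0]), int(ties[-1])
    breakpoint = int(round((lo + hi) / 2))
    identifiable = not (lo == 0 and hi == L)
    return FusionCall(promoter_id, orf_id, breakpoint, (lo, hi), float(best),
                      identifiable)


def infer_parents(chimera: str, candidates: dict[str, str],
                  scoring: Scoring = DEFAULT_SCORING) -> FusionCall:
    """Try every ordered (promoter, ORF) candidate pair and return the
    fusion call with the highest split score."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate parents")
    profiles = {name: match_profile(chimera, seq, scoring).astype(np.int64)
                for name, seq in candidates.items()}
    L = len(chimera)
    best_call: Optional[FusionCall] = None
    names = sorted(candidates)
    for pn in names:
        for on in names:
            if pn == on:
                continue
            prefix_a = np.concatenate([[0], np.cumsum(profiles[pn])])
            prefix_b = np.concatenate([[0], np.cumsum(profiles[on])])
            score = prefix_a + (prefix_b[-1] - prefix_b)
            best = score.max()
            ties = np.flatnonzero(score == best)
            lo, hi = int(ties[0]), int(ties[-1])
            call = FusionCall(pn, on, int(round((lo + hi) / 2)), (lo, hi),
                              float(best), not (lo == 0 and hi == L))
            if best_call is None or call.split_score > best_call.split_score:
                best_call = call
    return best_call
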