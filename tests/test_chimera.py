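"""Base-difference distances, UPGMA/bootstrap trees, signatures, fusion."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from tefam.chimera import (
    ColumnAlignment,
    base_difference_matrix,
    bootstrap_support,
    find_signature_stretches,
    infer_parents,
    localize_fusion,
    upgma,
)
from oracles import base_diff_double_loop, naive_upgma_cophenetic, enumerate_signature_runs


def _random_rows(n, ncol, rng, alphabet="ACGT"):
    return ["".join(rng.choice(list(alphabet), size=ncol)) for _ in range(n)]


# ------------------------------------------------------------- distances

def test_identical_rows_zero_distance():
    aln = ColumnAlignment(["a", "b"], ["ACGT", "ACGT"])
    assert (base_difference_matrix(aln) == 0).all()


def test_gap_column_skipped_pairwise():
    aln = ColumnAlignment(["a", "b"], ["AC-T", "ACGT"])
    assert base_difference_matrix(aln)[0, 1] == 0


def test_distances_match_double_loop_oracle(rng):
    rows = _random_rows(5, 40, rng, alphabet="ACGT-N")
    # guarantee at least one usable column per pair
    rows = [r[:-4] + "ACGT" for r in rows]
    aln = ColumnAlignment([f"s{i}" for i in range(5)], rows)
    D = base_difference_matrix(aln)
    assert np.array_equal(D, base_diff_double_loop(rows))


def test_complete_deletion_drops_columns_globally():
    aln = ColumnAlignment(["a", "b", "c"], ["ACGT", "AC-T", "ACAT"])
    # column 2 (gap in b) is removed for every pair; a and c differ only
    # there, so complete deletion gives 0 while pairwise deletion gives 1
    D = base_difference_matrix(aln, gap_mode="complete")
    assert D[0, 2] == 0
    assert base_difference_matrix(aln, gap_mode="pairwise")[0, 2] == 1


def test_unusable_pair_raises():
    aln = ColumnAlignment(["a", "b"], ["A---", "-CGT"])
    with pytest.raises(ValueError, match="a.*b|b.*a"):
        base_difference_matrix(aln)


# ------------------------------------------------------------- UPGMA

def test_two_taxa_cherry():
    tree = upgma(np.array([[0.0, 6.0], [6.0, 0.0]]), ["a", "b"])
    assert tree.height == 3.0
    assert sorted(tree.leaves()) == ["a", "b"]


def test_four_taxon_hand_example():
    """AB=2, CD=4, all cross pairs 8: topology ((A,B),(C,D)) with merge
    heights 1 and 2 (hand agglomeration)."""
    D = np.array([[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float)
    tree = upgma(D, list("ABCD"))
    clades = {frozenset(c) for c in tree.clades()}
    assert clades == {frozenset("AB"), frozenset("CD")}
    heights = sorted(c.height for c in tree.children)
    assert heights == [1.0, 2.0]
    assert tree.height == 4.0


def test_invalid_matrices_rejected():
    with pytest.raises(ValueError):
        upgma(np.array([[0.0, np.nan], [np.nan, 0.0]]), ["a", "b"])
    with pytest.raises(ValueError):
        upgma(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["a", "b"])


def test_cophenetic_matches_naive_and_scipy(rng):
    """Tree distances agree with a naive explicit-membership agglomeration
    and with scipy's average linkage."""
    for _ in range(5):
        n = 7
        A = rng.random((n, n)) * 10
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"t{i}" for i in range(n)]
        tree = upgma(D, labels)
        got = tree.cophenetic(labels)
        assert np.allclose(got, naive_upgma_cophenetic(D))
        Z = linkage(squareform(D), method="average")
        assert np.allclose(squareform(got), cophenet(Z))


def test_ultrametric_leaf_depths_equal(rng):
    n = 6
    A = rng.random((n, n))
    D = A + A.T
    np.fill_diagonal(D, 0)
    tree = upgma(D, [f"x{i}" for i in range(n)])

    depths = []

    def walk(node, acc):
        if node.is_leaf:
            depths.append(acc + node.height)
            return
        for c in node.children:
            walk(c, acc + (node.height - c.height))

    walk(tree, 0.0)
    assert np.allclose(depths, depths[0])


# ------------------------------------------------------------- bootstrap

def _two_clade_alignment(rng, n_fixed=20, ncol=120):
    base = "".join(rng.choice(list("ACGT"), size=ncol))
    other = list(base)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for i in rng.choice(ncol, size=n_fixed, replace=False):
        other[i] = flip[other[i]]
    other = "".join(other)

    def noise(s, k):
        s = list(s)
        for i in rng.choice(len(s), size=k, replace=False):
            s[i] = flip[s[i]]
        return "".join(s)

    rows = [noise(base, 1), noise(base, 1), noise(base, 2),
            noise(other, 1), noise(other, 1), noise(other, 2)]
    return ColumnAlignment([f"t{i}" for i in range(6)], rows)


def test_identical_sequences_collapse_to_star():
    aln = ColumnAlignment(list("abcd"), ["ACGTACGT"] * 4)
    tree = bootstrap_support(aln, n_iter=50, collapse=50, seed=1)
    assert len(tree.children) == 4
    assert all(c.is_leaf for c in tree.children)


def test_single_iteration_supports_are_binary(rng):
    aln = _two_clade_alignment(rng)
    tree = bootstrap_support(aln, n_iter=1, collapse=0, seed=3)

    sups = []

    def walk(n):
        if n.support is not None:
            sups.append(n.support)
        for c in n.children:
            walk(c)

    walk(tree)
    assert sups and set(sups) <= {0.0, 100.0}


def test_planted_clade_gets_high_support(rng):
    """Two 3-taxon clades separated by 20 fixed differences: the split is
    recovered with bootstrap support >= 95 (500 iterations, 50% collapse)."""
    aln = _two_clade_alignment(rng, n_fixed=20)
    tree = bootstrap_support(aln, n_iter=500, collapse=50, seed=7)
    clade_support = {}

    def walk(n):
        if not n.is_leaf:
            if n.support is not None:
                clade_support[frozenset(n.leaves())] = n.support
            for c in n.children:
                walk(c)

    walk(tree)
    c1 = frozenset(["t0", "t1", "t2"])
    c2 = frozenset(["t3", "t4", "t5"])
    assert clade_support.get(c1, clade_support.get(c2, 0)) >= 95


def test_bootstrap_reproducible_bit_for_bit(rng):
    aln = _two_clade_alignment(rng)
    t1 = bootstrap_support(aln, n_iter=100, collapse=50, seed=11)
    t2 = bootstrap_support(aln, n_iter=100, collapse=50, seed=11)
    assert t1.to_newick() == t2.to_newick()


def test_newick_roundtrips_through_dendropy(rng):
    import dendropy

    aln = _two_clade_alignment(rng)
    nwk = bootstrap_support(aln, n_iter=50, collapse=50, seed=2).to_newick()
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert {l.taxon.label for l in tree.leaf_node_iter()} == \
        {f"t{i}" for i in range(6)}


# ------------------------------------------------------------- signatures

def test_single_parent_signature_detected():
    """Chimera matches P1 over a 30-column block where P2 and P3 differ."""
    import numpy as np
    r = np.random.default_rng(5)
    block = "".join(r.choice(list("ACGT"), size=30))
    shared = "".join(r.choice(list("ACGT"), size=30))
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    other = "".join(flip[c] for c in block)
    chim = shared + block + shared
    p1 = shared + block + shared
    p2 = shared + other + shared
    p3 = shared + other + shared
    aln = ColumnAlignment(["chim", "p1", "p2", "p3"], [chim, p1, p2, p3],
                          chimera_id="chim", parent_ids=["p1", "p2", "p3"])
    stretches = find_signature_stretches(aln, min_len_bp=20)
    assert any(s.supporting_parents == frozenset({"p1"}) for s in stretches)


def test_fig2_style_fixture_identifies_two_ortholog_parents():
    """Chimera + 5 parents; one 25-column block is shared with exactly two
    (orthologous) parents and absent from the other three."""
    r = np.random.default_rng(9)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    flank = "".join(r.choice(list("ACGT"), size=40))
    not_flank = "".join(flip[c] for c in flank)
    sig = "".join(r.choice(list("ACGT"), size=25))
    not_sig = "".join(flip[c] for c in sig)
    chim = flank + sig + flank
    # the two ortholog carriers share only the signature block with the
    # chimera; the other three parents share only the flanks
    carriers = [not_flank + sig + not_flank] * 2
    others = [flank + not_sig + flank] * 3
    ids = ["chim", "GD", "GM", "x1", "x2", "x3"]
    aln = ColumnAlignment(ids, [chim] + carriers + others, chimera_id="chim",
                          parent_ids=ids[1:])
    stretches = find_signature_stretches(aln, min_len_bp=20)
    sig_stretches = [s for s in stretches
                     if s.supporting_parents == frozenset({"GD", "GM"})]
    assert len(sig_stretches) == 1
    s = sig_stretches[0]
    assert s.span == (40, 65)
    assert s.length_bp == 25


def test_equidistant_chimera_yields_no_stretch():
    # chimera differs from every parent at every column
    chim = "AAAA AAAA".replace(" ", "")
    p1 = "CCCCCCCC"
    p2 = "GGGGGGGG"
    aln = ColumnAlignment(["c", "p1", "p2"], [chim, p1, p2],
                          chimera_id="c", parent_ids=["p1", "p2"])
    assert find_signature_stretches(aln, min_len_bp=1) == []


def test_signature_runs_match_subset_enumeration(rng):
    """Greedy stretch finding agrees with exhaustive subset enumeration on a
    constructed 4-parent alignment."""
    r = np.random.default_rng(17)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    core = "".join(r.choice(list("ACGT"), size=30))
    blockA = "".join(r.choice(list("ACGT"), size=15))
    blockB = "".join(r.choice(list("ACGT"), size=15))
    notA = "".join(flip[c] for c in blockA)
    notB = "".join(flip[c] for c in blockB)
    chim = core + blockA + core + blockB + core
    p1 = core + blockA + core + notB + core   # shares A only
    p2 = core + blockA + core + notB + core
    p3 = core + notA + core + blockB + core   # shares B only
    p4 = core + notA + core + notB + core     # shares neither
    ids = ["c", "p1", "p2", "p3", "p4"]
    aln = ColumnAlignment(ids, [chim, p1, p2, p3, p4], "c", ids[1:])
    got = {(s.span[0], s.span[1], s.supporting_parents)
           for s in find_signature_stretches(aln, min_len_bp=10)}
    oracle = enumerate_signature_runs(chim, {"p1": p1, "p2": p2, "p3": p3, "p4": p4},
                                      min_len_bp=10)
    # the greedy scan consumes columns left to right, so each stretch must be
    # contained in the oracle's maximal interval for the same parent subset
    for s, e, S in got:
        assert any(S == So and so <= s and e <= eo for so, eo, So in oracle), \
            (s, e, S)
    # the two diagnostic blocks must be found with the right subsets
    subsets = {s for _, _, s in got}
    assert frozenset({"p1", "p2"}) in subsets
    assert frozenset({"p3"}) in subsets


def test_all_gap_chimera_rejected():
    aln = ColumnAlignment(["c", "a", "b"], ["----", "ACGT", "ACGT"],
                          chimera_id="c", parent_ids=["a", "b"])
    with pytest.raises(ValueError):
        find_signature_stretches(aln)


# ------------------------------------------------------------- fusion point

def test_exact_fusion_recovered_with_unit_ambiguity(rng):
    a = "".join(rng.choice(list("ACGT"), size=250))
    b = "".join(rng.choice(list("ACGT"), size=250))
    chim = a[:120] + b[120:]
    call = localize_fusion(chim, a, b)
    # chance matches between the random parents near the junction can tie a
    # few neighbouring breakpoints, so allow a small window around the truth
    assert call.breakpoint == pytest.approx(120, abs=6)
    lo, hi = call.ambiguity
    assert lo - 3 <= 120 <= hi + 3
    assert hi - lo <= 12
    assert call.identifiable


def test_identical_parents_flagged_unidentifiable(rng):
    a = "".join(rng.choice(list("ACGT"), size=200))
    call = localize_fusion(a, a, a)
    assert not call.identifiable
    assert call.ambiguity == (0, 200)


def test_label_permutation_equivariance(rng):
    a = "".join(rng.choice(list("ACGT"), size=200))
    b = "".join(rng.choice(list("ACGT"), size=200))
    c = "".join(rng.choice(list("ACGT"), size=200))
    chim = a[:90] + b[90:]
    call1 = infer_parents(chim, {"A": a, "B": b, "C": c})
    call2 = infer_parents(chim, {"zC": c, "zB": b, "zA": a})
    assert (call1.promoter_parent, call1.orf_parent) == ("A", "B")
    assert (call2.promoter_parent, call2.orf_parent) == ("zA", "zB")
    assert call1.breakpoint == call2.breakpoint
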