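"""Flank windows, TE-proximity counting and the χ² / permutation tests."""

import numpy as np
import pytest
from scipy import stats

from tefam.enrichment import (
    chi_square_two_cell,
    count_genes_with_te,
    enrichment_test,
    flank_window,
    permutation_null,
)
from tefam.records import GeneRecord, TERecord
from oracles import pairwise_overlap_counts


def gene(i, start, end, contig="c1", paralog=False):
    return GeneRecord(f"g{i}", contig, start, end, "+", f"f{i}", paralog)


def te(i, start, end, contig="c1"):
    return TERecord(f"t{i}", contig, start, end, "+", "REP")


# ------------------------------------------------------------- flank_window

@pytest.mark.parametrize("span,w,clen,expect", [
    ((1000, 2000), 3000, 10_000, [(0, 5000)]),     # clamp at origin
    ((1000, 2000), 0, 10_000, [(1000, 2000)]),     # w=0 equals gene span
    ((9500, 9900), 3000, 10_000, [(6500, 10_000)]),  # clamp at contig end
])
def test_flank_window_clamping(span, w, clen, expect):
    g = GeneRecord("g", "c", span[0], span[1])
    assert flank_window(g, w, clen) == expect


def test_flank_window_body_exclusive_mode():
    g = GeneRecord("g", "c", 5000, 6000)
    assert flank_window(g, 1000, 20_000, include_body=False) == \
        [(4000, 5000), (6000, 7000)]


def test_gene_outside_contig_rejected():
    g = GeneRecord("g", "c", 5000, 6000)
    with pytest.raises(ValueError):
        flank_window(g, 100, 5500)


# ------------------------------------------------------------- counting

def test_abutting_te_not_counted_half_open():
    g = gene(0, 1000, 2000)
    t_abut = te(0, 5000, 5200)   # window is [0, 5000): zero overlap
    t_in = te(1, 4999, 5200)     # 1 bp overlap counts
    clen = {"c1": 10_000}
    tab = count_genes_with_te([g], [t_abut], 3000, clen)
    assert not tab["has_te"].iloc[0]
    tab = count_genes_with_te([g], [t_in], 3000, clen)
    assert tab["has_te"].iloc[0]


def test_body_mode_controls_internal_te():
    g = gene(0, 1000, 2000)
    t_inside = te(0, 1400, 1600)
    clen = {"c1": 10_000}
    assert count_genes_with_te([g], [t_inside], 500, clen)["has_te"].iloc[0]
    assert not count_genes_with_te([g], [t_inside], 500, clen,
                                   include_body=False)["has_te"].iloc[0]


def test_counting_matches_quadratic_oracle(rng):
    clen = {"c1": 100_000, "c2": 50_000}
    genes, tes = [], []
    for i in range(50):
        contig = "c1" if rng.random() < 0.7 else "c2"
        s = int(rng.integers(0, clen[contig] - 2000))
        genes.append(gene(i, s, s + int(rng.integers(200, 2000)), contig,
                          paralog=bool(rng.random() < 0.4)))
    for i in range(30):
        contig = "c1" if rng.random() < 0.7 else "c2"
        s = int(rng.integers(0, clen[contig] - 500))
        tes.append(te(i, s, s + int(rng.integers(50, 500)), contig))
    for include_body in (True, False):
        tab = count_genes_with_te(genes, tes, 3000, clen, include_body)
        expected = pairwise_overlap_counts(genes, tes, 3000, clen, include_body)
        got = dict(zip(tab["gene_id"], tab["has_te"]))
        assert got == expected


# ------------------------------------------------------------- χ² test

def test_chi_square_from_published_counts():
    """243 observed vs 156 expected TE-associated paralogs among 1180:
    χ² ≈ 55.9 on 1 df, p far below 0.005."""
    chi2, p = chi_square_two_cell(243, 156.0, 1180)
    assert chi2 == pytest.approx(55.91, abs=0.01)
    assert p < 0.005


def test_observed_equals_expected_gives_p_one():
    chi2, p = chi_square_two_cell(10, 10.0, 20)
    assert chi2 == 0.0
    assert p == 1.0


def test_degenerate_expected_rejected():
    with pytest.raises(ValueError):
        chi_square_two_cell(5, 0.0, 20)
    with pytest.raises(ValueError):
        chi_square_two_cell(5, 20.0, 20)


def _planted_instance(rng, n_genes=400, n_par=20, p_par=0.5, p_bg=0.5):
    """Genes on one long contig; TE presence decided by per-gene coin flips,
    realised as a TE planted inside the gene's window or not at all."""
    genes, tes = [], []
    pos = 0
    par_idx = set(rng.choice(n_genes, size=n_par, replace=False).tolist())
    for i in range(n_genes):
        g = gene(i, pos + 4000, pos + 5000, paralog=i in par_idx)
        genes.append(g)
        p = p_par if i in par_idx else p_bg
        if rng.random() < p:
            tes.append(te(i, pos + 5500, pos + 5700))
        pos += 12_000
    return genes, tes, {"c1": pos + 10_000}


def test_small_sample_p_close_to_exact_binomial(rng):
    """With few paralogs the χ² tail approximates the exact binomial
    two-sided tail computed at the genome-wide rate."""
    from oracles import binomial_upper_tail_two_sided
    genes, tes, clen = _planted_instance(rng, 400, 20, 0.8, 0.4)
    res, tab = enrichment_test(genes, tes, 3000, contig_lengths=clen)
    p_hat = res.n_genes_with_te / res.n_genes_total
    exact = binomial_upper_tail_two_sided(res.observed, res.n_paralogs, p_hat)
    assert abs(res.p_value - exact) < 0.08


def test_literal_rate_mode_warns_when_rate_exceeds_one(rng):
    genes = [gene(0, 1000, 2000, paralog=True), gene(1, 20_000, 21_000)]
    tes = [te(i, 1500 + 10 * i, 1600 + 10 * i) for i in range(3)]
    with pytest.warns(UserWarning):
        res, _ = enrichment_test(genes, tes, 3000, null_mode="literal-rate",
                                 contig_lengths={"c1": 40_000})
    assert res.warning is not None


def test_exclusion_filter_is_inert(rng):
    """Adding genes and TEs on an excluded contig changes no count."""
    genes, tes, clen = _planted_instance(rng, 100, 10, 0.8, 0.3)
    res1, _ = enrichment_test(genes, tes, 3000, contig_lengths=clen,
                              excluded_contigs=["U"])
    extra_genes = genes + [gene(900, 100, 900, "U", paralog=True)]
    extra_tes = tes + [te(900, 120, 300, "U")]
    clen2 = {**clen, "U": 10_000}
    res2, _ = enrichment_test(extra_genes, extra_tes, 3000, contig_lengths=clen2,
                              excluded_contigs=["U"])
    assert res1.to_dict() == res2.to_dict()


def test_scale_invariance(rng):
    genes, tes, clen = _planted_instance(rng, 80, 10, 0.8, 0.3)
    res1, _ = enrichment_test(genes, tes, 3000, contig_lengths=clen)
    genes2 = [GeneRecord(g.id, g.contig, 2 * g.start, 2 * g.end, g.strand,
                         g.family_id, g.is_paralog) for g in genes]
    tes2 = [TERecord(t.id, t.contig, 2 * t.start, 2 * t.end, t.strand, "REP")
            for t in tes]
    res2, _ = enrichment_test(genes2, tes2, 6000,
                              contig_lengths={k: 2 * v for k, v in clen.items()})
    assert res1.observed == res2.observed
    assert res1.chi_square == pytest.approx(res2.chi_square)


# ------------------------------------------------------------- permutation

def test_all_paralogs_permutation_p_is_one(rng):
    genes, tes, clen = _planted_instance(rng, 30, 30, 0.5, 0.5)
    for g in genes:
        g.is_paralog = True
    out = permutation_null(genes, tes, 3000, n_perm=200, seed=1,
                           contig_lengths=clen)
    assert out["permutation_p"] == 1.0


def test_permutation_detects_planted_enrichment(rng):
    genes, tes, clen = _planted_instance(rng, 400, 60, 0.8, 0.1)
    out = permutation_null(genes, tes, 3000, n_perm=500, seed=2,
                           contig_lengths=clen)
    assert out["permutation_p"] < 0.01


def test_permutation_seed_reproducible(rng):
    genes, tes, clen = _planted_instance(rng, 100, 15, 0.6, 0.3)
    a = permutation_null(genes, tes, 3000, n_perm=300, seed=9, contig_lengths=clen)
    b = permutation_null(genes, tes, 3000, n_perm=300, seed=9, contig_lengths=clen)
    assert a == b
    with pytest.raises(ValueError):
        permutation_null(genes, tes, 3000, n_perm=50, seed=9, contig_lengths=clen)
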