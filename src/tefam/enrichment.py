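"""Paralog–TE proximity enrichment.

Scores each gene for the presence of a TE remnant within a fixed flank
window (3 kb by default), forms the expected count of TE-associated
paralogs from the genome-wide per-gene rate, and tests observed vs
expected with a two-cell χ² goodness-of-fit (df = 1). A label-permutation
null is provided as an independent check of the analytic p-value.
Excluded contigs (e.g. unplaced scaffolds) are dropped from every count.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tefam.records import EnrichmentResult, GeneRecord, RemnantHit, TERecord


def flank_window(gene: GeneRecord, w: int, contig_length: int,
                 include_body: bool = True) -> list[tuple[int, int]]:
    """Genomic interval(s) within ``w`` bp of a gene, clamped to the contig.

    With ``include_body`` (default) a single interval
    ``[start - w, end + w)`` is returned; otherwise the two flank-only
    intervals. Empty intervals after clamping are omitted.
    """
    if w < 0:
        raise ValueError("flank width must be >= 0")
    if gene.end > contig_length:
        raise ValueError(f"gene {gene.id} extends past its contig")
    if include_body:
        spans = [(gene.start - w, gene.end + w)]
    else:
        spans = [(gene.start - w, gene.start), (gene.end, gene.end + w)]
    out = []
    for s, e in spans:
        s, e = max(0, s), min(contig_length, e)
        if s < e:
            out.append((s, e))
    return out


def _te_intervals(tes: Iterable[TERecord | RemnantHit]) -> dict[str, np.ndarray]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for t in tes:
        by_contig.setdefault(t.contig, []).append((t.start, t.end))
    return {c: np.array(sorted(iv), dtype=np.int64) for c, iv in by_contig.items()}


def count_genes_with_te(
    genes: Sequence[GeneRecord],
    tes: Sequence[TERecord | RemnantHit],
    w: int,
    contig_lengths: Optional[dict[str, int]] = None,
    include_body: bool = True,
    excluded_contigs: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-gene flag: does at least one TE overlap the gene's flank window
    by ≥1 bp? Intervals are half-open, so exact abutment does not count.

    Returns a DataFrame (gene_id, contig, is_paralog, family_id, has_te);
    genes and TEs on excluded contigs are removed before counting.
    """
    excluded = set(excluded_contigs)
    genes = [g for g in genes if g.contig not in excluded]
    tes = [t for t in tes if t.contig not in excluded]
    by_contig = _te_intervals(tes)
    rows = []
    for g in genes:
        clen = (contig_lengths or {}).get(g.contig)
        if clen is None:
            clen = max([g.end] + [int(e) for _, e in by_contig.get(g.contig, [])])
        has = False
        iv = by_contig.get(g.contig)
        if iv is not None and len(iv):
            starts, ends = iv[:, 0], iv[:, 1]
            for ws, we in flank_window(g, w, clen, include_body):
                # overlap iff te.start < we and te.end > ws
                if bool(np.any((starts < we) & (ends > ws))):
                    has = True
                    break
        rows.append(dict(gene_id=g.id, contig=g.contig, is_paralog=g.is_paralog,
                         family_id=g.family_id, has_te=has))
    return pd.DataFrame(rows, columns=["gene_id", "contig", "is_paralog",
                                       "family_id", "has_te"])


def chi_square_two_cell(observed: float, expected: float, n_total: int) -> tuple[float, float]:
    """Two-cell χ² goodness-of-fit on (with-TE, without-TE) paralog counts.

    χ² = (O−E)²/E + ((N−O)−(N−E))²/(N−E), df = 1, upper-tail p-value.
    """
    if expected <= 0 or expected >= n_total:
        raise ValueError(
            f"expected count {expected} must lie strictly inside (0, {n_total})")
    chi2 = (observed - expected) ** 2 / expected \
        + (observed - expected) ** 2 / (n_total - expected)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def enrichment_test(
    genes: Sequence[GeneRecord],
    tes: Sequence[TERecord | RemnantHit],
    w: int = 3000,
    null_mode: str = "per-gene-rate",
    contig_lengths: Optional[dict[str, int]] = None,
    include_body: bool = True,
    excluded_contigs: Iterable[str] = (),
    continuity_correction: bool = False,
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Test whether paralogs carry nearby TEs more often than expected.

    ``per-gene-rate`` (default): the genome-wide fraction p̂ of genes with a
    TE in-window gives E = p̂ · n_paralogs. ``literal-rate`` divides the
    number of in-window TEs by the number of genes instead; that ratio can
    exceed 1, in which case a warning is attached.
    """
    table = count_genes_with_te(genes, tes, w, contig_lengths, include_body,
                                excluded_contigs)
    n_total = len(table)
    if n_total == 0:
        raise ValueError("no genes after contig exclusion")
    n_with = int(table["has_te"].sum())
    paralogs = table[table["is_paralog"]]
    n_par = len(paralogs)
    if n_par == 0:
        raise ValueError("no paralogs in the gene set")
    observed = int(paralogs["has_te"].sum())

    warning = None
    if null_mode == "per-gene-rate":
        rate = n_with / n_total
    elif null_mode == "literal-rate":
        excluded = set(excluded_contigs)
        kept_tes = [t for t in tes if t.contig not in excluded]
        n_te_near = _count_tes_near_genes(
            [g for g in genes if g.contig not in excluded], kept_tes, w,
            contig_lengths, include_body)
        rate = n_te_near / n_total
        if rate > 1:
            warning = (f"literal-rate null gives per-gene rate {rate:.3f} > 1; "
                       f"expected count exceeds the number of paralogs")
            warnings.warn(warning)
    else:
        raise ValueError(f"unknown null_mode {null_mode!r}")

    expected = rate * n_par
    if expected <= 0 or expected >= n_par:
        if warning is not None:
            # literal-rate pathology: report the counts, no defined test
            result = EnrichmentResult(
                flank_window=w, n_genes_total=n_total, n_genes_with_te=n_with,
                n_paralogs=n_par, observed=observed, expected=float(expected),
                chi_square=float("nan"), df=1, p_value=float("nan"),
                null_mode=null_mode, warning=warning)
            return result, table
        raise ValueError(
            f"expected count {expected:.2f} leaves the test undefined "
            f"(must lie strictly inside (0, {n_par}))")
    if continuity_correction:
        d = max(0.0, abs(observed - expected) - 0.5)
        chi2 = d ** 2 / expected + d ** 2 / (n_par - expected)
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = chi_square_two_cell(observed, expected, n_par)
    result = EnrichmentResult(
        flank_window=w, n_genes_total=n_total, n_genes_with_te=n_with,
        n_paralogs=n_par, observed=observed, expected=float(expected),
        chi_square=float(chi2), df=1, p_value=p, null_mode=null_mode,
        warning=warning)
    return result, table


def _count_tes_near_genes(genes, tes, w, contig_lengths, include_body) -> int:
    """Number of TEs lying within ≥1 gene's flank window (the literal rate's
    numerator)."""
    n = 0
    clens = contig_lengths or {}
    for t in tes:
        near = False
        for g in genes:
            if g.contig != t.contig:
                continue
            clen = clens.get(g.contig, max(g.end + w, t.end))
            for ws, we in flank_window(g, w, clen, include_body):
                if t.start < we and t.end > ws:
                    near = True
                    break
            if near:
                break
        n += near
    return n


def permutation_null(
    genes: Sequence[GeneRecord],
    tes: Sequence[TERecord | RemnantHit],
    w: int = 3000,
    n_perm: int = 1000,
    seed: int = 0,
    contig_lengths: Optional[dict[str, int]] = None,
    include_body: bool = True,
    excluded_contigs: Iterable[str] = (),
) -> dict:
    """Permutation p-value for the enrichment: paralog labels are shuffled
    across genes, preserving the number of paralogs and the per-gene TE
    flags. Uses the add-one estimator (1 + #{O* ≥ O}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    table = count_genes_with_te(genes, tes, w, contig_lengths, include_body,
                                excluded_contigs)
    has_te = table["has_te"].to_numpy()
    labels = table["is_paralog"].to_numpy()
    n_par = int(labels.sum())
    observed = int(has_te[labels].sum())
    rng = np.random.default_rng(seed)
    n_genes = len(table)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        idx = rng.choice(n_genes, size=n_par, replace=False)
        null[i] = int(has_te[idx].sum())
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return {
        "observed": observed,
        "permutation_p": float(p),
        "n_perm": n_perm,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        "null_q95": float(np.quantile(null, 0.95)),
    }
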