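# Methods

This note records the models, parameter choices and numerical decisions
behind each module, the scope of the synthetic-genome generator, and known
limitations. No empirical claim here goes beyond what the package itself
computes.

## Remnant scanning (`tefam.scan`)

**Model.** A remnant is a degenerate, possibly truncated and fragmented
copy of a consensus repeat. Scanning is seed-and-extend: exact 11-mer
matches between consensus and genome seed candidate windows; each window is
extended by affine-gap Smith–Waterman local alignment
(`Bio.Align.PairwiseAligner`) under BLASTN-like scores (match +2,
mismatch −3, gap open −5, gap extend −2, so a gap of length *k* costs
5 + 2*k*; `N` mismatches everything). Aligned spans are masked and the
window is re-scanned so multiple fragments per window are found.

**Chaining.** Fragments on the same contig/consensus/strand are chained by
a score-maximizing dynamic program. Two fragments are chainable when they
are in genomic order, the genomic gap is at most `max_gap_bp` (default
1000), and the consensus coordinates advance consistently (±20 bp
tolerance). A merged hit sums fragment scores and length-weights identity.

**Validation.** Each hit is re-aligned against every library consensus; it
is reciprocally valid only if its own family's score is at least 1.2× the
best other-family score. This rejects insertions of related families while
keeping genuine remnants (verified on planted decoys 35% diverged from the
target consensus).

**Threshold calibration.** `calibrate_min_score` shuffles each input contig
(preserving composition), scans the shuffles, and returns a high quantile
(default 99.9%) of the best-hit score distribution. On the packaged sizes
this controls false hits on ≥95% of fresh random genomes.

**Measured performance.** On 30 planted full-length copies decayed at 25%
substitutions and 2% indels, recall and precision are both 1.0
(`scripts/acceptance.py`). With the simulator's default truncation
(half of copies truncated to a uniform fraction of the consensus) recall
drops to ≈0.89 because very short fragments fall below the calibrated score
threshold; this is a sensitivity/specificity trade-off of the threshold,
not a chaining failure.

## Proximity enrichment (`tefam.enrichment`)

**Statistic.** Each gene is flagged if any TE remnant overlaps its flank
window (gene body ± `w`, default 3000 bp; half-open intervals, so exact
abutment does not count). With *N* paralogs, observed count *O* flagged,
and expected *E* from a null rate, the test is the two-cell χ²
goodness-of-fit with df = 1:

χ² = (O−E)²/E + (O−E)²/(N−E).

**Null rates.** The default `per-gene-rate` null sets E = p̂·N with p̂ the
genome-wide fraction of genes flagged. The `literal-rate` mode divides the
number of in-window TEs by the number of genes; that ratio can exceed 1, in
which case the counts are reported with a warning and no χ² (the test is
undefined there). The per-gene rate is the default because it is a proper
probability.

**Permutation null.** Paralog labels are permuted across genes (preserving
the paralog count and each gene's TE flag); the p-value uses the add-one
estimator (1 + #{O\* ≥ O})/(1 + n_perm). The analytic χ² is two-sided while
the permutation test is upper-tailed, so decision comparisons halve the χ²
p-value on the enriched side. Measured: type-I error of the χ² at α = 0.05
is within [0.03, 0.07] over 500 null simulations, and analytic/permutation
decisions agree in ≥90% of seeded replicates (see `tests/test_acceptance.py`).

With few paralogs the χ² approximation is rough; the permutation p-value is
the more trustworthy number there.

## Chimera origin inference (`tefam.chimera`)

**Distances.** Base-difference counts over alignment columns, with
`pairwise` gap deletion (default: a column is skipped only for pairs where
either row is gapped) or `complete` deletion (a gapped column is dropped
for all pairs). A pair with zero usable columns is an error, not a zero.

**UPGMA.** Standard size-weighted arithmetic-mean agglomeration; ties on
the minimum distance break toward the lowest (row, column) index so trees
are deterministic. Output is a rooted ultrametric tree with node heights in
half-distance units; cophenetic distances are cross-checked in tests
against a naive explicit-membership agglomeration and scipy's average
linkage.

**Bootstrap.** Columns are resampled with replacement `n_iter` times
(default 500); a clade's support is the percentage of replicate trees whose
*positively supported* clades (clades subtending a positive-length edge)
contain it. Branches below the collapse threshold (default 50%) are
collapsed to polytomies. Counting only positive-length clades makes a set
of identical sequences collapse to a star rather than inheriting arbitrary
tie-break topology.

**Signature stretches.** Scanning left to right, a stretch is a maximal run
of columns over which the chimera matches a fixed running intersection *S*
of candidate parents, where *S* is a proper non-empty subset, at least one
column is matched by *exactly* S (a diagnostic column), and the run covers
at least `min_len_bp` ungapped chimera bases. Because the scan consumes
columns greedily, a stretch may start inside the maximal interval for its
subset; tests verify containment against exhaustive subset enumeration.

**Fusion-point localization.** Re-scoring every candidate breakpoint *b*
with fresh alignments is O(L³). Instead, each parent is globally aligned to
the whole chimera once, giving a per-position boolean match profile; the
breakpoint maximizes prefix-matches(promoter parent) + suffix-matches(ORF
parent). Tied maximizers form the reported ambiguity interval, whose
midpoint is the point estimate; identical parents are flagged
unidentifiable. The global alignment deliberately penalizes end gaps: with
free end gaps, `PairwiseAligner` becomes a dovetail/overlap aligner
(adjacent insertions and deletions are forbidden), which destroys the
positional register the profiles depend on. Measured recovery: median
breakpoint error ≤ 1 bp over 50 replicates at 5% post-fusion mutation, with
the correct parent pair in ≥90%; `infer_parents` tries all ordered parent
pairs and breaks exact ties by sorted name.

## Synthetic genomes (`tefam.simulate`)

**Scope.** The generator produces what the estimators need and no more:
per-species contigs containing (i) background "anchor" genes shared across
species and diverged only at `species_divergence` (default 0.035 per
lineage, i.e. the ≈93% ortholog-identity regime), (ii) paralog families
whose members diverge from a per-species family sequence at
`paralog_divergence` (default 0.05), (iii) TE remnants decayed from one
simulated consensus at `te_decay_rate` (default 0.25) with 1–3 bp indels
and optional 5′/3′ truncation, planted in paralog flank windows with
probability `p_te_near_paralog` (default 0.8) and elsewhere at
`p_te_background` (default 0.1), and (iv) optionally one chimera fusing the
promoter prefix of one family's first member to another family's ORF,
mutated post-fusion at a configurable rate. Defaults mirror the study
conditions (3 kb flank; association strength scaled from the published
243/1180 counts). Because paralog divergence is re-drawn per species,
same-index family members across species are *not* pure orthologs; the
pipeline therefore measures ortholog identity on anchor genes.

**Edit model.** Substitutions always change the base (uniform over the
other three), so expected identity is exactly 1 − rate; the returned edit
log records every event and can reconstruct the realized identity.
Placement overwrites a pre-generated random contig in place (no coordinate
shifting), and over-full configurations raise `CapacityError` rather than
silently truncating. All randomness flows through one
`numpy.random.Generator`, making output byte-identical per seed.

## Synteny (`tefam.synteny`)

Block spans use 1-based inclusive coordinates (span = end − start + 1) and
a label rounded to a stated granularity — e.g. X:8186055..8516953 spans
330,899 bp, "~330 kb" at 10 kb granularity, and 13890387..14275449 spans
385,063 bp, "~400 kb" at 100 kb granularity. Identity is global-alignment
percent identity with gaps counted in the denominator by default.

## Pipeline (`tefam.pipeline`)

Stages run in dependency order (simulate → scan → enrich → chimera →
synteny); per-stage seeds derive from the global seed as
(seed·1000003 + offset) mod (2³¹ − 1), so every derived seed fits in 31
bits and a (config, seed) pair reproduces the entire run. Configuration
errors (missing inputs, invalid simulator parameters) are raised before any
stage executes. The report embeds parameters, outputs, wall times, and —
in simulation mode — truth comparisons (scan recall/precision, breakpoint
error, parent match).

## Limitations

- The scanner is tuned for decayed remnants of a known consensus; it is not
  a general de-novo repeat finder, and heavily truncated fragments below
  the calibrated threshold are missed (measured ≈0.89 recall under default
  truncation, 1.0 without).
- The two-cell χ² treats the expected count as fixed, ignoring the sampling
  noise of the genome-wide rate; with a small paralog count the permutation
  p-value should be preferred.
- Fusion localization assumes a single breakpoint and roughly collinear,
  similar-length parents; gene conversion or multiple crossovers would be
  summarized by one point estimate with a wide ambiguity interval.
- The simulator plants uniform substitution/indel decay; it does not model
  rate heterogeneity, CpG effects, nested insertions, or segmental
  duplications.
- UPGMA assumes clock-like divergence; for strongly rate-heterogeneous data
  its topology can be wrong even with high bootstrap support.
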