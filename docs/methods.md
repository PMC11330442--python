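# Methods

## The vote-counting score

Paired designs with heterogeneous cohorts (different stressors, cell types,
labs) make a pooled model fit fragile; the package instead uses a
per-pair vote. For gene *g* in pair *p* the pseudocounted ratio
`(T_stress + 1) / (T_control + 1)` on TPM-scale values is compared against a
fold threshold `f` (default 1.5, inclusive on both sides so the cutoff pair
`f, 1/f` is symmetric and exact-ratio inputs are classifiable). The score is
the number of up votes minus down votes across all pairs — a robust,
model-free consistency statistic. Its two deliberate biases:

- The +1 pseudocount shrinks ratios of lowly expressed genes toward 1, so
  genes below roughly `f(t−1)/(f−t)` TPM (≈2 TPM for a 2-fold effect at
  t = 1.5) cannot receive a down vote regardless of their true effect.
  Detection is conditional on expression.
- A gene dysregulated strongly in a few pairs but not consistently ranks
  below a gene dysregulated modestly everywhere. That is the intended
  meaning of "consistency across the cohort".

**Selection.** The extreme `fraction` of the universe is selected,
`m = round(fraction/2 · G)` genes per direction (halves up; 62,266 genes at
5% → 1557 per direction). Genes are placed in one total order — score
descending, then signed mean log2 ratio descending, then gene ID — and the
up list takes the first `m`, the down list the last `m`. Using the *signed*
mean ratio as tie-break favors the larger effect at either end and, unlike
an absolute-value tie-break, makes the two lists provably disjoint whenever
`2m ≤ G` (with an absolute tie-break, a block of score-0 genes could be
claimed by both ends). An optional `min_abs_score` filter can additionally
prune weak-score selections; it is off by default.

**Missing values.** A NaN in either sample makes the pair abstain
(vote unchanged) by default — vote counting degrades gracefully under
missing data; a strict mode raises instead. A gene at zero in both samples
has ratio 1 and votes unchanged (forced by the pseudocount).

## Disease evidence integration

Study DEG lists are united gene-wise; each study contributes a
`log2fc_<study>` column whose presence doubles as the membership flag.
Duplicate (gene, study) rows with identical fold change are collapsed;
conflicting duplicates raise, since silently picking one would fabricate
provenance. Conflicting fold-change *signs across studies* are preserved
unreconciled — the table records what each study reported. TWAS genes join
the union but keep a separate flag, Z score and source so the candidate
filter can distinguish evidence types. Venn region counts over up to six
sets are computed by direct membership enumeration.

## Database linkage

Snapshots are frozen TSV extracts of the five association databases, one
record per (gene key, disease ID) with semicolon-separated evidence PMIDs
and an optional association score. Matching is deliberately strict and
transparent: a hit requires an exact disease-ID string match (synonymous
IDs from different ontologies are listed in the config), a gene-key match
against any available key form (Ensembl, symbol, Entrez — unmapped genes
are kept, flagged, and classified unlinked with a warning), and a score at
or above the per-database threshold (default 0: any evidence counts, since
the original tool's thresholds are not published). A score-only record
links the gene but contributes no PMIDs. PMIDs are deduplicated across
databases. The classification is order-independent and monotone: raising
any threshold can only unlink genes.

## Candidate filter and adjudication

`min_studies` defaults to 2 (i.e. ≥ 2 meta-analyses), because the published
candidate table retains genes backed by exactly two fold-change entries;
the TWAS criterion is presence of a Z score of either sign (an optional
|Z| threshold exists, default 0). Inclusion–exclusion holds by
construction: |twas| + |multi-study| − |both| = output size.

Adjudication is data-driven from a curated evidence table, not text mining
— the decision "is this statement mechanistic?" is a human judgement. The
module enforces the rule's invariants instead: unexploited = yes requires a
functional statement, an evidence PMCID and a nonzero search-result count;
zero results force no; every candidate must have an evidence row (missing
rows raise, so incomplete curation cannot pass silently).

## Synthetic cohorts

The generator emulates the statistical shape of the real inputs: a gene
universe with lognormal baselines (`exp(N(3, 1.5))` TPM, median ≈20),
pair-level multiplicative lognormal noise (σ = 0.25 on the natural-log
scale, matching the dispersion of TPM quantification), planted symmetric
fold effects (×f up, ÷f down; default f = 2) that fire per pair with
probability 0.8 (cohort heterogeneity: not every stressor/cell-type pair
responds), partially overlapping study lists (capture 0.6 per true gene,
20 false positives per study), sparse TWAS hits (0.1), sparse database
registration (0.3 of true disease genes, matching the observed ≈31% linked
fraction) and sparse functional literature (0.2, planted only on unlinked
disease genes so the ground-truth unexploited set is nonempty). Planted
baselines are floored at 4 TPM so a planted effect is always detectable in
principle (see the pseudocount bias above). Defaults: 2000 genes × 50
pairs, 50 + 50 planted, 3 studies, seed 7 — a scale at which the whole
pipeline runs in seconds while every selection step stays non-trivial.

One global seed drives an independent stream per generator
(`SeedSequence((seed, k))`), so expression, study lists and snapshots can
be regenerated independently and all outputs are bit-reproducible.

What the generator does **not** model: read-level sequencing noise,
batch/library-size effects, correlated genes, study-specific effect-size
distributions, disease-vocabulary mismatches between databases, or
ambiguous ID mappings (the generated ID map is complete and collision-free;
those paths are exercised by hand-built test fixtures). Passing tests
therefore demonstrate the pipeline's correctness and statistical behavior
under its stated model, not performance on real cohorts.

## Numerical choices

- Hypergeometric upper tails are computed with scipy's stable tail
  summation; tests cross-check against exact rational enumeration
  (`Fraction` arithmetic) to 10 significant figures for all small universes
  and report p-values to 3 significant figures in scientific notation.
- The one-sided (enrichment) tail is reported. For tables as extreme as
  the worked examples the two-sided Fisher p equals the one-sided value to
  printed precision (no opposite-tail table has smaller point probability),
  which the suite asserts numerically.
- The per-direction selection count uses half-up rounding
  (`floor(x + 0.5)`), reproducing 1557 from 62,266 × 0.025.
- All intermediate artifacts are TSV with `%.10g` floats; round-trips are
  lossless at that precision.

## Known limitations

- Vote counting discards effect-size magnitude beyond the threshold; it is
  a detection statistic, not an estimator.
- The GO-term enrichment check inherits whatever universe it is given;
  annotation coverage differences can move that p-value by an order of
  magnitude, so it is treated as a magnitude check only.
- The linkage step is only as good as the snapshots; the package
  deliberately performs no live queries, trading freshness for
  reproducibility.
- Score-threshold choices for DisGeNET/RNADisease-style sources are
  config, not science: no published values exist to default to.
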