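# Methods

## The prioritization procedure

`priogene` treats disease-gene discovery as supervised binary
classification of genes in a 10-dimensional summary-statistic space.

**Features.** SNPs are assigned to genes by coordinate containment: a SNP
at position *p* belongs to every gene whose interval `[start − flank,
end + flank)` contains it on the same chromosome (internal coordinates are
0-based, half-open; GTF input is converted on read). For each gene the five
smallest GWAS p-values, sorted ascending, form the phenotype part; the eQTL
p-values of those same five SNPs, looked up as (variant, gene) pairs, form
the transcriptome part, index-aligned. All missing entries are padded with
exactly 1 — the padding value is part of the model: a p-value of 1 encodes
"no evidence", so short genes and eQTL-silent SNPs are pulled toward the
null corner of the feature space rather than being dropped or imputed.
Genes with zero mapped SNPs carry no information in either layer and are
excluded (reported, not silently scored). Ties between equal p-values are
broken by (position, variant_id), which makes the extraction invariant to
input row order.

**Labels.** Genes listed in the gene–disease table are positives,
regardless of their network scores (precedence rule). Every other annotated
gene is scored by its *relevance* — the maximum network correlation score
over its edges to any positive, 0 if isolated — and is a negative when the
relevance is below the threshold (default 1.0), otherwise a candidate. The
reading of "isolated" is genuinely open: relevance 0 can mean "known to be
unrelated" or "never measured". The default (`isolated="negative"`)
follows the threshold rule literally; `isolated="candidate"` is available
for the conservative reading. Counts of positives/negatives are treated as
data-dependent, never asserted.

**Evaluation.** Stratified, seeded k-fold cross-validation (default
k = 10); stratification avoids degenerate folds at imbalanced class
ratios. Per-fold AUC is computed on the held-out fold only; the summary
statistic is the arithmetic mean of the per-fold AUCs, and a pooled ROC
curve is built from the out-of-fold scores. When a hyperparameter grid is
supplied, it is searched by an inner 3-fold loop on the training folds only
(nested, to avoid selection leakage — the alternative of searching on the
full data was rejected) and the best combination is refit per fold. The
documented default grids are: forest — trees ∈ {100, 300, 500}, depth ∈
{∞, 10, 20}, features-per-split ∈ {sqrt, log2}; SVM — C ∈ {0.1, 1, 10},
γ ∈ {scale, 0.1}; naive Bayes — variance smoothing ∈ {1e−9, 1e−7, 1e−5}.
Classifier comparisons reuse one fold partition across all classifiers, so
per-fold AUC differences are paired. Confusion metrics use a 0.5
probability threshold by default; ROC/AUC are threshold-free and primary.
The feed-forward network comparator (`dnn`, a small MLP) is available but
off the default spec list, since no particular architecture is canonical
for this problem. Random-forest impurity importances are exposed as raw
scores only; no claim about their robustness to linkage disequilibrium is
made or tested.

**Ranking.** The final model is fit on all positives and negatives and
scores every admissible candidate. Ranks are 1..n, ties broken by gene_id.
Novel calls use an explicit probability threshold (default 0.5) or a
top-*n* cut, recorded in the output header so the selection is
reproducible. Candidates with no mapped SNPs are reported as unscorable
rather than scored on an all-ones vector.

## The synthetic-study generator

The generator emulates the *shapes and dependencies* of the five real
inputs, not their biology. Null SNP p-values are Uniform(0, 1); SNPs inside
causal genes draw Beta(a, 1) with a < 1 — the standard one-parameter
p-value enrichment model, chosen because the analytic mean a/(a + 1) gives
the tests an exact target. In the eQTL layer, each causal gene's top-k GWAS
SNPs carry an enriched pair with probability `eqtl_signal_prob`; every
other SNP (including a top SNP that misses its signal draw — this keeps
causal and non-causal genes exchangeable under the global null a = 1,
signal = 0) is emitted as a null pair with probability
`eqtl_null_pair_prob`. A fraction of causal genes is listed in the
gene–disease table; held-out causal genes get a strong (≥ 1) network edge
to a listed gene, so they surface as candidates and the ranking stage has a
recoverable truth. Non-causal genes get a weak (< 1) edge with probability
`negative_link_fraction`, otherwise a strong one.

Default condition (the reference planted-signal study used by the
calibration tests and the reproduction script): 2,000 genes, 400 causal,
3–15 SNPs per gene, a = 0.1, eqtl_signal_prob = 0.8, 80% of causal genes
labeled, negative-link fraction 0.5, two 15-Mb chromosomes with gene
lengths 1–5 kb (roughly gene-scale intervals with realistic SNP density for
interval-mapping purposes; the genome is sized so 2,000 genes pack
disjointly with ample intergenic space). All randomness flows from one seed
through per-output substreams; regeneration is byte-identical.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: linkage disequilibrium between SNPs (real
top-5 p-values are correlated, so real features are less informative than
independent draws), allele frequencies and effect sizes, realistic network
topology (edges here are mostly gene-to-positive spokes), annotation noise,
and any label noise in the disease table. The near-perfect AUC at the
reference condition reflects the strength of the planted signal, not an
expectation for real studies.

## Numerical choices and degenerate inputs

* p-values of exactly 0 are clamped to the smallest positive float with a
  warning (the feature space is raw p-values; 0 would survive the math but
  is suspicious input). Rows with p outside (0, 1] are dropped and counted.
* Raw p-values are the default feature scale, padding 1; a −log10 scale
  (padding 0) is available behind `scale="neglog10"`; for monotone-invariant
  classifiers the choice is immaterial, for distance-based ones it is not.
* Top-5 SNPs are selected purely by GWAS p-value, before any eQTL lookup
  (the alternative — requiring eQTL availability first — would change the
  meaning of the transcriptome part from "eQTL evidence for the strongest
  GWAS signals" to "strongest jointly-measured signals").
* No GWAS p-value ceiling is applied before mapping by default; an optional
  filter exists for analyses that want to restrict to nominally
  significant loci.
* AUC handles score ties by the trapezoidal rule (tied positive–negative
  pairs count 1/2); a classifier emitting non-finite scores on degenerate
  input (e.g. Gaussian NB on zero-variance features) is collapsed to a
  constant ranking, i.e. chance-level AUC.
* All stochastic components take explicit seeds; cross-validation reports
  include the seed and fold assignment, and fitted models carry their
  feature column order (reordered prediction input is an error, not a
  silent misprediction) and a training-set fingerprint.

## Problem sizes used by the test suite

Oracle-equivalence checks run on 1,000 random small instances (feature
matrix) and exhaustive pairwise AUC checks up to 200 samples. Calibration
properties run at the reference 2,000-gene condition for the permuted-label
null (20 permutation seeds) and at an 800-gene version of the global null
(20 simulation seeds), sizes at which the null AUC band [0.40, 0.60] holds
with margin while the suite stays fast.

## Known limitations

Single-SNP evidence only: no LD-aware clumping, colocalization, or
conditional eQTL analysis; no positive-unlabeled correction for the label
construction (candidates certainly contain unlabeled true positives); no
network propagation beyond the one-hop relevance score; gene identity
matching is by identifier/symbol equality, with unmapped symbols reported
rather than resolved.
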