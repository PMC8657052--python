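# Methods

This note documents the models, conventions and design choices behind the
package, in the order data flows through it.

## Proteomic composition pipeline

**Input model.** Quantification records are long-format rows
(protein id, gene, sample, group ∈ {tumor, normal}, intensity) in
arbitrary LFQ units. Gene symbols are uppercased on ingest; panel aliases
(CD31→PECAM1, CD45→PTPRC, CD10→MME, CK18→KRT18) are resolved through a
packaged table.

**Matrisome annotation.** A packaged reference table maps gene symbols to
matrisome division and category; genes absent from the reference are
non-matrisome by definition. Core matrisome = glycoproteins + collagens +
proteoglycans. Records whose reference entry carries GO:0050817
(coagulation — the fibrinogen chains FGA/FGB/FGG in the packaged table)
are excluded before composition analysis, and the exclusion is reported,
never silent.

**%LFQ.** Within each sample a gene's %LFQ is 100·intensity/sample total;
per-sample vectors sum to 100 by construction. The group summary is the
mean across samples (median available via `group_summary`). The choice of
summary only matters under skewed noise; at the default CV it is
immaterial.

**Differential abundance.** log2 fold change of group mean intensities;
Welch's unequal-variance t-test on log2 intensities; Benjamini–Hochberg
q-values. Zeros are treated as missing for the log transform, and a gene
missing in more than half of a group's samples is not tested. Identical
groups return t = 0, p = 1 even at zero variance (defined rather than
indeterminate). Significance gates default to p < 0.05 and FDR < 1%; note
that with five samples per group a four-fold enrichment reliably passes
the p-gate but not always a 1% FDR — tests assert accordingly.

**Abundance gate.** The "most abundant, by a normal fit" gate fits a
normal distribution to log10(%LFQ) and keeps genes strictly above
mean + z·SD, z = 0 by default. The exact published rule is not stated
anywhere we could pin down; the z-offset makes the choice explicit and
tunable.

**Core renormalization and blend selection.** Core-matrisome genes with
tumor %LFQ > 0.1% are renormalized so their percentages sum to 100
("core_pct"). Components with core_pct at or above the third quartile
enter the blend; Q3 uses linear interpolation (numpy type-7), documented
because tie and small-n behavior depend on the convention (ties at Q3 are
all included; 36 distinct values yield exactly 9 selections). Blend
fractions are core_pct renormalized over the selected set; mass
concentrations are fractions × total concentration (default 2 µg/mL);
coverage is the selected share of total core_pct before renormalization.

**Staining-pattern filter.** Candidates can be screened against tissue
staining records: removal if (A) tumor staining, when present, is not
interstitial-only; (B) normal-kidney staining, when present, is not
interstitial-only; (C) glomerular staining is present. Unknown fields
never remove a candidate; removals carry the failed criterion letters.

## Single-cell ECM source scoring

Counts are normalized to counts-per-10k per cell and log1p-transformed
(scanpy). Cluster profiles are arithmetic means of normalized values.

**Identity rule.** A cluster "hits" an identity when at least one panel
gene's cluster mean strictly exceeds that gene's grand mean across
clusters; an identity is assigned only when exactly one panel is hit —
i.e. every other panel's markers sit at or below their grand means.
Multiple hits give "Ambiguous", none give "Unassigned"; both are explicit
outcomes. "Average" is the unweighted grand mean of cluster means so that
large clusters do not define the baseline; a cell-weighted variant is
available.

**Tri-level scores.** For gene g with grand mean m, the bands are
"" ≤ 1·m < "+" ≤ 2·m < "++" ≤ 3·m < "+++". The published "above average /
2× above average / >2× above average" scheme is self-contradictory at its
2× boundary, so the (1×,2×], (2×,3×], (>3×) reading is adopted and all
three edges are configurable. The score of a cluster is monotone in its
own mean: raising one cluster's mean raises the grand mean by only 1/k of
the increment, so the ratio never decreases.

**Cluster comparison.** Genes are ranked by |log2((mean_a+ε)/(mean_b+ε))|
with pseudocount ε = 1 on normalized values; Wilcoxon rank-sum p-values
(BH-corrected) accompany the ranking and are withheld (NaN) when a
cluster has fewer than three cells. K-means (Lloyd, k-means++,
seed-deterministic) is provided as plumbing for unsupervised clustering;
all planted-truth tests supply labels directly so cluster recovery and
identity assignment are tested separately.

## Attachment quantification

Attachment is consumed as counts of attached cells per (cell line,
substrate, replicate); the morphological judgement that produces the
counts is out of scope. The exported effect size is
log2((mean_x + 0.5)/(mean_ref + 0.5)) against the uncoated "None" wells,
or against the full blend "All" for leave-one-out dropout conditions
("All-minus-X"); the 0.5 continuity constant keeps zero-count conditions
finite and is applied to both means, preserving antisymmetry. Replicates
are compared by Welch's t-test by default; the pooled-variance Student
form is a flag. With three replicates Welch is the safer default against
unequal variances at the cost of a little power.

## Culture census

**Classifier.** Seven decision markers (PDGFRα/β, CD45, CD34, VIM, CK18,
PAX2/8, CXCR4) feed a fixed-precedence rule table (Fibroblast →
Endothelial → Immune → Tumor → Other); the carcinoma marker set is
{CK18, VIM, PAX2/8, CXCR4} and Tumor requires any two of them positive
with PDGFRα/β, CD45 and CD34 negative. The Immune rule reads
"CD45+ CXCR4+/−" as CXCR4-unconstrained and leaves VIM unconstrained by
default (immune cells are commonly vimentin-positive); `strict_immune`
adds VIM− to the exclusion. Missing markers are tracked distinctly from
negative: a rule never fires on a missing value, and a cell with all
seven markers missing is "Unscorable", excluded from census denominators
and reported separately. The full 2⁷ rule table is committed as a golden
fixture and cross-checked against an independently coded oracle.

**Composition and clustering.** Per-condition fractions over the five
types sum to 1. For comparison across conditions the type × condition
matrix is Pareto-scaled per row — (x − mean)/√SD, sample SD, zero-variance
rows mapped to zeros — and conditions are clustered agglomeratively
(Euclidean distance, average linkage); the condition nearest to the
"input" column identifies the culture that best preserves the tumor's
cell repertoire.

**Joint fractions.** Two-marker co-stain fractions factor exactly as
marginal × conditional (e.g. 90% VIM+ with 41% CXCR4+ among them gives
36.9% double-positive and 53.1% VIM+/CXCR4−). Fractions are carried at
full precision and rounded half-up to integer percent only at display
(36.9 → 37, 53.1 → 53).

**3D structures.** Only Hoechst-positive structures enter the census.
Live = calcein+/EthD2−, dead = EthD2+/calcein−; double-positive
structures form a distinct "mixed" category (the source protocols are
silent on them) and double-negative structures are excluded with a count.
Structures strictly larger than 40 µm in diameter carry a necrotic-risk
flag. When replicates are recorded, conditions are compared pairwise by
two-sample tests on per-replicate structure counts.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of a single integer seed (independent
`SeedSequence`-derived streams) and every generated table round-trips
through its declared text format.

* **Proteomics** — lognormal intensities per gene per group
  (σ = √log(1+CV²)); fold changes act on the median. Defaults: 36 core
  genes, 200 non-matrisome genes, 3 fibrinogen genes at ~5× baseline
  abundance (emulating the few-percent-of-total fibrinogen seen in tumor
  lysates), 5 samples per group, CV 0.3, and nine planted components
  (COL6A1, FN1, TNC, HSPG2, COL12A1, TGFBI, LUM, POSTN, LAMA4 — LAMA4
  standing in for "laminin") enriched 4-fold in tumor. Background core
  genes sit log-uniformly in [0.3, 1.0]× the planted baseline so that
  every core gene clears the 0.1 %LFQ floor and blend membership is
  decided by the quartile rule, not the floor. The five-pair design
  matches a small nephrectomy cohort; CV 0.3 is a stand-in, since no
  variance estimates are published for such cohorts at this depth.
* **Counts** — negative binomial (gamma–Poisson) with shared dispersion
  2.0; one planted cluster per identity by default, 300 cells each,
  ~330 genes. Marker multipliers act on a cluster's expression
  composition: expected library size is equalized across clusters, since
  per-cell depth normalization discards absolute library differences
  anyway. The background gene set (300 filler genes) dilutes the
  compositional side-effect of marker elevation; with few background
  genes, elevating one cluster's markers measurably depresses the
  relative abundance of everything else in that cluster and the strict
  grand-mean identity rule then mislabels unrelated clusters as
  Ambiguous — a real compositional artifact that whole-transcriptome
  data dilutes across ~20k genes. CAF clusters additionally elevate
  ACTA2, IGFBP7, TAGLN, MYL9, MYLK and REN; `ecm_load` plants ECM
  production on chosen clusters and `gene_boost` elevates single genes.
* **Attachment** — binomial counts at planted probabilities;
  2000 seeded cells, 3 replicates.
* **Culture cells** — type counts follow the configured proportions
  exactly (largest-remainder allocation), so noise-free censuses equal
  the planted composition with no sampling error; marker booleans start
  from the noise-free type templates and flip independently at
  1−sensitivity / 1−specificity. Default composition is tumor-dominant
  with 7% fibroblasts. The Immune template draws CXCR4 positive with
  probability 0.5 (the phenotype admits either state).
* **Structures** — complementary live/dead stains at a planted live
  probability; lognormal diameters (median 30 µm, σ_log 0.4).

What passing tests show — and do not. Recovery results certify internal
consistency: the pipeline finds exactly the structure the generators
plant, under independent lognormal/NB/Bernoulli noise. Real LFQ data have
correlated missingness and shared-peptide effects, real scRNA-seq has
batch structure, doublets and ambient RNA, and real staining errors are
not independent across markers; none of these are modeled, so the planted
recovery rates are upper bounds on real-data behavior, not estimates of
it.

A note on classifier recovery under noise: with independent 5% flips
(sensitivity = specificity = 0.95) the rule table's per-type recalls have
closed forms — s²c⁴ ≈ 0.735 for Fibroblast (six constrained markers),
s·c⁵ ≈ 0.735 for Endothelial, ≈ 0.857 for Immune and Tumor — a macro
average near 0.80. The recovery test therefore checks empirical recalls
against an exact enumeration of the noise model rather than against a
round-number threshold.

## Problem sizes and determinism

Test and acceptance runs use 100-seed ensembles for the proteomic
end-to-end recovery, 10–25 seeds for single-cell checks, 1000 random
instances for oracle-equivalence checks, and n = 1000–5000 cells for
census checks — sizes at which Monte-Carlo error is far smaller than the
asserted margins while the whole suite stays fast. All randomness flows
from explicit integer seeds; reruns are bit-identical.

## Known limitations

* The matrisome reference is a 45-gene curated excerpt sufficient for the
  packaged analyses, not a full matrisome database; users can supply
  their own reference table to `annotate_matrisome`/`compose`.
* The DDA abundance gate's published selection rule is under-specified;
  the mean-of-logs cut with configurable z-offset is one defensible
  reading.
* %LFQ treats each sample's total intensity as a fixed normalizer;
  compositional effects of a few very abundant proteins (e.g. fibrinogen
  before exclusion) shift all other percentages.
* Condition clustering follows ClustVis-style defaults (Euclidean,
  average linkage); correlation distance is not currently exposed.
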