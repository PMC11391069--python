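# Methods

This note documents the models, defaults, and numerical choices behind
`hscfate`, and what the synthetic-data tests do and do not establish
about real data.

## Repopulation scoring and lineage-bias classification

All calls operate on raw flow-cytometry event counts, never on
pre-computed frequencies, so every threshold is auditable. Donor
chimerism is 100·donor/total per compartment; a compartment with zero
total events is marked undefined (NaN) and excluded from calls rather
than treated as zero.

Gating rules (all closed at the stated boundary): reconstitution at
month 2 requires ≥ 0.1 % donor frequency **and** ≥ 10 donor events in
the *same* compartment (leukocytes and/or platelets); single-lineage
positivity requires ≥ 0.01 % and ≥ 10 events, applied identically to
peripheral-blood lineages and bone-marrow progenitor gates.

The L/M ratio is (B+T+NK)/myeloid over relative donor contributions.
Platelet and erythrocyte readouts never enter L/M. Limit cases are
classified by the limit of the ratio: zero myeloid → +∞ → L-bi; zero
lymphoid → 0 → M-bi. The Bal interval is closed on both ends
(lower ≤ L/M ≤ upper → Bal) for deterministic tie-breaking.

Reference intervals come from unmanipulated cohorts. The exact numeric
bounds used with real data are a required configuration input; when
derived from a cohort, the default rule is the central 80 %
(10th–90th percentile with linear interpolation), with min–max and
geometric-mean ± 2 gSD² available. The percentile default is robust to
the heavy right tail of L/M ratios and keeps both bounds strictly
inside the observed range for cohorts of ≥ 10 mice.

Mice failing month-2 reconstitution are excluded from bias
classification (reported as `not-reconstituted`); missing T/NK panels
cause classification to refuse rather than impute. Classification is
scale-free in event counts.

## Clonal assay statistics

Poisson-seeded plates are inverted with the single-hit exponential
model: if cells land in wells as Poisson(λ) and each cell independently
realizes the readout with probability p, then P(well positive) =
1 − e^{−λp} and p = −ln(1 − f)/λ for an observed positive fraction f.
The estimate saturates when f approaches 1 − e^{−λ} (p would exceed 1);
it is then clipped to 1 with a warning, and f = 1 is an error because p
is unidentifiable. Division kinetics are cumulative fractions over
day-complete wells only (wells with a missing observation are excluded
and counted). CAFC output is a plain per-input-cell frequency at day
28 — no growth model — with migration inferred from non-migrated cell
counts at 24 h and 48 h.

## Differential chromatin accessibility

Counts are integer fragments per consensus peak region per sample.
Sample QC removes FRiP < 10 %. Normalization for reporting is
count·10⁶/reads-in-peaks; presence calling uses FPKM =
count/(kb · reads-in-peaks/10⁶) with a region "found" in a population
when strictly more than 5 FPKM is seen in at least ⌈n/3⌉ of its
samples ("at least a third" read as a ceiling on sample counts; the
fraction is configurable). Regions found in no population are dropped,
and each differential contrast additionally drops regions found in
neither compared population *before* testing, so the BH family is the
per-contrast tested set.

The test itself is a two-group negative-binomial GLM with log link and
log size-factor offsets, fitted per region by IRLS (vectorized across
regions; the 2×2 normal equations solve in closed form). Size factors
are median-of-ratios over regions positive in all samples, falling back
to reads-in-peaks scaling when fewer than 50 such regions exist.
log₂FC is the group coefficient divided by ln 2; Wald z = coef/SE with
two-sided normal p-values, BH-adjusted. Default significance is
p_adj < 10⁻⁴ for aging contrasts and p_adj < 0.05 for subset contrasts.
Non-converged regions are flagged and given p = 1.

Dispersion (α in Var = μ + αμ²) is estimated per region by maximizing
the Cox–Reid adjusted profile likelihood (group means plugged in; the
−½ log det(XᵀWX) term removes the downward bias of estimated means)
over an 80-point log grid on [10⁻⁸, 100] with quadratic refinement,
then moderated toward a log-linear trend of log α on log mean
normalized count, fitted over regions whose likelihood peaks inside the
grid. Two asymmetric rules complete the estimate: regions whose
likelihood peaks at the grid boundary carry no dispersion information
and receive the trend value outright, and no final estimate is allowed
*below* the trend. The rationale is statistical: with 5-vs-5 samples a
below-trend maximum-likelihood dispersion is overwhelmingly sampling
noise, and propagating it inflates Wald statistics; in null simulations
a symmetric 50/50 blend produced gross anticonservatism (empirical FDR
near 1 at BH 0.05), while the one-sided floor yields near-uniform null
p-values (mean KS ≈ 0.03 at 2000 regions) and empirical FDR within
binomial noise of the nominal level, at ~0.95 sensitivity for planted
log₂FC = 2 effects. Genuinely under-dispersed regions pay a small power
price; that trade is deliberate.

The low-dispersion limit of the Wald statistic is validated against an
exact Poisson GLM (independent implementation) to |Δz| < 0.05.

Clustering of differential regions: rows z-scored, 1 − Pearson
distance, average linkage, tree cut at k (k = 3 for aging clusters,
k = 2 for lineage clusters), labels renumbered by first appearance in
input order. Zero-variance rows cannot enter a correlation distance and
are assigned post hoc to the nearest cluster centroid (Euclidean).
Open-chromatin percentages are 100·found/total per cluster and
population. Lineage-bias DARs are the significant lineage-contrast
regions minus the union (default; intersection available) of the two
within-subset aging DAR sets.

Motif scanning: JASPAR-style PFMs with +0.25 pseudocount per cell,
log-odds against a uniform background, hit when any window on either
strand reaches 80 % of the maximum attainable score; ambiguous bases
contribute zero log-odds. Enrichment is the one-sided binomial tail
P(X ≥ k_target | n_target, p₀ = background hit rate), reported as
−ln p with thresholds 50 (primary) or 10 (secondary screens); a zero
background rate is replaced by an add-one pseudo-background and
flagged. These hit calls are deliberately simple — the enrichment
statistics, not individual hits, are the contract.

Nearest-gene annotation minimizes the distance from TSS to region
midpoint, is 0 for a TSS inside the region, and breaks ties
lexicographically.

## Single-cell expression

QC keeps cells with 50 000–750 000 total reads, < 10 % mitochondrial
and < 10 % ERCC fractions (strict inequalities); every rejection is
logged with the failed clause. Contaminant genes (default CT010467.1)
are removed before the ≤ 400-total-read gene filter, making the cell
and gene filters commute on typical data.

Normalization is per-cell depth scaling to the median depth followed by
log1p. A regularized variance-stabilizing transform is intentionally
not re-implemented: the inferential step that matters — the
likelihood-ratio test — handles the mitochondrial fraction as a model
covariate directly, and the simple transform is deterministic and
exactly invertible, which the test suite exploits.

Differential expression: per gene, logistic regression of group
membership on {normalized expression + mito fraction} against
{mito fraction only}; LR = 2Δℓ referred to χ²(1), BH across genes;
log₂FC is the ratio of group mean normalized expressions with
pseudocount 1 (bounded for zero-expression groups). Perfectly
separating genes are refit with a whisper of L2 (α = 10⁻⁶) to obtain a
finite near-saturated likelihood and flagged `separation`; their LR
statistic is bounded above by −2ℓ_null. Reporting thresholds are
p_adj < 0.01 and |log₂FC| > 1.

Module scores: genes are ranked into 25 equal-occupancy bins of mean
expression; for each bin containing signature genes, up to 100 control
genes are drawn (seeded, without replacement) from the bin's
non-signature genes, and the score is mean(signature) − mean(controls)
per cell. When a bin holds no non-signature gene the bin itself is the
control pool (warned) — this makes the degenerate all-genes signature
score ≈ 0 rather than fail. Binning/control-count defaults follow the
method's original description and are exposed as parameters.

PCA: top 3000 genes by variance/mean dispersion, z-scored, SVD, sign
fixed by making each component's largest-magnitude loading positive.

## Synthetic-data generator: what it emulates

The generator encodes the study conditions as defaults: limiting doses
of 5 HSCs for juvenile/adult donors and 100 for old donors; clone
number per mouse ~ Poisson(dose × engraftment probability 0.1); bias
archetypes M-bi/Bal/L-bi with Dirichlet means (B,T,NK,M) =
(0.15,0.05,0.05,0.75), (0.40,0.15,0.05,0.40), (0.65,0.20,0.05,0.10)
and age×subset mixtures in which juvenile/adult CD49b⁻ mice are mostly
myeloid-biased, CD49b⁺ mostly lymphoid-biased, and old mice shift
myeloid-ward with old CD49b⁺ enriching balanced output. Mouse
composition is a Dirichlet(1)-weighted convex combination of its
clones; the recorded dominant archetype is the largest-weight clone's.
Blood event counts are binomial/multinomial draws from the implied
mixture of donor and host composition, so downstream relative
contributions are unbiased for the planted fractions. Non-engrafted
mice emit uniform background donor signal strictly below the 0.1 %
positivity threshold, keeping negative controls negative by
construction. Chimerism is Beta with mean 0.3 and inverse concentration
0.02 (concentration 50).

Unmanipulated reference cohorts draw compositions from Dirichlet around
(0.40,0.15,0.05,0.40) for adults — i.e. the balanced archetype, L/M
= 1.5 — and (0.25,0.10,0.05,0.60) for old mice (concentration 100), so
the old cohort is strictly more myeloid on average. Archetype-recovery
checks use the adult reference; the archetype means are defined on the
adult scale, so recovery against the old interval is not a meaningful
target.

ATAC counts are NB with region log-means ~ N(4, 1) (natural log,
≈ 55 fragments), dispersion 0.1, per-sample library factors uniform in
[0.7, 1.3], and planted sets receiving per-group log₂ shifts.
Sequences are i.i.d. uniform nucleotides with exact consensus motifs
inserted at uniform positions in planted regions — no GC matching or
dinucleotide structure, so motif *hit-rate* realism is limited; only
relative enrichment is meaningful.

Single-cell counts are multinomial draws over lognormal gene rates at
lognormal depths (median ≈ 150 000 reads); signature genes are drawn
from a well-expressed rate tier so that a natural-log shift of the rate
appears, to good approximation, as the same shift in log1p normalized
expression. Exactly round(fail_fraction·n) cells are forced to violate
one QC clause each; passing cells are guaranteed compliant.

What passing these tests does **not** show: the generators have no
batch structure, no GC or fragment-length biases, no doublets, no
zero-inflation beyond NB/multinomial sampling, and no correlation
between regions or genes. They establish correctness of the inference
machinery under its own model assumptions, not robustness to real-data
artifacts.

## Problem sizes and determinism

Default demonstration sizes (20 mice/group, 2000 regions × 5
samples/group, 150 cells/group × 1500 genes) were chosen so a full
`run_all` completes in well under a minute on one CPU while leaving all
recovery metrics stable; the error-control suite uses 20 independent
2000-region null replicates. Every random draw flows from a single
`numpy.random.default_rng` seed per generator; `run_all` embeds the
package version, seed, and a config hash in every output header and is
bit-identical across reruns of the same configuration.
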