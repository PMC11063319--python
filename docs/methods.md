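# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make runs
reproducible.

## Study design and data model

The package targets paired array studies: the same patients assayed on a
450K-style methylation chip (β = M/(M+U+100) ∈ [0,1], probes annotated
with gene symbol, genic feature, CpG-island relation and Infinium design
type) and an expression chip (raw intensities with per-cell detection
p-values and a many-to-one probe→gene map). Samples carry patient ID,
group (AR case / HC control), season (pollen / non-pollen), sex and a
symptom score; (patient, season) identifies at most one sample per
assay, which is what makes cross-assay matching well defined. Seasons
are analysed as fully independent runs sharing code paths.

## Preprocessing

**Methylation** runs missing-rate filtering, then probe blacklisting,
then probe-type normalization, in that fixed order. The missing filter
drops probes with > 10% missing entries, then samples, and repeats the
sweep to a fixed point: a single two-pass sweep is not idempotent
(removing samples can raise a surviving probe's missing fraction), and
idempotence is the property downstream code relies on. Ties at exactly
10% are kept. The Infinium Type-II beta distribution is compressed
relative to Type I; rather than a full intra-array beta-mixture
recalibration, each sample's Type-II values are quantile-mapped onto its
Type-I empirical distribution. This is a deliberate simplification: it
preserves ranks, keeps β ∈ [0,1], and is the identity when the two
chemistries already agree, but it is not the method reference pipelines
use, so probe-level benchmark counts from published datasets should be
treated as approximate.

**Expression** is background-corrected per sample by subtracting the
mean intensity of probes whose detection p > 0.5, flooring at one
intensity unit, and taking log2. This replaces the normexp-by-control
convolution model used by standard array pipelines with a transparent
monotone transform; the divergence matters only for absolute intensity
levels, not for the rank and contrast structure the screen consumes.
Detection filtering is per study arm: a probe is significant for a group
when detection p < 0.05 in at least half (inclusive) of the group's
samples; non-significant probes are flattened to their within-group mean
so present/absent probes cannot fabricate within-group variance. Probes
then collapse to genes by keeping the probe with the highest mean
expression, ties broken toward the lexicographically smallest probe ID.

## Differential screening

The moderated t-test follows the standard empirical-Bayes construction:
log pooled variances are assumed to scatter around a scaled
inverse-chi-square prior; the prior df d₀ solves
trigamma(d₀/2) = var(e) − mean(trigamma(d_g/2)) with
e_g = log s_g² − digamma(d_g/2) + log(d_g/2), inverted by Newton
iteration (tolerance 1e-8) and capped at 1e6 to represent "infinite";
the prior scale is s₀² = exp(mean(e) + digamma(d₀/2) − log(d₀/2)).
Setting d₀ = 0 recovers the ordinary pooled t exactly, which the test
suite asserts to 1e-10. Tests are nan-aware per feature; features with
zero pooled variance and zero effect get t = 0, p = 1.

Calls gate on raw p < 0.05 (BH-adjusted values are reported alongside
for transparency) and on the adaptive effect threshold
τ = mean(|effect|) + 2·sd(|effect|), with the sample SD (n−1). The
threshold adapts to the effect-size distribution of each dataset, which
also means a handful of extreme effects (e.g. detection-limit dropouts)
inflates τ for everyone — a property of the published criterion, not of
this implementation. Methylation tests run on β values directly
(matching the β-matrix workflow); DMPs additionally require a promoter
feature label (TSS1500, TSS200, 5'UTR, 1stExon).

## CpG–gene integration

Candidate pairs come from the array annotation (a probe is tested only
against its annotated gene); no all-vs-all scan is performed. Spearman's
ρ uses average ranks; the two-sided p-value is the exact permutation
tail over all n! orderings for n ≤ 9 (the matched-sample counts in this
design make the t-approximation questionable there) and the
t-approximation t = ρ√((n−2)/(1−ρ²)) otherwise. Pairs use complete
cases only and are skipped below 4. A called driver pair needs
ρ < −0.4 (strict), p < 0.05, probe ∈ DMPs, gene ∈ DEGs, and direction
consistency: a hypermethylated probe must pair with a downregulated gene
(class `hyper_low`) and vice versa (`hypo_high`); inconsistent pairs are
dropped with a warning — this encodes the post-hoc exclusion a manual
analysis would apply when a gene's correlated probes do not behave as
methylation-driven.

## Enrichment

ORA uses the hypergeometric upper tail P(X ≥ k) with set sizes counted
inside the universe; the universe defaults to all genes on the platform
after collapse. GSEA uses the weighted KS running sum (weight |score|^w,
w = 1 by default); the permutation null randomises gene labels rather
than phenotypes because matched sample counts near 15 give too few
phenotype permutations — a documented divergence from classic GSEA that
makes the null a competitive (gene-sampling) one. NES divides ES by the
mean |ES| of same-sign permutations; the empirical p carries an add-one
correction, so a degenerate null reports p = 1/(n_perm+1); FDR q pools
signed NES across sets in the usual positive/negative convention.

## Co-expression modules

An unsigned network a_ij = |cor|^β on the top-25% MAD genes of the
pollen-season matrix. Outlier samples are removed when their first
merge in an average-linkage tree of standardized profiles exceeds
median + 3·MAD (normal-consistent) of the first-merge heights, floored
at 20% above the median — with tightly clustered heights the MAD
collapses and the unfloored rule flags unremarkable samples; the stage
aborts rather than silently dropping more than a quarter of samples.

The soft threshold is the smallest candidate power whose signed
scale-free fit index R²·sign(−slope) (equal-width binning of the
connectivity distribution, 10 bins) reaches 0.85, falling back to the
argmax. Candidate powers default to 1–12: with the 16–18 samples this
design targets, |cor|^p for larger p amplifies correlation estimation
noise (sampling sd ≈ 0.25) past any real signal and module structure
dissolves; the range is configurable.

Modules are branches of the average-linkage tree on 1 − TOM. A dynamic
branch-cutting heuristic is out of proportion to what the result
consumes, so the cut is static; because the dissimilarity scale
compresses as the power grows, no single fixed fraction of the tallest
merge works across powers, and the default cut is instead chosen by a
deterministic scan over candidate heights for the one yielding the most
branches of at least `min_module_size` (100) genes, preferring the
greatest such height. A fixed `cut_height` can be supplied to override
the scan. Branches below the minimum size are grey; labels follow the
conventional colour sequence by decreasing size. Eigengenes are the
first right singular vector of the standardized module submatrix
(unit-norm over samples, sign-aligned with the module's mean profile),
with variance explained s₁²/Σs². Module–trait and key-gene
correlations are Pearson (the network convention; Spearman is reserved
for the integration stage), with traits encoded AR=1/HC=0, M=0/F=1, and
the signed rule Cor > 0.4 at p < 0.05 taken literally from the
selection criterion; an absolute-value variant is available via
`signed=False`.

## Synthetic data

The generator emulates the study design at desk scale: 8 patients per
arm, each sampled in two seasons (32 samples per assay), 2000 CpG
probes and 2000 genes by default. Background β follows a two-component
Beta mixture (Beta(2,10) / Beta(10,2)) per probe with N(0, 0.05)
per-sample jitter, clipped to [0.01, 0.99]. Planted DMPs shift the case
arm by ±0.3 β units and are promoter-annotated; an equal-size decoy set
receives the same shift with a Body annotation so the promoter criterion
has something to reject. Planted DEGs shift case-arm log2 expression by
±1.5. Driver pairs couple a gene to its CpG via
expression = a − b·probit(β) + ε, with b scaled so the induced group
contrast matches the DEG effect size and the noise SD solved numerically
(Brent's method on a fixed Monte-Carlo draw) so the population Spearman
correlation hits the target (−0.8 by default); the planted correlation
is verified to converge within 0.05 at n = 200 per arm.

Co-expression modules are latent-factor driven with hub-like per-gene
loadings (within-module correlation U(0.3, 0.95) per gene pair factor,
total gene SD 1.0 against a 0.4 background), which gives the roughly
scale-free degree structure the soft-threshold criterion presumes and
lets the MAD filter find module genes the way it does on real data.
Factors are centred within each (group, season) cell and orthogonalised
across modules: planted co-expression carries no case/control contrast
(the planted trait is the symptom score, correlated with the first
module's factor at 0.8). A small set of control-arm dropout genes
(0.2%) falls to background intensity with detection p > 0.5 —
"undetected" must mean background-level signal or the background
estimator itself is poisoned — exercising per-group imputation without
letting a handful of detection-limit effects dominate the adaptive
threshold. Unannotated "empty" probes at background intensity give the
background corrector something to estimate. Missingness is completely
at random (the 10% filter assumes no informative missingness). One seed
drives named RNG streams per component, and output is byte-identical
across runs for a fixed seed.

What the generator does **not** emulate: Infinium chemistry biases
(probe-type effects are planted only implicitly via annotation labels),
batch effects, genomic coordinates, correlated probes within a gene's
promoter, and informative missingness. Passing recovery tests therefore
show the pipeline's statistics behave as designed under the stated
effect sizes — not that real preprocessing artefacts (normalization
residuals, batch structure) are handled.

## Validation scales and expectations

The test suite and `scripts/acceptance.py` run everything at desk
scale, chosen so the full suite completes in a couple of minutes: exact
oracles (ordinary-t equivalence, hypergeometric enumeration, brute-force
GSEA running sums, O(n³) TOM recomputation, rank-formula Spearman);
calibration (type-I error of the moderated test on 20×5000 null
features at n=8+8, GSEA permutation p uniformity over 500 random sets,
driver-pair false positives ≈ 0 under a global-null simulation);
and recovery at the planted effect sizes (driver-pair sensitivity and
precision over 50 seeds, two-block module purity over 20 seeds,
trait-linked module flagging over 50 seeds at n=18, key-gene neighbor
recall at cor 0.7). Published benchmark counts from public accessions
(probe counts after reference QC chains, absolute DMP totals, module
counts of specific cohorts) are not reproduction targets here: they
depend on the exact third-party normalization internals this package
deliberately simplifies.

## Known limitations

No covariate adjustment, batch correction or paired-design contrasts
(the target contrasts are simple two-group); no module merging by
eigengene similarity; no eQTM distance windows (no genomic coordinates
in scope); GSEA's gene-label null understates inter-gene correlation;
and the adaptive mean+2·SD threshold is sensitive to heavy tails in the
effect distribution, as noted above.
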