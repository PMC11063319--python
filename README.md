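# methdriver

Methylation-driven gene discovery from paired DNA-methylation and gene-
expression array data.

Environmental exposures such as seasonal pollen leave marks on DNA
methylation, and promoter methylation tends to repress transcription. In
study designs where the same patients are profiled on a 450K-style
methylation array and an expression array — for example allergic-rhinitis
(AR) patients and healthy controls (HC) sampled in the pollen and
non-pollen seasons — a *methylation-driven gene* is a gene that is
differentially expressed, whose promoter CpG is differentially
methylated, and whose expression is negatively rank-correlated with that
CpG's methylation across patient-matched samples. `methdriver`
implements that screen end to end, for bioinformaticians who want a
tested, scriptable version of the workflow rather than a chain of
one-off R sessions.

## What it computes

**Differential screening.** Per feature, an empirical-Bayes moderated
two-group t-test: with per-feature pooled variance s_g² on d_g residual
df and a prior (d₀, s₀²) fitted by method of moments on log s²,

    s̃_g² = (d₀·s₀² + d_g·s_g²) / (d₀ + d_g),
    t_g = effect_g / (s̃_g·√(1/n₁ + 1/n₂)),  df = d₀ + d_g.

Calls use raw p < 0.05 together with the adaptive effect threshold
τ = mean(|effect|) + 2·sd(|effect|) — |Δβ| > τ for methylation (β =
M/(M+U+100)), |log2FC| > τ for expression — and methylation calls are
restricted to promoter probes (TSS1500, TSS200, 5'UTR, 1stExon).

**Integration.** Samples are matched by (patient, season); every
annotated (CpG, gene) pair is scored with Spearman's ρ (exact
permutation p for n ≤ 9, t-approximation otherwise), and pairs with
ρ < −0.4, p < 0.05, probe ∈ DMPs, gene ∈ DEGs and opposing directions
become *hyper_low* / *hypo_high* driver pairs.

**Enrichment.** Hypergeometric over-representation of gene lists in a
GMT collection, and single-CpG GSEA: genes ranked by correlation with
one CpG, weighted Kolmogorov–Smirnov running sum, gene-label permutation
null, NES and pooled-sign FDR.

**Co-expression modules.** WGCNA-style: top-25% MAD gene filter,
outlier-sample removal, soft-threshold power chosen by the scale-free
fit index R²·sign(−slope) ≥ 0.85, topological overlap
TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), average-linkage
modules (min size 100), eigengenes, module–trait Pearson correlation
(key modules: Cor > 0.4, p < 0.05), and key-gene neighborhoods.

**Synthetic data.** A first-class simulator plants DMPs, DEGs,
negatively correlated driver pairs (noise SD solved numerically to hit a
target Spearman ρ), trait-linked co-expression modules, per-group
detection dropouts and missingness — so every stage can be validated
against known ground truth.

## Worked example

```python
from methdriver import (SimulationConfig, generate_dataset,
                        AnalysisParams, run_analysis)

mset, eset, truth = generate_dataset(SimulationConfig(seed=7))
params = AnalysisParams(seasons=("pollen", "non-pollen"), run_coexpression=False)
results = run_analysis(mset, eset, params=params, seed=7)
pairs = results["seasons"]["pollen"]["pairs"]
print(pairs[["probe", "gene", "rho", "p", "regulation_class"]].head())
```

prints

```
     probe  gene       rho        p regulation_class
cg00000000 G0000 -0.788235 0.000286        hyper_low
cg00000001 G0001 -0.720588 0.001638        hypo_high
cg00000002 G0002 -0.720588 0.001638        hyper_low
cg00000003 G0003 -0.714706 0.001863        hypo_high
cg00000004 G0004 -0.841758 0.000160        hyper_low
```

Each row is a called methylation-driven pair: `hyper_low` means the CpG
is hypermethylated in AR and its gene downregulated, `hypo_high` the
reverse; ρ is the Spearman correlation across the 16 matched samples.
On this seed the screen recovers 14 of the 15 planted driver pairs with
no false calls, and the two seasons share 13 driver genes. The
`examples/` directory walks through every capability
(`01_simulate_and_screen.py` … `05_full_pipeline.py`); a thin CLI
(`methdriver run|simulate|compare`) drives the same code from a shell.

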