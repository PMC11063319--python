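"""Paired methylation/expression simulator with planted ground truth.

The generator emulates the study design the analysis targets: two arms
(cases ``AR`` and controls ``HC``), each patient sampled in a pollen and a
non-pollen season, with a 450K-style beta matrix and an expression-array
intensity matrix over the same patients.  Planted structure:

* background beta values follow a two-component Beta mixture
  (Beta(2, 10) for unmethylated probes, Beta(10, 2) for methylated ones),
  reproducing the bimodal 450K landscape without modelling intensities;
* planted DMPs shift the case-arm mean beta by +-``delta_beta`` and are
  promoter-annotated, while an equally sized decoy set receives the same
  shift but a gene-body annotation (so the promoter criterion has
  something to reject);
* planted DEGs shift case-arm log2 expression by +-``log2fc``;
* driver pairs couple a gene to its CpG through a monotone decreasing
  probit link, expression = a - b * probit(beta) + noise, with the noise
  SD solved numerically so the population Spearman correlation matches
  ``driver_cor``;
* co-expression modules share a latent per-sample factor through
  hub-like per-gene loadings (pairwise within-module correlation ~0.6 on
  average, approximating the scale-free topology co-expression methods
  presume) and the first module's factor is correlated with the
  symptom-score trait at ``trait_module_cor``;
* a small block of annotation-free "empty" probes stays at background
  intensity with high detection p-values, giving the background corrector
  something to estimate, and a few background genes drop out of the
  control arm to exercise per-group detection filtering;
* missingness is completely at random at ``missing_rate``.

One seed drives a hierarchy of named RNG streams (one per component), so
the draws for one component do not depend on the sizes of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import ndtri

from . import io as _io
from .datatypes import (
    ExpressionSet,
    ISLAND_LABELS,
    MethylationSet,
    SEASONS,
    SampleSheet,
)
from .errors import ValidationError

BETA_NOISE_SD = 0.05
EXPR_NOISE_SD = 0.4
MODULE_GENE_SD = 1.0
PROMOTER_CYCLE = ("TSS200", "TSS1500", "5'UTR", "1stExon")
BACKGROUND_FEATURE_P = (0.14, 0.10, 0.10, 0.08, 0.31, 0.07, 0.20)
BACKGROUND_FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")

_STREAMS = (
    "samples",
    "meth",
    "planted_meth",
    "expr",
    "planted_expr",
    "driver",
    "modules",
    "detection",
    "missing",
    "annotation",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated paired dataset.

    Defaults are the conditions the recovery analyses are run under:
    8 samples per arm per season, a 0.3 beta-unit methylation shift, a
    1.5 log2-unit expression shift, driver pairs at Spearman -0.8, and
    120-gene co-expression modules whose lead factor correlates with the
    symptom score at 0.8.
    """

    n_probes_meth: int = 2000
    n_genes: int = 2000
    n_per_group: int = 8
    n_planted_dmps: int = 30
    delta_beta: float = 0.3
    n_planted_degs: int = 30
    log2fc: float = 1.5
    n_driver_pairs: int = 15
    driver_cor: float = -0.8
    n_modules: int = 3
    module_size: int = 120
    trait_module_cor: float = 0.8
    missing_rate: float = 0.02
    seed: int = 0
    emit_intensities: bool = False

    def __post_init__(self) -> None:
        for name in (
            "n_probes_meth",
            "n_genes",
            "n_per_group",
            "n_planted_dmps",
            "n_planted_degs",
            "n_driver_pairs",
            "n_modules",
            "module_size",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2 for two-group testing")
        if self.n_driver_pairs > min(self.n_planted_dmps, self.n_planted_degs):
            raise ValidationError(
                "n_driver_pairs must not exceed min(n_planted_dmps, n_planted_degs)"
            )
        if not (-1.0 < self.driver_cor <= 0.0):
            raise ValidationError("driver_cor must lie in (-1, 0]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.delta_beta <= 0.7:
            raise ValidationError("delta_beta must lie in [0, 0.7] (beta stays inside [0, 1])")
        if self.log2fc < 0:
            raise ValidationError("log2fc must be >= 0")
        if not -1.0 <= self.trait_module_cor <= 1.0:
            raise ValidationError("trait_module_cor must lie in [-1, 1]")
        if self.n_probes_meth < 2 * self.n_planted_dmps:
            raise ValidationError(
                "n_probes_meth must be >= 2 * n_planted_dmps (planted plus decoy probes)"
            )
        if self.n_genes < self.n_planted_degs + self.n_modules * self.module_size:
            raise ValidationError(
                "n_genes must cover n_planted_degs + n_modules * module_size"
            )


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    dmp_ids: set[str]
    deg_ids: set[str]
    driver_pairs: list[tuple[str, str]]
    module_membership: dict[str, int]
    trait_values: dict[str, float]

    def __post_init__(self) -> None:
        for probe, gene in self.driver_pairs:
            if probe not in self.dmp_ids or gene not in self.deg_ids:
                raise ValidationError(f"driver pair ({probe}, {gene}) outside dmp_ids x deg_ids")
        mods = sorted(set(self.module_membership.values()))
        if mods and mods != list(range(len(mods))):
            raise ValidationError("module indices must be contiguous from 0")


def _solve_driver_noise(
    base: float,
    direction: float,
    delta: float,
    b: float,
    target: float,
    rng: np.random.Generator,
    n_mc: int = 3000,
) -> float:
    """Noise SD giving the target population Spearman for one driver pair.

    A fixed Monte-Carlo draw from the pair's generative law makes the
    Spearman correlation a smooth decreasing-magnitude function of the
    noise SD; the root is bracketed and solved with Brent's method.
    """
    group = np.repeat([0.0, 1.0], n_mc // 2)
    bm = np.clip(
        base + direction * delta * group + rng.normal(0.0, BETA_NOISE_SD, group.size),
        0.01,
        0.99,
    )
    e0 = -b * ndtri(np.clip(bm, 1e-4, 1 - 1e-4))
    z = rng.standard_normal(group.size)

    def gap(s: float) -> float:
        return stats.spearmanr(bm, e0 + s * z).statistic - target

    if gap(1e-9) >= 0:
        return 1e-9
    hi = max(abs(b), 0.1)
    while gap(hi) < 0 and hi < 1e4:
        hi *= 2.0
    return float(brentq(gap, 1e-9, hi, xtol=1e-4, rtol=1e-4))


def generate_dataset(
    config: SimulationConfig,
) -> tuple[MethylationSet, ExpressionSet, TruthTable]:
    """Generate one paired dataset; deterministic given ``config.seed``."""
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, np.random.SeedSequence(config.seed).spawn(len(_STREAMS)))
    }
    n = config.n_per_group
    patients = [f"AR{i + 1:02d}" for i in range(n)] + [f"HC{i + 1:02d}" for i in range(n)]
    pat_groups = ["AR"] * n + ["HC"] * n
    sexes = rngs["samples"].choice(["M", "F"], size=len(patients))

    meth_rows, expr_rows = [], []
    for season in SEASONS:
        tag = season.replace("-", "")
        for pat, grp, sx in zip(patients, pat_groups, sexes):
            meth_rows.append((f"M_{pat}_{tag}", pat, grp, season, sx))
            expr_rows.append((f"E_{pat}_{tag}", pat, grp, season, sx))
    ns = len(meth_rows)  # same for both assays, column j matched across assays
    ar_cols = np.array([r[2] == "AR" for r in meth_rows])

    # ---- latent module factors and the symptom-score trait -------------
    # factors are centred within each (group, season) cell (module
    # programs carry no case/control contrast; the trait link is the
    # symptom score) and orthogonalised across modules
    F = rngs["modules"].standard_normal((max(config.n_modules, 1), ns))
    cells = {}
    for j, row in enumerate(meth_rows):
        cells.setdefault((row[2], row[3]), []).append(j)
    for cols in cells.values():
        F[:, cols] -= F[:, cols].mean(axis=1, keepdims=True)
    q, _r = np.linalg.qr(F.T)
    F = q.T[: F.shape[0]] * np.sqrt(ns)
    rho_t = config.trait_module_cor
    trait_noise = rngs["samples"].standard_normal(ns)
    if config.n_modules > 0:
        symptom_z = rho_t * F[0] + np.sqrt(max(1.0 - rho_t**2, 0.0)) * trait_noise
    else:
        symptom_z = trait_noise
    symptom = 5.0 + 2.0 * symptom_z

    def _sheet(rows: list[tuple]) -> SampleSheet:
        df = pd.DataFrame(
            rows, columns=["sample_id", "patient_id", "group", "season", "sex"]
        ).set_index("sample_id")
        df["symptom_score"] = symptom
        return SampleSheet(df)

    meth_sheet = _sheet(meth_rows)
    expr_sheet = _sheet(expr_rows)

    # ---- methylation ---------------------------------------------------
    P = config.n_probes_meth
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(P)], name="probe_id")
    mrng = rngs["meth"]
    high = mrng.random(P) < 0.5
    base = np.where(high, mrng.beta(10, 2, P), mrng.beta(2, 10, P))

    n_dmp = config.n_planted_dmps
    planted_idx = np.arange(n_dmp)
    decoy_idx = np.arange(n_dmp, 2 * n_dmp)
    signs = np.where(np.arange(n_dmp) % 2 == 0, 1.0, -1.0)
    prng = rngs["planted_meth"]
    delta = config.delta_beta
    for idx_block in (planted_idx, decoy_idx):
        hyper = signs > 0
        lo = np.where(hyper, 0.20, 0.05 + delta)
        hi = np.where(hyper, 0.95 - delta, 0.80)
        base[idx_block] = prng.uniform(lo, hi)
    mean_beta = np.repeat(base[:, None], ns, axis=1)
    ar_pos = np.flatnonzero(ar_cols)
    if n_dmp:
        mean_beta[np.ix_(planted_idx, ar_pos)] += (signs * delta)[:, None]
        mean_beta[np.ix_(decoy_idx, ar_pos)] += (signs * delta)[:, None]
    beta = np.clip(mean_beta + mrng.normal(0.0, BETA_NOISE_SD, (P, ns)), 0.01, 0.99)

    # ---- expression ----------------------------------------------------
    G = config.n_genes
    gene_ids = pd.Index([f"G{i:04d}" for i in range(G)], name="gene")
    erng = rngs["expr"]
    mu = np.clip(erng.normal(8.0, 1.5, G), 6.0, 14.0)
    x = mu[:, None] + erng.normal(0.0, EXPR_NOISE_SD, (G, ns))

    # module genes: hub-like structure with per-gene loadings l_g = sqrt(c_g),
    # c_g ~ U(0.3, 0.95); the wide loading spread yields the roughly
    # scale-free degree distribution the soft-threshold fit presumes
    # (pairwise within-module correlation ~0.6 on average); total SD fixed
    # at MODULE_GENE_SD, above background, which is what lets the MAD
    # filter find module genes
    mrng_mod = rngs["modules"]
    mod_start = config.n_planted_degs
    module_membership: dict[str, int] = {}
    for m in range(config.n_modules):
        rows = slice(mod_start + m * config.module_size, mod_start + (m + 1) * config.module_size)
        l = np.sqrt(mrng_mod.uniform(0.3, 0.95, config.module_size))
        noise = mrng_mod.standard_normal((config.module_size, ns))
        x[rows] = mu[rows, None] + MODULE_GENE_SD * (
            l[:, None] * F[m][None, :] + np.sqrt(1.0 - l**2)[:, None] * noise
        )
        for gidx in gene_ids[rows]:
            module_membership[gidx] = m

    n_deg = config.n_planted_degs
    n_driver = config.n_driver_pairs
    for i in range(n_driver, n_deg):
        d = 1.0 if i % 2 == 0 else -1.0
        x[i, ar_pos] += d * config.log2fc

    drng = rngs["driver"]
    driver_pairs: list[tuple[str, str]] = []
    for k in range(n_driver):
        probe_row = int(planted_idx[k])
        d = float(signs[k])
        b0 = float(base[probe_row])
        shifted = float(np.clip(b0 + d * delta, 0.01, 0.99))
        denom = abs(ndtri(np.clip(shifted, 1e-4, 1 - 1e-4)) - ndtri(np.clip(b0, 1e-4, 1 - 1e-4)))
        if config.driver_cor == 0.0:
            b_link, sigma = 0.0, EXPR_NOISE_SD
        else:
            if denom > 1e-9 and config.log2fc > 0:
                b_link = config.log2fc / denom
            else:
                b_link = 1.0
            sigma = _solve_driver_noise(b0, d, delta, b_link, config.driver_cor, drng)
        z = drng.standard_normal(ns)
        link = b_link * (ndtri(np.clip(b0, 1e-4, 1 - 1e-4)) - ndtri(np.clip(beta[probe_row], 1e-4, 1 - 1e-4)))
        x[k] = mu[k] + link + sigma * z
        driver_pairs.append((str(probe_ids[probe_row]), str(gene_ids[k])))

    # ---- probes, intensities, detection p-values -----------------------
    arng = rngs["annotation"]
    n_dup = G // 10
    dup_gene_idx = np.sort(arng.choice(G, size=n_dup, replace=False)) if n_dup else np.array([], dtype=int)
    n_empty = max(20, G // 20) if G else 0
    primary_ids = [f"ILMN_{1000000 + i}" for i in range(G)]
    dup_ids = [f"ILMN_{2000000 + i}" for i in range(n_dup)]
    empty_ids = [f"ILMN_{3000000 + i}" for i in range(n_empty)]

    det = rngs["detection"]
    # a few background genes drop out of the control arm: undetected there
    # means background-level intensity, not full signal
    background_pool = np.arange(mod_start + config.n_modules * config.module_size, G)
    # dropouts fall to true background level in controls ("undetected"
    # must mean background, or the background estimator is poisoned);
    # they are rare so they exercise per-group imputation without
    # dominating the adaptive log2FC threshold
    n_dropout = len(background_pool) // 500
    dropout_rows = (
        det.choice(background_pool, size=n_dropout, replace=False) if n_dropout else np.array([], dtype=int)
    )
    hc_pos = np.flatnonzero(~ar_cols)
    if n_dropout:
        x[np.ix_(dropout_rows, hc_pos)] = 4.0 + det.normal(0.0, 0.3, (n_dropout, hc_pos.size))

    x_dup = x[dup_gene_idx] - 1.5 + erng.normal(0.0, 0.2, (n_dup, ns)) if n_dup else np.empty((0, ns))
    x_empty = 4.0 + erng.normal(0.0, 0.3, (n_empty, ns))
    intensity = 2.0 ** np.vstack([x, x_dup, x_empty]) if G or n_empty else np.empty((0, ns))

    p_signal = det.uniform(5e-4, 0.04, (G + n_dup, ns))
    p_empty = det.uniform(0.55, 0.99, (n_empty, ns))
    detection_p = np.vstack([p_signal, p_empty]) if G or n_empty else np.empty((0, ns))
    if n_dropout:
        detection_p[np.ix_(dropout_rows, hc_pos)] = det.uniform(0.55, 1.0, (n_dropout, hc_pos.size))

    probe_index = pd.Index(primary_ids + dup_ids + empty_ids, name="probe_id")
    probe_to_gene = pd.Series(
        list(gene_ids) + [gene_ids[i] for i in dup_gene_idx] + [np.nan] * n_empty,
        index=probe_index,
        name="gene",
    )

    # ---- missingness (completely at random) ----------------------------
    if config.missing_rate > 0:
        miss = rngs["missing"]
        beta[miss.random(beta.shape) < config.missing_rate] = np.nan
        intensity[miss.random(intensity.shape) < config.missing_rate] = np.nan

    # ---- methylation probe annotation ----------------------------------
    gene_of_probe = arng.choice(np.asarray(gene_ids), P) if G else np.array([""] * P)
    feature = arng.choice(BACKGROUND_FEATURES, P, p=BACKGROUND_FEATURE_P)
    island = arng.choice(ISLAND_LABELS, P)
    design = arng.choice(["I", "II"], P, p=[0.28, 0.72])
    for k in range(n_dmp):
        feature[planted_idx[k]] = PROMOTER_CYCLE[k % len(PROMOTER_CYCLE)]
        feature[decoy_idx[k]] = "Body"
    for k in range(n_driver):
        gene_of_probe[planted_idx[k]] = gene_ids[k]
    annotation = pd.DataFrame(
        {"gene": gene_of_probe, "feature": feature, "island": island, "design_type": design},
        index=probe_ids,
    )

    beta_df = pd.DataFrame(beta, index=probe_ids, columns=[r[0] for r in meth_rows])
    meth_kwargs = {}
    if config.emit_intensities:
        u = mrng.lognormal(mean=np.log(1000.0), sigma=0.35, size=beta.shape)
        with np.errstate(invalid="ignore"):
            m_int = beta * (u + 100.0) / (1.0 - beta)
        meth_kwargs = {
            "meth": pd.DataFrame(m_int, index=probe_ids, columns=beta_df.columns),
            "unmeth": pd.DataFrame(u, index=probe_ids, columns=beta_df.columns),
        }
    mset = MethylationSet(beta=beta_df, annotation=annotation, samples=meth_sheet, **meth_kwargs)

    expr_df = pd.DataFrame(intensity, index=probe_index, columns=[r[0] for r in expr_rows])
    detp_df = pd.DataFrame(detection_p, index=probe_index, columns=expr_df.columns)
    eset = ExpressionSet(
        expr=expr_df,
        detection_p=detp_df,
        probe_to_gene=probe_to_gene,
        samples=expr_sheet,
        log2_scale=False,
    )

    truth = TruthTable(
        dmp_ids={str(p) for p in probe_ids[planted_idx]},
        deg_ids={str(g) for g in gene_ids[:n_deg]},
        driver_pairs=driver_pairs,
        module_membership=module_membership,
        trait_values={r[0]: float(s) for r, s in zip(expr_rows, symptom)},
    )
    return mset, eset, truth


def _synthetic_gene_sets(truth: TruthTable, all_genes: list[str], decoy_sets: int = 5) -> dict:
    """One GMT set per planted module plus shuffled decoy sets."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    by_module: dict[int, list[str]] = {}
    for gene, m in truth.module_membership.items():
        by_module.setdefault(m, []).append(gene)
    for m in sorted(by_module):
        sets[f"module_{m}"] = ("planted co-expression module", tuple(sorted(by_module[m])))
    pool = sorted(set(all_genes) - set(truth.module_membership))
    rng = np.random.default_rng(12345)  # decoys fixed across datasets
    size = min(len(pool), max(20, len(by_module.get(0, [])) or 50))
    for d in range(decoy_sets):
        if len(pool) < 5:
            break
        pick = rng.choice(pool, size=min(size, len(pool)), replace=False)
        sets[f"decoy_{d}"] = ("random decoy set", tuple(sorted(map(str, pick))))
    return sets


def write_dataset(
    dataset: tuple[MethylationSet, ExpressionSet, TruthTable],
    directory: str | Path,
) -> dict[str, Path]:
    """Write a simulated dataset as TSV matrices plus a GMT file.

    The files round-trip losslessly through :func:`read_dataset`.
    """
    mset, eset, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["meth_beta"] = _io.write_matrix(mset.beta, directory / "meth_beta.tsv", "probe_id")
    paths["meth_annotation"] = _io.write_annotation(mset.annotation, directory / "meth_annotation.tsv")
    paths["meth_samples"] = _io.write_sample_sheet(mset.samples, directory / "meth_samples.tsv")
    if mset.meth is not None:
        paths["meth_M"] = _io.write_matrix(mset.meth, directory / "meth_M.tsv", "probe_id")
        paths["meth_U"] = _io.write_matrix(mset.unmeth, directory / "meth_U.tsv", "probe_id")
    paths["expr_matrix"] = _io.write_matrix(eset.expr, directory / "expr_matrix.tsv", "probe_id")
    paths["expr_detection_p"] = _io.write_matrix(
        eset.detection_p, directory / "expr_detection_p.tsv", "probe_id"
    )
    paths["expr_probe_gene"] = _io.write_probe_gene_map(
        eset.probe_to_gene, directory / "expr_probe_gene.tsv"
    )
    paths["expr_samples"] = _io.write_sample_sheet(eset.samples, directory / "expr_samples.tsv")

    rows = (
        [("dmp", p, "") for p in sorted(truth.dmp_ids)]
        + [("deg", g, "") for g in sorted(truth.deg_ids)]
        + [("pair", p, g) for p, g in truth.driver_pairs]
        + [("module", g, str(m)) for g, m in sorted(truth.module_membership.items())]
        + [("trait", s, repr(v)) for s, v in sorted(truth.trait_values.items())]
    )
    truth_df = pd.DataFrame(rows, columns=["kind", "a", "b"])
    paths["truth"] = directory / "truth.tsv"
    truth_df.to_csv(paths["truth"], sep="\t", index=False)

    genes = sorted({str(g) for g in eset.probe_to_gene.dropna()})
    paths["gene_sets"] = _io.write_gmt(
        _synthetic_gene_sets(truth, genes), directory / "gene_sets.gmt"
    )
    return paths


def read_dataset(directory: str | Path) -> tuple[MethylationSet, ExpressionSet, TruthTable]:
    """Read a dataset previously written by :func:`write_dataset`."""
    directory = Path(directory)
    beta = _io.read_matrix(directory / "meth_beta.tsv")
    annotation = _io.read_annotation(directory / "meth_annotation.tsv")
    meth_sheet = _io.read_sample_sheet(directory / "meth_samples.tsv")
    kwargs = {}
    if (directory / "meth_M.tsv").exists():
        kwargs["meth"] = _io.read_matrix(directory / "meth_M.tsv")
        kwargs["unmeth"] = _io.read_matrix(directory / "meth_U.tsv")
    mset = MethylationSet(beta=beta, annotation=annotation, samples=meth_sheet, **kwargs)

    expr = _io.read_matrix(directory / "expr_matrix.tsv")
    detp = _io.read_matrix(directory / "expr_detection_p.tsv")
    mapping = _io.read_probe_gene_map(directory / "expr_probe_gene.tsv")
    expr_sheet = _io.read_sample_sheet(directory / "expr_samples.tsv")
    eset = ExpressionSet(
        expr=expr, detection_p=detp, probe_to_gene=mapping, samples=expr_sheet, log2_scale=False
    )

    truth_df = pd.read_csv(directory / "truth.tsv", sep="\t", dtype=str).fillna("")
    truth = TruthTable(
        dmp_ids=set(truth_df.loc[truth_df["kind"] == "dmp", "a"]),
        deg_ids=set(truth_df.loc[truth_df["kind"] == "deg", "a"]),
        driver_pairs=[
            (r.a, r.b) for r in truth_df[truth_df["kind"] == "pair"].itertuples()
        ],
        module_membership={
            r.a: int(r.b) for r in truth_df[truth_df["kind"] == "module"].itertuples()
        },
        trait_values={
            r.a: float(r.b) for r in truth_df[truth_df["kind"] == "trait"].itertuples()
        },
    )
    return mset, eset, truth
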