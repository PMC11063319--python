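"""End-to-end orchestration of the per-season analysis.

Stage order is fixed: methylation preprocessing, expression
preprocessing, per-season differential screening (methylation and
expression), CpG-gene integration, season comparison, enrichment, and a
co-expression module stage on the pollen-season expression matrix.  The
run manifest records the counts a study report would table: probes
surviving each filter, DMP/DEG calls, scored and called pairs, shared and
season-unique driver genes, modules and key modules.

Only the GSEA permutation null consumes randomness; one global seed is
expanded into named per-stage streams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from . import io as _io
from .coexpress import (
    CoexpressionResult,
    NetworkConfig,
    coexpression_analysis,
    key_gene_neighbors,
)
from .datatypes import ExpressionSet, MethylationSet
from .differential import (
    PROMOTER_FEATURES,
    adaptive_threshold,
    annotate_calls,
    call_degs,
    call_dmps,
    moderated_ttest,
)
from .enrich import GeneSetCollection, gsea_run, ora_hypergeometric, rank_by_cpg
from .errors import ValidationError
from .expr import preprocess_expression
from .integrate import (
    call_driver_pairs,
    compare_gene_sets,
    correlate_pairs,
    match_samples,
)
from .meth import preprocess_methylation

logger = logging.getLogger(__name__)

_SEX_CODE = {"M": 0.0, "F": 1.0}
_GROUP_CODE = {"HC": 0.0, "AR": 1.0}


@dataclass
class AnalysisParams:
    """All tunable thresholds, at their study defaults."""

    alpha_dmp: float = 0.05
    alpha_deg: float = 0.05
    alpha_pair: float = 0.05
    rho_max: float = -0.4
    max_missing: float = 0.10
    normalize_probes: bool = True
    beta_offset: float = 100.0
    detection_alpha: float = 0.05
    detection_fraction: float = 0.5
    promoter_features: frozenset = PROMOTER_FEATURES
    exact_max_n: int = 9
    network: NetworkConfig = field(default_factory=NetworkConfig)
    trait_cor_min: float = 0.4
    trait_alpha: float = 0.05
    signed_cor: bool = True
    gsea_permutations: int = 1000
    weight_exponent: float = 1.0
    seasons: tuple[str, ...] = ("pollen", "non-pollen")
    coexpress_season: str = "pollen"
    run_coexpression: bool = True
    run_gsea: bool = True


def _encode_traits(sheet: pd.DataFrame) -> pd.DataFrame:
    """Numeric trait table: group AR=1/HC=0, sex M=0/F=1, symptom score."""
    return pd.DataFrame(
        {
            "group": sheet["group"].map(_GROUP_CODE),
            "sex": sheet["sex"].map(_SEX_CODE),
            "symptom_score": pd.to_numeric(sheet["symptom_score"], errors="coerce"),
        },
        index=sheet.index,
    )


def _candidate_map(annotation: pd.DataFrame, probes: Iterable[str]) -> pd.Series:
    genes = annotation["gene"].reindex(list(probes)).dropna()
    genes = genes[genes.astype(str).str.len() > 0]
    return genes.astype(str)


def run_analysis(
    mset: MethylationSet,
    eset: ExpressionSet,
    params: AnalysisParams | None = None,
    gene_sets: GeneSetCollection | None = None,
    blacklist: Iterable[str] | None = None,
    seed: int = 0,
) -> dict[str, Any]:
    """Run the full in-memory analysis; returns a results dictionary.

    Keys: ``meth`` (preprocessed set), ``gene_expr`` (collapsed log2
    matrix), ``seasons`` (per-season dict with differential tables, call
    tables, scored and called pairs, ORA), ``overlap`` (driver-gene
    comparison between seasons), ``coexpression``, ``key_gene`` and
    ``manifest`` (flat counts).
    """
    params = params or AnalysisParams()
    results: dict[str, Any] = {"params": params}
    manifest: dict[str, Any] = {"seed": seed, "probes_input": int(mset.beta.shape[0])}

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("stage: %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and isinstance(exc, ValidationError):
                    raise ValidationError(f"[stage {name}] {exc}") from exc
                return False

        return _Ctx()

    with stage("meth_preprocess"):
        meth, report = preprocess_methylation(
            mset,
            blacklist=blacklist,
            max_missing=params.max_missing,
            normalize=params.normalize_probes,
            beta_offset=params.beta_offset,
        )
    manifest["probes_after_missing"] = int(mset.beta.shape[0]) - len(report.dropped_features)
    manifest["meth_samples_after_missing"] = int(mset.beta.shape[1]) - len(report.dropped_samples)
    manifest["probes_after_blacklist"] = int(meth.beta.shape[0])
    results["meth"] = meth

    with stage("expr_preprocess"):
        gene_expr, significant = preprocess_expression(
            eset,
            detection_alpha=params.detection_alpha,
            detection_fraction=params.detection_fraction,
        )
    manifest["expr_probes_input"] = int(eset.expr.shape[0])
    manifest["genes_after_collapse"] = int(gene_expr.shape[0])
    for grp, probes in sorted(significant.items()):
        manifest[f"significant_probes_{grp.replace('/', '_')}"] = len(probes)
    results["gene_expr"] = gene_expr
    results["significant_probes"] = significant

    results["seasons"] = {}
    driver_genes_by_season: dict[str, set[str]] = {}
    for season in params.seasons:
        with stage(f"differential[{season}]"):
            season_out = _season_analysis(meth, eset, gene_expr, season, params, gene_sets)
        results["seasons"][season] = season_out
        driver_genes_by_season[season] = set(season_out["pairs"]["gene"]) if len(season_out["pairs"]) else set()
        manifest[f"matched_samples_{season}"] = season_out["match"].n_pairs
        manifest[f"dmps_stat_{season}"] = int(season_out["n_dmps_stat"])
        manifest[f"dmps_{season}"] = int(len(season_out["dmps"]))
        deg_dirs = season_out["degs"]["direction"]
        manifest[f"degs_{season}"] = int(len(season_out["degs"]))
        manifest[f"degs_up_{season}"] = int((deg_dirs == "up").sum())
        manifest[f"degs_down_{season}"] = int((deg_dirs == "down").sum())
        manifest[f"scored_pairs_{season}"] = int(len(season_out["scored"]))
        manifest[f"called_pairs_{season}"] = int(len(season_out["pairs"]))
        manifest[f"driver_genes_{season}"] = len(driver_genes_by_season[season])

    if len(params.seasons) == 2:
        a, b = params.seasons
        overlap = compare_gene_sets(
            driver_genes_by_season[a], driver_genes_by_season[b], labels=(a, b)
        )
        results["overlap"] = overlap
        for key, count in overlap.counts.items():
            manifest[f"driver_gene_{key}"] = count

    if params.run_coexpression:
        with stage("coexpress"):
            season = params.coexpress_season
            cols = [
                s
                for s in eset.samples.select(season=season)
                if s in gene_expr.columns
            ]
            traits = _encode_traits(eset.samples.data.loc[cols])
            coex = coexpression_analysis(
                gene_expr[cols],
                traits,
                config=params.network,
                cor_min=params.trait_cor_min,
                alpha=params.trait_alpha,
                signed=params.signed_cor,
            )
        results["coexpression"] = coex
        manifest["coexpress_power"] = coex.power
        manifest["modules"] = len(coex.assignment.modules)
        manifest["key_modules"] = len(coex.key_modules)

        with stage("key_gene"):
            key_info = _key_gene_analysis(results, meth, eset, gene_expr, params, gene_sets, seed)
        results["key_gene"] = key_info
        manifest["key_gene"] = key_info.get("gene", "")
        manifest["key_gene_neighbors"] = key_info.get("n_neighbors", 0)

    results["manifest"] = manifest
    return results


def _season_analysis(
    meth: MethylationSet,
    eset: ExpressionSet,
    gene_expr: pd.DataFrame,
    season: str,
    params: AnalysisParams,
    gene_sets: GeneSetCollection | None,
) -> dict[str, Any]:
    meth_cols = [s for s in meth.samples.select(season=season) if s in meth.beta.columns]
    if not meth_cols:
        raise ValidationError(f"no methylation samples for season {season!r}")
    beta = meth.beta[meth_cols]
    mlabels = meth.samples.group_labels(meth_cols)
    meth_res = moderated_ttest(beta, mlabels)
    thr_m = adaptive_threshold(meth_res["effect"])
    dmps = call_dmps(
        meth_res,
        meth.annotation,
        threshold=thr_m,
        alpha=params.alpha_dmp,
        promoter_features=params.promoter_features,
    )
    flagged = annotate_calls(meth_res, thr_m, params.alpha_dmp, meth.annotation, params.promoter_features)
    n_dmps_stat = int((flagged["passes_p"] & flagged["passes_effect"]).sum())

    expr_cols = [s for s in eset.samples.select(season=season) if s in gene_expr.columns]
    if not expr_cols:
        raise ValidationError(f"no expression samples for season {season!r}")
    elabels = eset.samples.group_labels(expr_cols)
    expr_res = moderated_ttest(gene_expr[expr_cols], elabels)
    thr_e = adaptive_threshold(expr_res["effect"])
    degs = call_degs(expr_res, threshold=thr_e, alpha=params.alpha_deg)

    meth_sheet = meth.samples.data.loc[meth_cols]
    expr_sheet = eset.samples.data.loc[expr_cols]
    match = match_samples(meth_sheet, expr_sheet)
    candidates = _candidate_map(meth.annotation, beta.index)
    scored = correlate_pairs(
        beta, gene_expr, candidates, match, exact_max_n=params.exact_max_n
    )
    pairs = call_driver_pairs(
        scored, dmps, degs, rho_max=params.rho_max, alpha=params.alpha_pair, season=season
    )

    ora = None
    if gene_sets is not None and len(pairs):
        ora = ora_hypergeometric(set(pairs["gene"]), gene_sets, set(gene_expr.index))

    return {
        "meth_results": meth_res,
        "meth_threshold": thr_m,
        "dmps": dmps,
        "n_dmps_stat": n_dmps_stat,
        "expr_results": expr_res,
        "expr_threshold": thr_e,
        "degs": degs,
        "match": match,
        "scored": scored,
        "pairs": pairs,
        "ora": ora,
    }


def _key_gene_analysis(
    results: dict[str, Any],
    meth: MethylationSet,
    eset: ExpressionSet,
    gene_expr: pd.DataFrame,
    params: AnalysisParams,
    gene_sets: GeneSetCollection | None,
    seed: int,
) -> dict[str, Any]:
    """Pick the strongest driver pair of the co-expression season and
    characterise its gene: module neighborhood plus single-CpG GSEA."""
    season = params.coexpress_season
    season_out = results["seasons"].get(season)
    coex: CoexpressionResult = results["coexpression"]
    if season_out is None or len(season_out["pairs"]) == 0:
        return {"gene": "", "n_neighbors": 0}
    pairs = season_out["pairs"].sort_values("rho")
    labels = coex.assignment.labels
    key_modules = set(coex.key_modules)
    chosen = None
    for row in pairs.itertuples():
        module = labels.get(row.gene)
        if module is not None and module in key_modules:
            chosen = row
            break
    if chosen is None:
        chosen = next(pairs.itertuples())
    gene, probe = chosen.gene, chosen.probe
    module = labels.get(gene)

    out: dict[str, Any] = {"gene": gene, "probe": probe, "module": module, "n_neighbors": 0}
    if module is not None and module != "grey":
        module_genes = [g for g in coex.assignment.genes_in(module) if g in gene_expr.index]
        module_expr = gene_expr.loc[module_genes, coex.retained_samples]
        neighbors = key_gene_neighbors(
            module_expr,
            gene,
            cor_min=params.trait_cor_min,
            alpha=params.trait_alpha,
            signed=params.signed_cor,
        )
        out["neighbors"] = neighbors
        out["n_neighbors"] = int(len(neighbors))
        if gene_sets is not None and len(neighbors):
            out["neighbor_ora"] = ora_hypergeometric(
                set(neighbors["gene"]) | {gene}, gene_sets, set(gene_expr.index)
            )

    if params.run_gsea and gene_sets is not None:
        match = season_out["match"]
        usable = [
            (m, e)
            for m, e in zip(match.pairs["meth_sample"], match.pairs["expr_sample"])
            if m in meth.beta.columns and e in gene_expr.columns
        ]
        if len(usable) >= 4 and probe in meth.beta.index:
            cpg = pd.Series(
                meth.beta.loc[probe, [m for m, _ in usable]].to_numpy(),
                index=[e for _, e in usable],
            )
            try:
                scores = rank_by_cpg(cpg, gene_expr[[e for _, e in usable]])
                gsea_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
                out["gsea"] = gsea_run(
                    scores,
                    gene_sets,
                    n_perm=params.gsea_permutations,
                    seed=gsea_seed,
                    weight_exponent=params.weight_exponent,
                )
            except ValidationError as exc:
                logger.warning("single-CpG GSEA skipped: %s", exc)
    return out


def external_comparison(
    deg_table_a: pd.DataFrame,
    deg_table_b: pd.DataFrame,
    driver_genes: Iterable[str],
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Presence/direction of each driver gene in two external DEG tables.

    Each DEG table is a call table indexed by gene with a ``direction``
    column (``up``/``down``).  Genes absent from both vocabularies are
    reported as unmatched.
    """
    rows = []
    for gene in sorted(set(driver_genes)):
        in_a = gene in deg_table_a.index
        in_b = gene in deg_table_b.index
        dir_a = str(deg_table_a.loc[gene, "direction"]) if in_a else ""
        dir_b = str(deg_table_b.loc[gene, "direction"]) if in_b else ""
        if in_a and in_b:
            verdict = f"concordant {dir_a}" if dir_a == dir_b else "discordant"
        elif in_a or in_b:
            verdict = f"{labels[0] if in_a else labels[1]}_only"
        else:
            verdict = "absent"
        rows.append((gene, in_a, dir_a, in_b, dir_b, verdict))
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            f"in_{labels[0]}",
            f"direction_{labels[0]}",
            f"in_{labels[1]}",
            f"direction_{labels[1]}",
            "verdict",
        ],
    )


@dataclass
class PipelineConfig:
    """File-based pipeline run description (flat YAML mapping on disk)."""

    meth_beta: str
    meth_annotation: str
    meth_samples: str
    expr_matrix: str
    expr_detection_p: str
    expr_probe_gene: str
    expr_samples: str
    output_dir: str
    blacklist: str | None = None
    gene_sets: str | None = None
    seed: int = 0
    params: AnalysisParams = field(default_factory=AnalysisParams)

    _PATH_FIELDS = (
        "meth_beta",
        "meth_annotation",
        "meth_samples",
        "expr_matrix",
        "expr_detection_p",
        "expr_probe_gene",
        "expr_samples",
    )

    def validate(self) -> None:
        for name in self._PATH_FIELDS:
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValidationError(f"input file for {name!r} does not exist: {p}")
        for name in ("blacklist", "gene_sets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input file for {name!r} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = _io.read_config(path)
        param_names = {f.name for f in fields(AnalysisParams)}
        net_names = {f.name for f in fields(NetworkConfig)}
        params_kw = {}
        net_kw = {}
        top_kw = {}
        for key, value in raw.items():
            if key in ("seasons",) and isinstance(value, list):
                value = tuple(value)
            if key in ("promoter_features",) and isinstance(value, list):
                value = frozenset(value)
            if key in ("candidate_powers",) and isinstance(value, list):
                value = tuple(value)
            if key in net_names:
                net_kw[key] = value
            elif key in param_names:
                params_kw[key] = value
            else:
                top_kw[key] = value
        params = AnalysisParams(**params_kw)
        if net_kw:
            params.network = NetworkConfig(**{**_net_defaults(), **net_kw})
        unknown = set(top_kw) - {f.name for f in fields(cls) if f.name != "params"}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(params=params, **top_kw)


def _net_defaults() -> dict:
    return {f.name: getattr(NetworkConfig(), f.name) for f in fields(NetworkConfig)}


def _load_inputs(config: PipelineConfig) -> tuple[MethylationSet, ExpressionSet]:
    mset = MethylationSet(
        beta=_io.read_matrix(config.meth_beta),
        annotation=_io.read_annotation(config.meth_annotation),
        samples=_io.read_sample_sheet(config.meth_samples),
    )
    eset = ExpressionSet(
        expr=_io.read_matrix(config.expr_matrix),
        detection_p=_io.read_matrix(config.expr_detection_p),
        probe_to_gene=_io.read_probe_gene_map(config.expr_probe_gene),
        samples=_io.read_sample_sheet(config.expr_samples),
        log2_scale=False,
    )
    return mset, eset


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """File-in, file-out pipeline run; returns the manifest.

    Writes per-stage TSVs, ``manifest.json`` (sorted keys, no timestamps,
    so identical configs give byte-identical manifests) and a plain-text
    log of parameters into the output directory.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    mset, eset = _load_inputs(config)
    blacklist = _io.read_blacklist(config.blacklist) if config.blacklist else None
    gene_sets = GeneSetCollection.from_gmt(config.gene_sets) if config.gene_sets else None

    results = run_analysis(
        mset, eset, params=config.params, gene_sets=gene_sets, blacklist=blacklist, seed=config.seed
    )

    for season, out in results["seasons"].items():
        tag = season.replace("-", "_")
        _write_result_table(out["meth_results"], out["meth_threshold"], outdir / f"meth_results_{tag}.tsv")
        _write_result_table(out["expr_results"], out["expr_threshold"], outdir / f"expr_results_{tag}.tsv")
        out["dmps"].to_csv(outdir / f"dmps_{tag}.tsv", sep="\t", index_label="probe_id")
        out["degs"].to_csv(outdir / f"degs_{tag}.tsv", sep="\t", index_label="gene")
        out["scored"].to_csv(outdir / f"scored_pairs_{tag}.tsv", sep="\t", index=False)
        out["pairs"].to_csv(outdir / f"driver_pairs_{tag}.tsv", sep="\t", index=False)
        if out["ora"] is not None:
            out["ora"].to_csv(outdir / f"ora_{tag}.tsv", sep="\t", index=False)
    if "overlap" in results:
        results["overlap"].to_frame().to_csv(outdir / "driver_gene_overlap.tsv", sep="\t", index=False)
    if "coexpression" in results:
        coex: CoexpressionResult = results["coexpression"]
        coex.assignment.labels.to_frame().to_csv(outdir / "module_assignment.tsv", sep="\t", index_label="gene")
        coex.eigengenes.to_csv(outdir / "module_eigengenes.tsv", sep="\t", index_label="module")
        coex.trait_table.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
        coex.fit_table.to_csv(outdir / "soft_threshold_fit.tsv", sep="\t", index=False)
    key_info = results.get("key_gene", {})
    if key_info.get("n_neighbors"):
        key_info["neighbors"].to_csv(outdir / "key_gene_neighbors.tsv", sep="\t", index=False)
    if "gsea" in key_info:
        key_info["gsea"].table.to_csv(outdir / "key_cpg_gsea.tsv", sep="\t", index=False)

    manifest = results["manifest"]
    manifest["parameters"] = _params_record(config.params)
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2, default=str) + "\n")
    (outdir / "run_log.txt").write_text(
        "\n".join(
            [
                "methdriver pipeline run",
                f"seed: {config.seed}",
                f"seasons: {list(config.params.seasons)}",
                f"parameters: {json.dumps(_params_record(config.params), sort_keys=True, default=str)}",
            ]
        )
        + "\n"
    )
    return manifest


def _params_record(params: AnalysisParams) -> dict:
    rec = asdict(params)
    rec["promoter_features"] = sorted(params.promoter_features)
    rec["seasons"] = list(params.seasons)
    rec["network"]["candidate_powers"] = list(params.network.candidate_powers)
    return rec


def _write_result_table(results: pd.DataFrame, threshold, path: Path) -> None:
    out = results.copy()
    out["passes_p"] = out["p"] < 0.05
    out["passes_effect"] = out["effect"].abs() > threshold.tau
    out.to_csv(path, sep="\t", index_label="feature")
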