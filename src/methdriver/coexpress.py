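"""Weighted co-expression network analysis.

A signed-magnitude ("unsigned") network is built from gene expression:
adjacency a_ij = |cor(i, j)|^power, with the soft-threshold power chosen
as the smallest candidate whose degree distribution approximates a
scale-free law (signed fit index R^2 * sign(-slope) >= the target,
default 0.85).  Topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

credits shared neighborhoods; modules are branches of an average-linkage
tree on 1 - TOM cut at a fixed height, with branches smaller than
``min_module_size`` assigned the ``grey`` label.  Each module is
summarised by its eigengene (first principal component of the
standardized module submatrix) and related to sample traits by Pearson
correlation; modules with cor above a threshold at p < alpha are "key"
modules, and a key gene's neighborhood is every module gene correlated
with it beyond the same threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: conventional module colour sequence, assigned by decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "skyblue", "saddlebrown", "steelblue",
)

GREY = "grey"


@dataclass
class NetworkConfig:
    # powers beyond ~12 amplify correlation estimation noise past the
    # signal at the small sample sizes this analysis targets
    candidate_powers: tuple[int, ...] = tuple(range(1, 13))
    r2_target: float = 0.85
    min_module_size: int = 100
    mad_top_fraction: float = 0.25
    cut_height: float | None = None  # None -> cut_fraction of the tallest merge
    cut_fraction: float = 0.995
    n_bins: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.r2_target < 1:
            raise ValidationError("r2_target must lie in (0, 1)")
        if any(p <= 0 for p in self.candidate_powers):
            raise ValidationError("candidate powers must be positive")
        if self.min_module_size < 1:
            raise ValidationError("min_module_size must be >= 1")
        if not 0 < self.mad_top_fraction <= 1:
            raise ValidationError("mad_top_fraction must lie in (0, 1]")


def mad_filter(expr: pd.DataFrame, top_fraction: float = 0.25) -> pd.DataFrame:
    """Keep the ceil(top_fraction * G) genes with the largest MAD.

    Median absolute deviation is the unscaled median |x - median(x)| per
    gene; ties are broken by gene ID so the selection is deterministic.
    """
    if expr.shape[0] < 4:
        raise ValidationError("mad_filter needs at least 4 genes")
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must lie in (0, 1]")
    vals = expr.to_numpy(dtype=float)
    med = np.nanmedian(vals, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(vals - med), axis=1)
    k = int(np.ceil(top_fraction * expr.shape[0]))
    order = sorted(range(expr.shape[0]), key=lambda i: (-mad[i], str(expr.index[i])))
    keep = sorted(order[:k], key=lambda i: i)  # preserve input row order
    return expr.iloc[keep].copy()


def good_genes(expr: pd.DataFrame, impute: bool = True) -> pd.DataFrame:
    """Drop zero-variance genes; optionally mean-impute residual NaN."""
    out = expr
    if impute and out.isna().any().any():
        means = out.mean(axis=1)
        out = out.apply(lambda row: row.fillna(means[row.name]), axis=1)
    sd = out.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("good_genes: dropped %d zero-variance genes", dropped)
    return out.loc[keep].copy()


def remove_outlier_samples(
    expr: pd.DataFrame,
    cut: float | None = None,
    max_drop_fraction: float = 0.25,
) -> list[str]:
    """Retained sample IDs after hierarchical-clustering outlier removal.

    Samples are average-linkage clustered on the Euclidean distance of
    their standardized expression profiles; a sample is an outlier when
    the height at which it first merges exceeds ``cut`` (default: median
    first-merge height + 3 * normal-consistent MAD of those heights, but
    never less than 20% above the median -- with tightly clustered
    heights the MAD collapses and a purely MAD-based rule would flag
    unremarkable samples).  Aborts when more than ``max_drop_fraction``
    of samples would go.
    """
    n = expr.shape[1]
    if n < 4:
        raise ValidationError("remove_outlier_samples needs at least 4 samples")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1, keepdims=True, ddof=0)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd
    Z = linkage(z.T, method="average", metric="euclidean")

    first_merge = np.zeros(n)
    cluster_members: dict[int, list[int]] = {i: [i] for i in range(n)}
    assigned = np.zeros(n, dtype=bool)
    for step, (a, b, height, _size) in enumerate(Z):
        members = cluster_members[int(a)] + cluster_members[int(b)]
        for leaf in (int(a), int(b)):
            if leaf < n and not assigned[leaf]:
                first_merge[leaf] = height
                assigned[leaf] = True
        cluster_members[n + step] = members
    if cut is None:
        med = float(np.median(first_merge))
        mad = float(stats.median_abs_deviation(first_merge, scale="normal"))
        cut = max(med + 3.0 * mad, 1.20 * med)
    outliers = first_merge > cut
    if outliers.sum() > max_drop_fraction * n:
        raise ValidationError(
            f"outlier cut would drop {int(outliers.sum())}/{n} samples "
            f"(> {max_drop_fraction:.0%}); inspect the data instead"
        )
    if outliers.any():
        logger.info("dropping outlier samples: %s", list(expr.columns[outliers]))
    return [c for c, o in zip(expr.columns, outliers) if not o]


def _correlation(expr: pd.DataFrame) -> np.ndarray:
    vals = expr.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("expression matrix contains NaN; run good_genes first")
    cor = np.corrcoef(vals)
    if not np.isfinite(cor).all():
        raise ValidationError("correlation undefined (constant gene); run good_genes first")
    return cor


def adjacency(expr: pd.DataFrame, power: int) -> pd.DataFrame:
    """Unsigned adjacency |cor|^power with zero diagonal."""
    cor = _correlation(expr)
    a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit: R^2 * sign(-slope) of log10 p(k) on log10 k.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins
    are dropped.  Returns (index, slope); NaN index when fewer than three
    usable bins remain.
    """
    k = np.asarray(k, dtype=float)
    k = k[np.isfinite(k) & (k > 0)]
    if k.size < 3 or np.ptp(k) == 0:
        return np.nan, np.nan
    counts, edges = np.histogram(k, bins=n_bins)
    centers = []
    freqs = []
    for i, c in enumerate(counts):
        if c == 0:
            continue
        in_bin = (k >= edges[i]) & (k <= edges[i + 1] if i == n_bins - 1 else k < edges[i + 1])
        centers.append(float(np.mean(k[in_bin])))
        freqs.append(c / k.size)
    if len(centers) < 3:
        return np.nan, np.nan
    x = np.log10(np.asarray(centers))
    y = np.log10(np.asarray(freqs))
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r * np.sign(-slope)), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    config: NetworkConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power for an approximately scale-free net.

    For each candidate power the adjacency connectivities k_i are
    computed and the signed scale-free fit index evaluated; the smallest
    power reaching the R^2 target wins, falling back to the argmax of the
    index when none reaches it.  Returns the power and the full fit table
    (power, fit_index, slope, mean_k, median_k, max_k).
    """
    config = config or NetworkConfig()
    if expr.shape[0] < 50:
        raise ValidationError("pick_soft_threshold needs at least 50 genes")
    cor = np.abs(_correlation(expr))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for power in config.candidate_powers:
        a = cor**power
        k = a.sum(axis=1)
        index, slope = scale_free_fit_index(k, n_bins=config.n_bins)
        rows.append((power, index, slope, float(k.mean()), float(np.median(k)), float(k.max())))
    table = pd.DataFrame(rows, columns=["power", "fit_index", "slope", "mean_k", "median_k", "max_k"])
    reaching = table[table["fit_index"] >= config.r2_target]
    if len(reaching):
        power = int(reaching["power"].iloc[0])
    else:
        power = int(table.loc[table["fit_index"].fillna(-np.inf).idxmax(), "power"])
        logger.warning("no power reached fit index %.2f; using argmax power %d", config.r2_target, power)
    return power, table


def tom_similarity(adjacency_matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix from an adjacency with zero diagonal."""
    a = adjacency_matrix.to_numpy(dtype=float) if isinstance(adjacency_matrix, pd.DataFrame) else np.asarray(adjacency_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if np.abs(a - a.T).max() > 1e-10:
        raise ValidationError("adjacency must be symmetric within 1e-10")
    if np.nanmin(a) < 0 or np.nanmax(a) > 1:
        raise ValidationError("adjacency values must lie in [0, 1]")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValidationError("adjacency diagonal must be zero")
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    tom = (tom + tom.T) / 2.0
    if isinstance(adjacency_matrix, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency_matrix.index, columns=adjacency_matrix.columns)
    return tom


@dataclass
class ModuleAssignment:
    """Gene -> module colour labels plus module bookkeeping."""

    labels: pd.Series
    sizes: dict[str, int] = field(default_factory=dict)
    cut_height: float = np.nan

    @property
    def modules(self) -> list[str]:
        return [m for m in self.sizes if m != GREY]

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _scan_cut_height(Z: np.ndarray, min_size: int, top: float) -> float:
    """Deterministic static-cut height: most modules >= min_size, ties high."""
    if len(Z) == 0:
        return top
    heights = np.unique(Z[:, 2])
    heights = heights[heights <= top]
    if heights.size == 0:
        return top
    # candidate cuts sit between consecutive merge heights
    mids = np.concatenate([(heights[:-1] + heights[1:]) / 2.0, [top]])
    best_cut = top
    best_count = -1
    for h in mids:
        labels = fcluster(Z, t=h, criterion="distance")
        counts = np.bincount(labels)
        n_modules = int((counts >= min_size).sum())
        if n_modules >= best_count:  # >= prefers the greatest height
            best_count = n_modules
            best_cut = float(h)
    return best_cut


def detect_modules(
    tom: pd.DataFrame,
    config: NetworkConfig | None = None,
) -> ModuleAssignment:
    """Static tree cut of the average-linkage dendrogram on 1 - TOM.

    Branches at the cut height with at least ``min_module_size`` genes
    become modules, labelled with the conventional colour sequence by
    decreasing size; everything else is ``grey``.  When ``cut_height`` is
    not fixed in the config, the cut is chosen deterministically by
    scanning candidate heights (up to ``cut_fraction`` of the tallest
    merge) for the one yielding the most modules of the minimum size,
    preferring the greatest such height; a single fixed fraction is
    brittle across soft-threshold powers because the dissimilarity scale
    compresses as the power grows.
    """
    config = config or NetworkConfig()
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    max_height = float(Z[:, 2].max()) if len(Z) else 0.0
    if config.cut_height is not None:
        cut = config.cut_height
    else:
        cut = _scan_cut_height(Z, config.min_module_size, config.cut_fraction * max_height)
    raw = fcluster(Z, t=cut, criterion="distance")
    genes = tom.index

    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= config.min_module_size]
    # order modules by size, ties by smallest member gene ID
    def _tiebreak(cluster_id: int) -> str:
        members = genes[raw == cluster_id]
        return min(str(g) for g in members)

    ordered = sorted(big.index, key=lambda c: (-big[c], _tiebreak(c)))
    color_of = {c: MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module_{i}" for i, c in enumerate(ordered)}
    labels = pd.Series([color_of.get(c, GREY) for c in raw], index=genes, name="module")
    size_map = labels.value_counts().to_dict()
    if not ordered:
        logger.warning("no branch reached min_module_size=%d; all genes grey", config.min_module_size)
    return ModuleAssignment(labels=labels, sizes=size_map, cut_height=cut)


def module_eigengenes(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component per module, unit-norm over samples.

    Gene rows are standardized before the SVD; the eigengene sign is
    aligned so it correlates positively with the module's average
    standardized profile.  Returns (eigengenes modules x samples,
    variance explained per module).
    """
    eigengenes = {}
    varexpl = {}
    for module in assignment.modules:
        member_genes = assignment.genes_in(module)
        sub = expr.loc[[g for g in member_genes if g in expr.index]]
        if sub.shape[0] == 0:
            continue
        vals = sub.to_numpy(dtype=float)
        sd = vals.std(axis=1, keepdims=True, ddof=0)
        keep = sd[:, 0] > 0
        if not keep.any():
            logger.warning("module %s has only constant genes; skipped", module)
            continue
        z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep]
        _u, s, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        mean_profile = z.mean(axis=0)
        align = float(np.dot(v, mean_profile))
        if align < 0 or (align == 0 and v[np.argmax(np.abs(v) > 0)] < 0):
            v = -v
        eigengenes[module] = v
        varexpl[module] = float(s[0] ** 2 / np.sum(s**2))
    eg = pd.DataFrame(eigengenes, index=expr.columns).T
    return eg, pd.Series(varexpl, name="variance_explained")


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    cor_min: float = 0.4,
    alpha: float = 0.05,
    signed: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each numeric trait.

    Key modules satisfy cor > ``cor_min`` (signed, the literal reading of
    the selection rule; set ``signed=False`` for |cor|) together with
    p < ``alpha``.  Constant traits are skipped with a warning.
    """
    samples = [s for s in eigengenes.columns if s in traits.index]
    if len(samples) < 4:
        raise ValidationError("module_trait_correlation needs >= 4 shared samples")
    rows = []
    for trait in traits.columns:
        t = traits.loc[samples, trait].to_numpy(dtype=float)
        ok = np.isfinite(t)
        if ok.sum() < 4 or np.nanstd(t) == 0:
            logger.warning("trait %s constant or too sparse; skipped", trait)
            continue
        for module in eigengenes.index:
            e = eigengenes.loc[module, samples].to_numpy(dtype=float)
            r, p = stats.pearsonr(e[ok], t[ok])
            passed = (r > cor_min if signed else abs(r) > cor_min) and p < alpha
            rows.append((module, trait, float(r), float(p), bool(passed)))
    out = pd.DataFrame(rows, columns=["module", "trait", "cor", "p", "is_key"])
    return out.astype({"cor": float, "p": float, "is_key": bool})


def key_gene_neighbors(
    module_expr: pd.DataFrame,
    key_gene: str,
    cor_min: float = 0.4,
    alpha: float = 0.05,
    signed: bool = True,
) -> pd.DataFrame:
    """Module genes correlated with the key gene beyond the threshold.

    The key gene itself is excluded from the returned list (add it back
    for downstream enrichment when desired).
    """
    if key_gene not in module_expr.index:
        raise ValidationError(
            f"key gene {key_gene!r} not among the {module_expr.shape[0]} genes of the module searched"
        )
    target = module_expr.loc[key_gene].to_numpy(dtype=float)
    rows = []
    for gene in module_expr.index:
        if gene == key_gene:
            continue
        r, p = stats.pearsonr(module_expr.loc[gene].to_numpy(dtype=float), target)
        passed = (r > cor_min if signed else abs(r) > cor_min) and p < alpha
        if passed:
            rows.append((gene, float(r), float(p)))
    return pd.DataFrame(rows, columns=["gene", "cor", "p"]).sort_values(
        "cor", ascending=False
    ).reset_index(drop=True)


@dataclass
class CoexpressionResult:
    power: int
    fit_table: pd.DataFrame
    assignment: ModuleAssignment
    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    trait_table: pd.DataFrame
    retained_samples: list[str]

    @property
    def key_modules(self) -> list[str]:
        if len(self.trait_table) == 0:
            return []
        keys = self.trait_table.loc[self.trait_table["is_key"], "module"]
        return sorted(set(keys))


def coexpression_analysis(
    expr: pd.DataFrame,
    traits: pd.DataFrame,
    config: NetworkConfig | None = None,
    power: int | None = None,
    cor_min: float = 0.4,
    alpha: float = 0.05,
    signed: bool = True,
) -> CoexpressionResult:
    """Full module pipeline: filter, soft threshold, TOM, modules, traits."""
    config = config or NetworkConfig()
    clean = good_genes(expr)
    filtered = mad_filter(clean, top_fraction=config.mad_top_fraction)
    retained = remove_outlier_samples(filtered)
    filtered = filtered[retained]
    filtered = good_genes(filtered)
    if power is None:
        power, fit_table = pick_soft_threshold(filtered, config)
    else:
        _, fit_table = pick_soft_threshold(filtered, config)
    adj = adjacency(filtered, power)
    tom = tom_similarity(adj)
    assignment = detect_modules(tom, config)
    eigengenes, varexpl = module_eigengenes(filtered, assignment)
    if len(eigengenes):
        trait_table = module_trait_correlation(
            eigengenes, traits, cor_min=cor_min, alpha=alpha, signed=signed
        )
    else:
        trait_table = pd.DataFrame(
            columns=["module", "trait", "cor", "p", "is_key"]
        ).astype({"cor": float, "p": float, "is_key": bool})
    return CoexpressionResult(
        power=power,
        fit_table=fit_table,
        assignment=assignment,
        eigengenes=eigengenes,
        variance_explained=varexpl,
        trait_table=trait_table,
        retained_samples=retained,
    )
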