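"""Over-representation analysis and single-CpG GSEA.

ORA uses the upper tail of the hypergeometric distribution: with a
universe of N genes of which K belong to a set, and a query of n genes
with overlap k, p = P(X >= k), X ~ Hypergeom(N, K, n), with
Benjamini-Hochberg adjustment across the collection.

The single-CpG GSEA ranks every gene by the Spearman correlation of its
expression with one CpG's beta values and runs the weighted
Kolmogorov-Smirnov statistic along that ranking: walking the list, the
running sum gains |score|^w / sum_set(|score|^w) on set members and loses
1/(L - |set|) otherwise; the enrichment score (ES) is the extremum of
largest magnitude.  Significance comes from gene-label permutation of the
ranking (the set positions are randomised), which is the practical null
when the matched sample count is too small for phenotype permutation.
NES divides ES by the mean magnitude of same-sign permutation scores; FDR
follows the usual pooled positive/negative convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from . import io as _io

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[str, tuple[str, ...]]] = {}
        for name, (desc, genes) in self.sets.items():
            members = tuple(dict.fromkeys(g for g in genes if g))
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            cleaned[name] = (desc, members)
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        return cls(_io.read_gmt(path))

    def to_gmt(self, path) -> None:
        _io.write_gmt(self.sets, path)


def ora_hypergeometric(
    query: Iterable[str],
    collection: GeneSetCollection | Mapping[str, tuple[str, tuple[str, ...]]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    The query is intersected with the universe (dropped IDs are logged);
    set sizes K are counted within the universe, and sets absent from the
    universe are skipped.  Rows come back sorted by p then set name.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("universe is empty")
    q_raw = set(query)
    if not q_raw:
        raise ValidationError("query gene list is empty")
    q = q_raw & uni
    dropped = q_raw - uni
    if dropped:
        logger.info("ORA: %d query genes outside the universe dropped", len(dropped))
    if not q:
        raise ValidationError("no query genes remain inside the universe")
    sets = collection.sets if isinstance(collection, GeneSetCollection) else dict(collection)
    N = len(uni)
    n = len(q)
    rows = []
    for name, (_desc, genes) in sets.items():
        members = set(genes) & uni
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(q & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(max(p, 0.0), 1.0), ";".join(overlap)))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "overlap_genes"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["p", "set"]).reset_index(drop=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def rank_by_cpg(
    cpg_beta: pd.Series,
    expr: pd.DataFrame,
    samples: Sequence[str] | None = None,
) -> pd.Series:
    """Rank genes by Spearman correlation with one CpG's beta values.

    Returns a Series of correlations indexed by gene, sorted descending
    with ties broken by gene ID for determinism.
    """
    if samples is None:
        samples = [s for s in expr.columns if s in cpg_beta.index]
    samples = list(samples)
    if len(samples) < 4:
        raise ValidationError("rank_by_cpg needs at least 4 shared samples")
    x = cpg_beta.loc[samples].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        keep = np.isfinite(x)
        samples = [s for s, k in zip(samples, keep) if k]
        if len(samples) < 4:
            raise ValidationError("rank_by_cpg needs at least 4 complete samples")
        x = cpg_beta.loc[samples].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValidationError("CpG beta values are constant across samples; ranks undefined")
    rx = stats.rankdata(x)
    rx = (rx - rx.mean()) / rx.std()
    E = expr[samples].to_numpy(dtype=float)
    RE = np.apply_along_axis(stats.rankdata, 1, E)
    RE = RE - RE.mean(axis=1, keepdims=True)
    sd = RE.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (RE @ rx) / (len(samples) * np.where(sd > 0, sd, np.nan))
    scores = pd.Series(rho, index=expr.index, name="rho").dropna()
    order = sorted(scores.index, key=lambda gidx: (-scores[gidx], str(gidx)))
    return scores.loc[order]


def _validate_set(scores: pd.Series, gene_set: Iterable[str]) -> np.ndarray:
    members = set(gene_set)
    mask = scores.index.isin(members)
    if not mask.any():
        raise ValidationError("gene set does not intersect the ranked list")
    if mask.all():
        raise ValidationError("gene set covers the entire ranked list; ES undefined")
    return mask


def gsea_es(
    scores: pd.Series,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running-sum profile.

    ``scores`` must be the ranking metric sorted descending.  The running
    sum telescopes back to zero at the end of the list; ES is the value
    of largest magnitude along the way.
    """
    mask = _validate_set(scores, gene_set)
    s = scores.to_numpy(dtype=float)
    w = np.abs(s) ** weight_exponent
    total = w[mask].sum()
    if total <= 0:
        w = np.ones_like(w)
        total = w[mask].sum()
    L = len(s)
    n_miss = L - int(mask.sum())
    inc = np.where(mask, w / total, -1.0 / n_miss)
    running = np.cumsum(inc)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_from_positions(weights: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ES for many hit-position sets.

    ``positions`` is (m, S) of 0-based ranks.  Returns (es, argmax hit
    index per row) using the fact that the running-sum extrema occur
    immediately after a hit (maxima) or immediately before one (minima).
    """
    pos = np.sort(positions, axis=1)
    w = weights[pos]
    tot = w.sum(axis=1, keepdims=True)
    uniform = tot[:, 0] <= 0
    if uniform.any():
        w[uniform] = 1.0
        tot = w.sum(axis=1, keepdims=True)
    L = weights.shape[0]
    S = pos.shape[1]
    n_miss = L - S
    if n_miss <= 0:
        raise ValidationError("gene set covers the entire ranked list; ES undefined")
    j = np.arange(S)[None, :]
    gap = (pos - j) / n_miss
    cw = np.cumsum(w, axis=1) / tot
    after = cw - gap
    before = after - w / tot
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    take_hi = hi >= -lo
    es = np.where(take_hi, hi, lo)
    arg = np.where(take_hi, after.argmax(axis=1), before.argmin(axis=1))
    return es, arg


@dataclass
class GseaResult:
    table: pd.DataFrame
    leading_edges: dict[str, list[str]]


def gsea_run(
    scores: pd.Series,
    collection: GeneSetCollection | Mapping[str, tuple[str, tuple[str, ...]]],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> GseaResult:
    """GSEA over a collection with a gene-label permutation null.

    Deterministic given ``seed``.  Per set: observed ES, NES = ES divided
    by the mean |ES| of same-sign permutations, an empirical one-tail p
    with add-one correction (a degenerate null with no same-sign
    permutation yields p = 1/(n_perm + 1), i.e. "< 1/n_perm"), and an FDR
    q-value from the pooled signed-NES convention.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    sets = collection.sets if isinstance(collection, GeneSetCollection) else dict(collection)
    rng = np.random.default_rng(seed)
    s = scores.to_numpy(dtype=float)
    weights = np.abs(s) ** weight_exponent
    L = len(s)

    rows = []
    leading: dict[str, list[str]] = {}
    null_nes_pool: list[np.ndarray] = []
    for name, (_desc, genes) in sets.items():
        mask = _validate_set(scores, genes)
        S = int(mask.sum())
        obs_pos = np.flatnonzero(mask)[None, :]
        es_obs, arg_obs = _es_from_positions(weights, obs_pos)
        es = float(es_obs[0])

        keys = rng.random((n_perm, L))
        perm_pos = np.argpartition(keys, S - 1, axis=1)[:, :S]
        null_es, _ = _es_from_positions(weights, perm_pos)

        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        mean_pos = float(pos_null.mean()) if pos_null.size else np.nan
        mean_neg = float(np.abs(neg_null).mean()) if neg_null.size else np.nan
        fallback = float(np.abs(null_es).mean()) if null_es.size else 1.0

        if es >= 0:
            denom = mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else fallback
            same = pos_null
        else:
            denom = mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else fallback
            same = neg_null
        nes = es / denom if denom > 0 else np.nan
        n_same = same.size
        exceed = int(np.sum(np.abs(same) >= abs(es) - 1e-12))
        p = (1 + exceed) / (1 + n_same) if n_same else 1.0 / (n_perm + 1)

        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes = np.where(
                null_es >= 0,
                null_es / (mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else fallback),
                null_es / (mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else fallback),
            )
        null_nes_pool.append(null_nes)

        sorted_pos = np.sort(np.flatnonzero(mask))
        j_star = int(arg_obs[0])
        if es >= 0:
            le_positions = sorted_pos[: j_star + 1]
        else:
            le_positions = sorted_pos[j_star:]
        leading[name] = [str(scores.index[i]) for i in le_positions]
        rows.append((name, S, es, nes, p))

    table = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p"])
    table["fdr_q"] = _gsea_fdr(table["nes"].to_numpy(), np.concatenate(null_nes_pool) if null_nes_pool else np.array([]))
    table = table.sort_values(["p", "set"]).reset_index(drop=True)
    return GseaResult(table=table, leading_edges=leading)


def _gsea_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Pooled-null FDR with the positive/negative NES split."""
    q = np.full(obs_nes.shape, np.nan)
    for sign in (1, -1):
        sel = (obs_nes >= 0) if sign > 0 else (obs_nes < 0)
        if not sel.any():
            continue
        null_side = null_nes[null_nes >= 0] if sign > 0 else null_nes[null_nes < 0]
        obs_side = obs_nes[sel]
        for i, nes in zip(np.flatnonzero(sel), obs_side):
            if not np.isfinite(nes):
                q[i] = np.nan
                continue
            if null_side.size:
                frac_null = np.mean(np.abs(null_side) >= abs(nes))
            else:
                frac_null = 0.0
            frac_obs = np.mean(np.abs(obs_side) >= abs(nes))
            q[i] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else np.nan
    return q
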