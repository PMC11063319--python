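"""CpG-gene integration: sample matching, correlation, driver-pair calls.

Samples from the two assays are matched by (patient, season).  For every
candidate (probe, gene) pair from the array annotation, the Spearman rank
correlation between the probe's beta values and the gene's expression
across matched samples is computed; methylation-driven pairs are those
with rho < -0.4 and p < 0.05 whose probe is a called DMP and whose gene a
called DEG.  A hypermethylated probe must pair with a downregulated gene
(class ``hyper_low``) and a hypomethylated probe with an upregulated one
(``hypo_high``); inconsistent pairs are dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SampleSheet
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MatchResult:
    """Matched (methylation sample, expression sample) pairs by patient."""

    pairs: pd.DataFrame  # columns: patient_id, season, meth_sample, expr_sample
    unmatched_meth: list[str] = field(default_factory=list)
    unmatched_expr: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _as_sheet_frame(sheet: SampleSheet | pd.DataFrame, assay: str) -> pd.DataFrame:
    df = sheet.data if isinstance(sheet, SampleSheet) else sheet
    for col in ("patient_id", "season"):
        if col not in df.columns:
            raise ValidationError(f"{assay} sheet is missing column {col!r}")
    dup = df.duplicated(subset=["patient_id", "season"])
    if dup.any():
        offenders = df.loc[dup, ["patient_id", "season"]].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (patient, season) in {assay} sheet: {offenders}")
    return df


def match_samples(
    meth_sheet: SampleSheet | pd.DataFrame,
    expr_sheet: SampleSheet | pd.DataFrame,
) -> MatchResult:
    """Pair methylation and expression samples sharing (patient, season)."""
    mdf = _as_sheet_frame(meth_sheet, "methylation")
    edf = _as_sheet_frame(expr_sheet, "expression")
    mkey = {(r.patient_id, r.season): idx for idx, r in mdf.iterrows()}
    ekey = {(r.patient_id, r.season): idx for idx, r in edf.iterrows()}
    shared = sorted(set(mkey) & set(ekey), key=lambda k: (str(k[0]), str(k[1])))
    pairs = pd.DataFrame(
        {
            "patient_id": [k[0] for k in shared],
            "season": [k[1] for k in shared],
            "meth_sample": [mkey[k] for k in shared],
            "expr_sample": [ekey[k] for k in shared],
        }
    )
    unmatched_meth = [mkey[k] for k in sorted(set(mkey) - set(ekey), key=str)]
    unmatched_expr = [ekey[k] for k in sorted(set(ekey) - set(mkey), key=str)]
    if not shared:
        logger.warning("no (patient, season) keys shared between assays")
    if unmatched_meth or unmatched_expr:
        logger.info(
            "unmatched samples: %d methylation, %d expression",
            len(unmatched_meth),
            len(unmatched_expr),
        )
    return MatchResult(pairs=pairs, unmatched_meth=unmatched_meth, unmatched_expr=unmatched_expr)


@lru_cache(maxsize=8)
def _permutation_indices(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def spearman_pair(
    x: np.ndarray,
    y: np.ndarray,
    exact_max_n: int = 9,
) -> tuple[float, float, int]:
    """Spearman rho with average ranks and a two-sided p-value.

    Complete cases only.  For n <= ``exact_max_n`` the p-value is the
    exact permutation tail probability P(|rho_perm| >= |rho|) over all n!
    orderings of one variable; otherwise the usual t-approximation
    t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 df is used.

    Returns (rho, p, n_complete); rho is NaN when either variable is
    constant or fewer than 4 complete cases remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4:
        return np.nan, np.nan, n
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan, n
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    if n <= exact_max_n:
        perms = _permutation_indices(n)
        ry_c = ry - ry.mean()
        null = (ry_c[perms] @ (rx - rx.mean())) / (n * sx * sy)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        r = min(max(rho, -1.0), 1.0)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0), n


def correlate_pairs(
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    candidate_map: Mapping[str, Iterable[str]] | pd.Series,
    matched: MatchResult | pd.DataFrame,
    min_n: int = 4,
    exact_max_n: int = 9,
) -> pd.DataFrame:
    """Score every annotated (probe, gene) candidate pair.

    ``candidate_map`` maps probes to their annotated gene symbol(s); only
    these pairs are tested (no all-vs-all scan).  Pairs with fewer than
    ``min_n`` complete matched samples are skipped with a warning.
    """
    pairs_df = matched.pairs if isinstance(matched, MatchResult) else matched
    if len(pairs_df) == 0:
        raise ValidationError("no matched samples to correlate over")
    usable = [
        (m, e)
        for m, e in zip(pairs_df["meth_sample"], pairs_df["expr_sample"])
        if m in beta.columns and e in expr.columns
    ]
    meth_cols = [m for m, _ in usable]
    expr_cols = [e for _, e in usable]
    if len(meth_cols) < min_n:
        raise ValidationError(f"only {len(meth_cols)} matched samples present in both matrices")
    bmat = beta[meth_cols]
    emat = expr[expr_cols]

    if isinstance(candidate_map, pd.Series):
        items = [(p, g) for p, g in candidate_map.items() if isinstance(g, str) and g]
    else:
        items = []
        for probe, genes in candidate_map.items():
            if isinstance(genes, str):
                genes = [genes]
            items.extend((probe, g) for g in genes)

    records = []
    skipped = 0
    for probe, gene in items:
        if probe not in bmat.index or gene not in emat.index:
            continue
        rho, p, n = spearman_pair(
            bmat.loc[probe].to_numpy(),
            emat.loc[gene].to_numpy(),
            exact_max_n=exact_max_n,
        )
        if n < min_n or not np.isfinite(rho):
            skipped += 1
            continue
        records.append((probe, gene, rho, p, n))
    if skipped:
        logger.warning("%d candidate pairs skipped (too few complete cases or constant values)", skipped)
    return pd.DataFrame(records, columns=["probe", "gene", "rho", "p", "n"])


def call_driver_pairs(
    scored: pd.DataFrame,
    dmps: pd.DataFrame | Mapping[str, str],
    degs: pd.DataFrame | Mapping[str, str],
    rho_max: float = -0.4,
    alpha: float = 0.05,
    season: str | None = None,
) -> pd.DataFrame:
    """Methylation-driven pair calls.

    Retains scored pairs with rho < ``rho_max`` (strict), p < ``alpha``,
    probe in the DMP set and gene in the DEG set.  ``dmps`` / ``degs`` are
    the call tables from :func:`~methdriver.differential.call_dmps` /
    ``call_degs`` (or any mapping from ID to direction).  The regulation
    class follows the DMP direction; pairs whose DEG direction does not
    oppose the DMP direction are dropped with a warning.
    """
    dmp_dir = dmps["direction"] if isinstance(dmps, pd.DataFrame) else pd.Series(dict(dmps))
    deg_dir = degs["direction"] if isinstance(degs, pd.DataFrame) else pd.Series(dict(degs))

    sel = (
        (scored["rho"] < rho_max)
        & (scored["p"] < alpha)
        & scored["probe"].isin(dmp_dir.index)
        & scored["gene"].isin(deg_dir.index)
    )
    out = scored[sel].copy()
    if len(out) == 0:
        out["regulation_class"] = pd.Series(dtype=str)
        out["season"] = pd.Series(dtype=str)
        return out
    pdir = dmp_dir.loc[out["probe"]].to_numpy()
    gdir = deg_dir.loc[out["gene"]].to_numpy()
    consistent = ((pdir == "hyper") & (gdir == "down")) | ((pdir == "hypo") & (gdir == "up"))
    if (~consistent).any():
        dropped = out[~consistent]
        logger.warning(
            "%d pairs dropped for direction inconsistency: %s",
            int((~consistent).sum()),
            list(zip(dropped["probe"].head(), dropped["gene"].head())),
        )
    out = out[consistent].copy()
    out["regulation_class"] = np.where(
        dmp_dir.loc[out["probe"]].to_numpy() == "hyper", "hyper_low", "hypo_high"
    )
    out["season"] = season if season is not None else ""
    return out.reset_index(drop=True)


@dataclass
class GeneOverlap:
    """Venn-style two-set comparison."""

    labels: tuple[str, str]
    unique_a: list[str]
    unique_b: list[str]
    intersection: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            f"unique_{self.labels[0]}": len(self.unique_a),
            f"unique_{self.labels[1]}": len(self.unique_b),
            "intersection": len(self.intersection),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, f"unique_{self.labels[0]}") for g in self.unique_a]
            + [(g, f"unique_{self.labels[1]}") for g in self.unique_b]
            + [(g, "intersection") for g in self.intersection]
        )
        return pd.DataFrame(rows, columns=["gene", "partition"])


def compare_gene_sets(
    set_a: Iterable[str],
    set_b: Iterable[str],
    labels: tuple[str, str] = ("A", "B"),
) -> GeneOverlap:
    """Unique-to-each and shared members of two gene sets."""
    a = set(set_a)
    b = set(set_b)
    return GeneOverlap(
        labels=labels,
        unique_a=sorted(a - b),
        unique_b=sorted(b - a),
        intersection=sorted(a & b),
    )
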