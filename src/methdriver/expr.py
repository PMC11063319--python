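"""Expression matrix preprocessing.

Background correction subtracts, per sample, the mean intensity of probes
the detection p-value marks as indistinguishable from background
(p > 0.5), floors at one intensity unit and moves to log2 scale.
Detection filtering works per group: a probe is significant for a group
when its detection p < 0.05 in at least half of that group's samples;
non-significant probes are flattened to their within-group mean so they
cannot drive group contrasts.  Finally probes are collapsed to genes by
keeping, per gene, the probe with the highest mean expression.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import ExpressionSet
from .errors import DimensionError, ValidationError

logger = logging.getLogger(__name__)


def background_correct(
    expr: pd.DataFrame,
    detection_p: pd.DataFrame,
    floor: float = 1.0,
    undetected_threshold: float = 0.5,
) -> pd.DataFrame:
    """Subtract a per-sample background level and log2-transform.

    The background estimate for a sample is the mean intensity of its
    probes with detection p > ``undetected_threshold``; samples with no
    such probe get background 0 with a warning.  The corrected value is
    ``log2(max(intensity - background, floor))``, a monotone transform of
    the input intensities.
    """
    if expr.shape != detection_p.shape:
        raise DimensionError(f"expr shape {expr.shape} != detection_p shape {detection_p.shape}")
    vals = expr.to_numpy(dtype=float)
    pvals = detection_p.to_numpy(dtype=float)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        undetected = pvals[:, j] > undetected_threshold
        usable = undetected & np.isfinite(vals[:, j])
        if usable.any():
            b = float(np.mean(vals[usable, j]))
        else:
            b = 0.0
            logger.warning("sample %s has no undetected probes; background set to 0", expr.columns[j])
        out[:, j] = np.log2(np.maximum(vals[:, j] - b, floor))
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def detection_filter_impute(
    expr: pd.DataFrame,
    detection_p: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    min_fraction: float = 0.5,
    drop_undetected: bool = False,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Per-group detection filter with within-group mean replacement.

    ``groups`` maps each sample (column) to a group label; the groups must
    partition the columns and be non-empty.  For each group, a probe is
    significant when detection p < ``alpha`` in at least ``min_fraction``
    (inclusive) of that group's samples.  Values of significant probes are
    never changed; non-significant probes have that group's entries
    replaced by the probe's pre-imputation mean over the group.  With
    ``drop_undetected`` probes significant in no group are removed.

    Returns the imputed matrix and the per-group significant probe sets.
    """
    g = pd.Series(groups)
    missing = [c for c in expr.columns if c not in g.index]
    if missing:
        raise ValidationError(f"samples without a group label: {missing[:5]}")
    g = g.loc[expr.columns]
    out = expr.copy()
    significant: dict[str, set[str]] = {}
    for label in sorted(g.unique()):
        cols = list(g.index[g == label])
        if not cols:
            raise ValidationError(f"group {label!r} has no samples")
        det = (detection_p[cols] < alpha).sum(axis=1) / len(cols)
        sig = det >= min_fraction
        significant[str(label)] = set(expr.index[sig])
        nonsig = expr.index[~sig]
        if len(nonsig):
            group_mean = expr.loc[nonsig, cols].mean(axis=1)
            out.loc[nonsig, cols] = np.repeat(
                group_mean.to_numpy()[:, None], len(cols), axis=1
            )
    if drop_undetected:
        keep = expr.index.isin(set().union(*significant.values()))
        out = out.loc[keep]
    return out, significant


def collapse_to_genes(expr: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probes to unique genes, keeping the highest-mean probe.

    Probes without a gene annotation are dropped.  Ties on mean expression
    are broken toward the lexicographically smallest probe ID so the
    result is deterministic.
    """
    mapping = probe_to_gene.reindex(expr.index)
    annotated = mapping.notna() & (mapping.astype(str).str.len() > 0)
    if not annotated.any():
        return expr.iloc[0:0].copy()
    table = pd.DataFrame(
        {
            "probe": expr.index[annotated],
            "gene": mapping[annotated].astype(str).to_numpy(),
            "mean": expr.loc[annotated].mean(axis=1, skipna=True).to_numpy(),
        }
    )
    table = table.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    winners = table.drop_duplicates(subset="gene", keep="first")
    out = expr.loc[winners["probe"]].copy()
    out.index = pd.Index(winners["gene"].to_numpy(), name="gene")
    return out


def preprocess_expression(
    eset: ExpressionSet,
    groups: Mapping[str, str] | pd.Series | None = None,
    detection_alpha: float = 0.05,
    detection_fraction: float = 0.5,
    floor: float = 1.0,
    undetected_threshold: float = 0.5,
    drop_undetected: bool = False,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Background correct, detection-filter/impute and collapse to genes.

    ``groups`` defaults to the sample sheet's (group, season) combinations
    so each study arm is filtered on its own samples.  Returns the
    gene x sample log2 matrix and the per-group significant probe sets.
    """
    if eset.log2_scale:
        corrected = eset.expr
    else:
        corrected = background_correct(
            eset.expr, eset.detection_p, floor=floor, undetected_threshold=undetected_threshold
        )
    if groups is None:
        meta = eset.samples.data.loc[list(corrected.columns)]
        groups = (meta["group"].astype(str) + "/" + meta["season"].astype(str))
    imputed, significant = detection_filter_impute(
        corrected,
        eset.detection_p,
        groups,
        alpha=detection_alpha,
        min_fraction=detection_fraction,
        drop_undetected=drop_undetected,
    )
    genes = collapse_to_genes(imputed, eset.probe_to_gene)
    return genes, significant
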