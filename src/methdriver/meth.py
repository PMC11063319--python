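"""Methylation matrix quality control and normalization.

The preprocessing order is fixed: missing-rate filtering, probe blacklist
removal, then Infinium probe-type normalization.  Beta values are computed
from methylated / unmethylated intensities as beta = M / (M + U + offset)
with the conventional offset of 100 intensity units stabilising
low-intensity probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import MethylationSet
from .errors import DimensionError, EmptyResultError, ValidationError

logger = logging.getLogger(__name__)


def compute_beta(
    meth: pd.DataFrame | np.ndarray,
    unmeth: pd.DataFrame | np.ndarray,
    offset: float = 100.0,
) -> pd.DataFrame | np.ndarray:
    """beta = M / (M + U + offset), elementwise; missing values propagate."""
    m_arr = np.asarray(meth, dtype=float) if not isinstance(meth, pd.DataFrame) else meth.to_numpy(float)
    u_arr = np.asarray(unmeth, dtype=float) if not isinstance(unmeth, pd.DataFrame) else unmeth.to_numpy(float)
    if m_arr.shape != u_arr.shape:
        raise DimensionError(f"M shape {m_arr.shape} != U shape {u_arr.shape}")
    if isinstance(meth, pd.DataFrame) and isinstance(unmeth, pd.DataFrame):
        if not meth.index.equals(unmeth.index) or not meth.columns.equals(unmeth.columns):
            raise DimensionError("M and U must share index and columns")
    for arr, name in ((m_arr, "M"), (u_arr, "U")):
        finite = arr[np.isfinite(arr)]
        if finite.size and finite.min() < 0:
            raise ValidationError(f"{name} intensities must be nonnegative")
    if offset < 0:
        raise ValidationError("offset must be nonnegative")
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = m_arr / (m_arr + u_arr + offset)
    if isinstance(meth, pd.DataFrame):
        return pd.DataFrame(beta, index=meth.index, columns=meth.columns)
    return beta


@dataclass
class MissingFilterReport:
    """Dropped feature / sample IDs with the missing fractions that caused it."""

    dropped_features: dict[str, float] = field(default_factory=dict)
    dropped_samples: dict[str, float] = field(default_factory=dict)
    passes: int = 0


def filter_missing(
    matrix: pd.DataFrame,
    max_rate: float = 0.10,
) -> tuple[pd.DataFrame, MissingFilterReport]:
    """Drop features then samples whose missing fraction exceeds ``max_rate``.

    Features (rows) are evaluated first, then samples (columns) on the
    surviving rows; the sweep repeats until nothing changes, so the
    operation is idempotent.  Fractions exactly at the threshold are kept
    (strict ``>`` drops).  Raises :class:`EmptyResultError` when no
    feature survives.
    """
    if not 0 <= max_rate < 1:
        raise ValidationError("max_rate must lie in [0, 1)")
    report = MissingFilterReport()
    out = matrix
    while True:
        changed = False
        if out.shape[1] > 0:
            row_rate = out.isna().mean(axis=1)
            bad_rows = row_rate[row_rate > max_rate]
            if len(bad_rows):
                report.dropped_features.update({str(k): float(v) for k, v in bad_rows.items()})
                out = out.drop(index=bad_rows.index)
                changed = True
        if out.shape[0] == 0:
            raise EmptyResultError("missing-rate filter removed every feature")
        if out.shape[0] > 0:
            col_rate = out.isna().mean(axis=0)
            bad_cols = col_rate[col_rate > max_rate]
            if len(bad_cols):
                report.dropped_samples.update({str(k): float(v) for k, v in bad_cols.items()})
                out = out.drop(columns=bad_cols.index)
                changed = True
        report.passes += 1
        if not changed:
            break
    return out.copy(), report


def apply_probe_blacklist(mset: MethylationSet, blacklist: Iterable[str]) -> MethylationSet:
    """Remove blacklisted probes (cross-reactive / multi-mapping lists).

    Unknown IDs are ignored and logged; the number removed equals
    ``|blacklist ∩ probes|``.
    """
    black = set(blacklist)
    present = [p for p in mset.beta.index if p not in black]
    removed = mset.beta.shape[0] - len(present)
    unknown = len(black) - removed
    if unknown:
        logger.info("blacklist: %d listed probes not present on the array", unknown)
    logger.info("blacklist: removed %d of %d probes", removed, mset.beta.shape[0])
    return replace(
        mset,
        beta=mset.beta.loc[present],
        meth=None if mset.meth is None else mset.meth.loc[present],
        unmeth=None if mset.unmeth is None else mset.unmeth.loc[present],
    )


def normalize_probe_types(
    beta: pd.DataFrame,
    design_type: pd.Series,
) -> pd.DataFrame:
    """Quantile-map Type-II beta values onto the Type-I distribution per sample.

    The two Infinium chemistries produce systematically different beta
    distributions; within each sample the Type-II values are replaced by
    the Type-I empirical quantile function evaluated at their Type-II
    quantiles.  Type-I values are untouched, ranks within the Type-II set
    are preserved, and the output stays inside [0, 1].  Samples with fewer
    than two observed Type-I values are skipped with a warning.
    """
    types = design_type.reindex(beta.index)
    if types.isna().any():
        missing = list(beta.index[types.isna()][:5])
        raise ValidationError(f"design type missing for probes: {missing}")
    bad = ~types.isin(("I", "II"))
    if bad.any():
        raise ValidationError(f"unknown design types: {sorted(types[bad].unique())}")
    is_one = (types == "I").to_numpy()
    is_two = ~is_one
    if not is_two.any():
        return beta.copy()

    out = beta.copy()
    vals = out.to_numpy(dtype=float)
    for j in range(vals.shape[1]):
        t1 = vals[is_one, j]
        t1 = np.sort(t1[np.isfinite(t1)])
        if t1.size < 2:
            logger.warning("sample %s has < 2 Type-I probes; normalization skipped", out.columns[j])
            continue
        col = vals[is_two, j]
        obs = np.isfinite(col)
        if not obs.any():
            continue
        ranks = rankdata(col[obs], method="average")
        q = (ranks - 0.5) / obs.sum()
        grid = (np.arange(t1.size) + 0.5) / t1.size
        mapped = np.interp(q, grid, t1)
        new_col = col.copy()
        new_col[obs] = mapped
        vals[is_two, j] = new_col
    out.loc[:, :] = vals
    return out


def preprocess_methylation(
    mset: MethylationSet,
    blacklist: Iterable[str] | None = None,
    max_missing: float = 0.10,
    normalize: bool = True,
    beta_offset: float = 100.0,
) -> tuple[MethylationSet, MissingFilterReport]:
    """Full methylation QC in the fixed order missing -> blacklist -> normalize."""
    beta = mset.beta
    if beta is None and mset.meth is not None:
        beta = compute_beta(mset.meth, mset.unmeth, offset=beta_offset)
    filtered, report = filter_missing(beta, max_rate=max_missing)
    current = replace(
        mset,
        beta=filtered,
        samples=mset.samples.subset(list(filtered.columns)),
        meth=None,
        unmeth=None,
    )
    if blacklist:
        current = apply_probe_blacklist(current, blacklist)
        if current.beta.shape[0] == 0:
            raise EmptyResultError("blacklist removed every probe")
    if normalize:
        normalized = normalize_probe_types(current.beta, current.annotation["design_type"])
        current = replace(current, beta=normalized)
    return current, report
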