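"""Two-group moderated tests and adaptive effect-size thresholds.

The screening statistic is an empirical-Bayes moderated t: per-feature
pooled variances s_g^2 with d_g residual degrees of freedom are shrunk
toward a prior (d0, s0^2) fitted by method of moments on log s^2, giving
posterior variances

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and t_g = effect_g / (s~_g * sqrt(1/n1 + 1/n2)) on d0 + d_g degrees of
freedom.  As d0 -> 0 this is the ordinary pooled-variance t; as d0 -> inf
every feature is tested against the common prior variance.

Feature calls use the study's adaptive effect threshold: a feature passes
when |effect| exceeds mean(|effect|) + 2 * sd(|effect|) computed over all
tested features, together with a raw p < alpha.  Methylation calls are
additionally restricted to promoter-annotated probes
(TSS1500, TSS200, 5'UTR, 1stExon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

PROMOTER_FEATURES = frozenset({"TSS1500", "TSS200", "5'UTR", "1stExon"})

#: prior degrees of freedom treated as "infinite"
MAX_PRIOR_DF = 1e6


@dataclass(frozen=True)
class AdaptiveThreshold:
    """Data-driven effect cutoff tau = mean(|effect|) + 2 * sd(|effect|)."""

    tau: float
    mean_abs: float
    sd_abs: float
    n_features: int


def adaptive_threshold(effects: Iterable[float]) -> AdaptiveThreshold:
    """Compute the mean + 2*SD threshold on absolute effects.

    The sample standard deviation (n-1 denominator) is used.  NaN effects
    are ignored; fewer than two finite effects is an error.
    """
    a = np.abs(np.asarray(list(effects), dtype=float))
    a = a[np.isfinite(a)]
    if a.size < 2:
        raise ValidationError("adaptive_threshold needs at least 2 finite effects")
    mean_abs = float(a.mean())
    sd_abs = float(a.std(ddof=1))
    return AdaptiveThreshold(tau=mean_abs + 2.0 * sd_abs, mean_abs=mean_abs, sd_abs=sd_abs, n_features=int(a.size))


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValidationError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Returns (d0, s0_squared); d0 is capped at ``MAX_PRIOR_DF`` when the
    observed spread of log variances is no larger than expected from the
    residual degrees of freedom alone.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return MAX_PRIOR_DF, float(np.nanmedian(s2[np.isfinite(s2)])) if np.isfinite(s2).any() else 1.0
    z = np.log(s2[ok])
    half_df = df[ok] / 2.0
    e = z - special.digamma(half_df) + np.log(half_df)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    t2 = evar - float(np.mean(special.polygamma(1, half_df)))
    if t2 > 0:
        d0 = min(2.0 * trigamma_inverse(t2), MAX_PRIOR_DF)
    else:
        d0 = MAX_PRIOR_DF
    if d0 >= MAX_PRIOR_DF:
        s0 = float(np.exp(emean))
    else:
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def moderated_ttest(
    matrix: pd.DataFrame,
    groups: pd.Series | Iterable[str],
    case: str | None = None,
    control: str | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per feature (row).

    Parameters
    ----------
    matrix
        features x samples; NaN entries are excluded feature-wise.
    groups
        group label per column of ``matrix`` (two distinct labels).
    case, control
        which label is subtracted from which: effect = mean(case) -
        mean(control).  By convention ``case`` defaults to ``"AR"`` when
        present, otherwise the lexicographically larger label.
    prior_df
        override the fitted prior degrees of freedom d0 (``0`` gives the
        ordinary pooled-variance t exactly).

    Returns a DataFrame indexed by feature with columns ``effect``, ``t``,
    ``p``, ``p_adj`` (Benjamini-Hochberg), ``direction``, ``n_case``,
    ``n_control`` and ``df_total``.  The fitted prior is stored in
    ``result.attrs["prior_df"]`` / ``attrs["prior_var"]``.
    """
    g = pd.Series(list(groups))
    if len(g) != matrix.shape[1]:
        raise ValidationError("group labels must match the number of columns")
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValidationError(f"exactly two group labels required, got {labels}")
    if case is None:
        case = "AR" if "AR" in labels else labels[1]
    if control is None:
        control = next(l for l in labels if l != case)
    if case not in labels or control not in labels:
        raise ValidationError(f"case/control {case!r}/{control!r} not among labels {labels}")

    X = matrix.to_numpy(dtype=float)
    m1 = X[:, (g == case).to_numpy()]
    m2 = X[:, (g == control).to_numpy()]
    if m1.shape[1] < 2 or m2.shape[1] < 2:
        raise ValidationError("each group needs at least 2 samples")

    with np.errstate(invalid="ignore", divide="ignore"):
        n1 = np.sum(np.isfinite(m1), axis=1).astype(float)
        n2 = np.sum(np.isfinite(m2), axis=1).astype(float)
        mean1 = np.where(n1 > 0, np.nansum(m1, axis=1) / np.maximum(n1, 1), np.nan)
        mean2 = np.where(n2 > 0, np.nansum(m2, axis=1) / np.maximum(n2, 1), np.nan)
        v1 = _nanvar(m1, mean1, n1)
        v2 = _nanvar(m2, mean2, n2)
    df = n1 + n2 - 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    effect = mean1 - mean2
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ((n1 - 1.0) * v1 + (n2 - 1.0) * v2) / np.where(df > 0, df, np.nan)

    if prior_df is None:
        d0, s0 = fit_variance_prior(s2[valid], df[valid])
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValidationError("prior_df must be >= 0")
        d0 = min(d0, MAX_PRIOR_DF)
        _, s0 = fit_variance_prior(s2[valid], df[valid])

    with np.errstate(invalid="ignore", divide="ignore"):
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    df_total = d0 + df

    t = np.zeros_like(effect)
    nz = se > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t[nz] = effect[nz] / se[nz]
    # zero residual + zero prior variance: t = 0 when effect is 0, +-inf otherwise
    degenerate = valid & ~nz
    t[degenerate & (effect != 0)] = np.sign(effect[degenerate & (effect != 0)]) * np.inf
    t[~valid] = np.nan

    p = np.full_like(effect, np.nan)
    with np.errstate(invalid="ignore"):
        p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df_total[valid])
    p[valid & np.isinf(t)] = 0.0
    p = np.clip(p, 0.0, 1.0)

    p_adj = np.full_like(p, np.nan)
    if valid.any():
        p_adj[valid] = multipletests(p[valid], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(effect < 0, "down", "up"),
            "n_case": n1.astype(int),
            "n_control": n2.astype(int),
            "df_total": df_total,
        },
        index=matrix.index,
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0
    out.attrs["case"] = case
    out.attrs["control"] = control
    return out


def _nanvar(m: np.ndarray, mean: np.ndarray, n: np.ndarray) -> np.ndarray:
    dev = (m - mean[:, None]) ** 2
    ss = np.nansum(dev, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 1, ss / np.maximum(n - 1.0, 1.0), np.nan)


def annotate_calls(
    results: pd.DataFrame,
    threshold: AdaptiveThreshold | None = None,
    alpha: float = 0.05,
    annotation: pd.DataFrame | None = None,
    promoter_features: frozenset[str] = PROMOTER_FEATURES,
) -> pd.DataFrame:
    """Attach pass/fail flags (and promoter flag when annotation is given)."""
    if threshold is None:
        threshold = adaptive_threshold(results["effect"])
    out = results.copy()
    out["passes_p"] = out["p"] < alpha
    out["passes_effect"] = out["effect"].abs() > threshold.tau
    if annotation is not None:
        feat = annotation["feature"].reindex(out.index)
        out["feature_label"] = feat
        out["promoter"] = feat.isin(promoter_features).fillna(False)
    out.attrs.update(results.attrs)
    out.attrs["tau"] = threshold.tau
    return out


def call_dmps(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    threshold: AdaptiveThreshold | None = None,
    alpha: float = 0.05,
    promoter_features: frozenset[str] = PROMOTER_FEATURES,
) -> pd.DataFrame:
    """Differentially methylated position calls.

    A probe is called when p < alpha, |delta beta| exceeds the adaptive
    threshold, and its genic feature label lies in the promoter vocabulary.
    Probes that pass statistics but lack annotation are excluded with a
    warning.  Direction is ``hyper`` (beta higher in cases) or ``hypo``.
    """
    if threshold is None:
        threshold = adaptive_threshold(results["effect"])
    flagged = annotate_calls(results, threshold, alpha, annotation, promoter_features)
    stat_pass = flagged["passes_p"] & flagged["passes_effect"]
    unannotated = stat_pass & flagged["feature_label"].isna()
    if unannotated.any():
        logger.warning(
            "%d significant probes lack annotation and were excluded: %s",
            int(unannotated.sum()),
            list(flagged.index[unannotated][:5]),
        )
    called = flagged[stat_pass & flagged["promoter"]].copy()
    called["direction"] = np.where(called["effect"] > 0, "hyper", "hypo")
    called.attrs["tau"] = threshold.tau
    return called


def call_degs(
    results: pd.DataFrame,
    threshold: AdaptiveThreshold | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differentially expressed gene calls: p < alpha and |log2FC| > tau."""
    if threshold is None:
        threshold = adaptive_threshold(results["effect"])
    flagged = annotate_calls(results, threshold, alpha)
    called = flagged[flagged["passes_p"] & flagged["passes_effect"]].copy()
    called["direction"] = np.where(called["effect"] > 0, "up", "down")
    called.attrs["tau"] = threshold.tau
    return called
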