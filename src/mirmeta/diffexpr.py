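"""Two-group differential expression with empirical-Bayes moderated t.

Per feature: logFC = mean(resistant) - mean(control), pooled within-group
variance s2 with df = n1 + n2 - 2, ordinary t, then variance moderation

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)
    t_mod   = logFC / sqrt(s2_post * (1/n1 + 1/n2)),  df_total = d0 + df

with the prior (d0, s0^2) estimated by the method of moments on log s2
(closed forms of Smyth 2004).  P-values are two-sided from t with d0 + df
degrees of freedom (normal when d0 is infinite), BH-adjusted across features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist
from statsmodels.stats.multitest import multipletests

from .studies import ExpressionStudy


@dataclass
class EBayesParams:
    """Empirical-Bayes prior: degrees of freedom d0 (may be inf) and variance s0_2."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_2 > 0):
            raise ValueError("s0_2 must be > 0")


# ---------------------------------------------------------------------------
# per-study fits
# ---------------------------------------------------------------------------
def fit_two_group(study: ExpressionStudy) -> pd.DataFrame:
    """Per-feature logFC, pooled variance and ordinary t for one study.

    Returns a DataFrame indexed by feature id with columns ``logFC``, ``s2``,
    ``df_residual``, ``t_ordinary``, ``n1``, ``n2`` (n1 = resistant).
    """
    if not study.log_scale:
        raise ValueError("fit requires log2-scale values")
    if study.missing_mask.to_numpy().any():
        raise ValueError("fit requires a complete matrix; impute first")
    r = study.group_matrix("resistant")
    c = study.group_matrix("control")
    n1, n2 = r.shape[1], c.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    logfc = r.mean(axis=1) - c.mean(axis=1)
    df = n1 + n2 - 2
    s2 = (r.var(axis=1, ddof=1) * (n1 - 1) + c.var(axis=1, ddof=1) * (n2 - 1)) / df
    scale = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = logfc / scale
    t_ord = np.where((s2 == 0) & (logfc == 0), 0.0, t_ord)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "df_residual": float(df),
            "t_ordinary": t_ord,
            "n1": n1,
            "n2": n2,
        },
        index=study.feature_ids.rename("feature_id"),
    )


# ---------------------------------------------------------------------------
# prior estimation (method of moments on log s2)
# ---------------------------------------------------------------------------
def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) / x < 1e-10:
            break
    return x


def estimate_ebayes_params(s2: np.ndarray, df: float) -> EBayesParams:
    """Moment estimation of the variance prior from the observed s2.

    Under the hierarchical model, log s2 is distributed as log s0^2 plus a
    log-F(df, d0) variable; matching the mean and variance of
    e = log(s2) - digamma(df/2) + log(df/2) yields the closed forms used here.
    Zero variances are excluded from the moments.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need >= 2 positive variances to estimate the prior")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return EBayesParams(d0=d0, s0_2=s0_2)


# ---------------------------------------------------------------------------
# moderation and calling
# ---------------------------------------------------------------------------
def ebayes_moderate(
    fits: pd.DataFrame, params: EBayesParams | str = "estimate"
) -> pd.DataFrame:
    """Shrink per-feature variances toward the prior and recompute t and p.

    ``params="estimate"`` fits the prior from the data; ``d0=0`` reproduces
    the ordinary t exactly, ``d0=inf`` replaces every variance by s0_2.
    """
    df = float(fits["df_residual"].iloc[0])
    if (fits["df_residual"] < 1).any():
        raise ValueError("df_residual must be >= 1 for every feature")
    if isinstance(params, str):
        if params != "estimate":
            raise ValueError("params must be EBayesParams or 'estimate'")
        params = estimate_ebayes_params(fits["s2"].to_numpy(), df)

    s2 = fits["s2"].to_numpy(dtype=float)
    logfc = fits["logFC"].to_numpy(dtype=float)
    n1 = fits["n1"].to_numpy(dtype=float)
    n2 = fits["n2"].to_numpy(dtype=float)
    if np.isinf(params.d0):
        s2_post = np.full_like(s2, params.s0_2)
        df_total = np.inf
    else:
        s2_post = (params.d0 * params.s0_2 + df * s2) / (params.d0 + df)
        df_total = params.d0 + df
    scale = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = logfc / scale
    t_mod = np.where((s2_post == 0) & (logfc == 0), 0.0, t_mod)
    if np.isinf(df_total):
        p = 2.0 * norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    # degenerate zero-variance zero-logFC features: defined as null
    p = np.where(np.isnan(t_mod), 1.0, p)
    out = fits.copy()
    out["t_moderated"] = t_mod
    out["s2_post"] = s2_post
    out["df_total"] = df_total
    out["p"] = p
    out["adj_p"] = bh_adjust(p)
    out["d0"] = params.d0
    out["s0_2"] = params.s0_2
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_des(
    results: pd.DataFrame, alpha: float = 0.05, lfc_cut: float | None = None
) -> pd.DataFrame:
    """Flag features with adj_p < alpha and, when given, |logFC| > lfc_cut."""
    out = results.copy()
    is_de = out["adj_p"] < alpha
    if lfc_cut is not None:
        is_de &= out["logFC"].abs() > lfc_cut
    out["is_de"] = is_de
    return out


def de_workflow(
    study: ExpressionStudy,
    alpha: float = 0.05,
    lfc_cut: float | None = None,
    params: EBayesParams | str = "estimate",
) -> pd.DataFrame:
    """fit -> moderate -> BH -> call, for one study."""
    return call_des(ebayes_moderate(fit_two_group(study), params), alpha, lfc_cut)
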