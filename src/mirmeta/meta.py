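"""Random-effects meta-analysis of per-study miRNA effects.

Per feature, the per-study effect size is the log2 fold change with standard
error derived as |logFC / t| (the identity SE = estimate / t for a Wald-type
statistic).  Heterogeneity is measured by Cochran's Q,

    w_i = 1 / se_i^2,   Q = sum w_i (es_i - es_fixed)^2,   Q ~ chi2(k-1),

and effects are combined with the DerSimonian-Laird random-effects model:

    tau2  = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_i  = 1 / (se_i^2 + tau2)
    es    = sum w* es / sum w*,   se = 1 / sqrt(sum w*),   z = es / se,

with two-sided normal p-values BH-adjusted across the feature universe.
A Hedges-g standardised-mean-difference effect is available as an
alternative effect scale.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

META_COLUMNS = [
    "k", "es_meta", "se_meta", "z", "p", "adj_p", "Q", "Q_p", "tau2",
    "model", "direction",
]


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------
def derive_se(logfc, t):
    """Standard error of a logFC recovered from its t statistic: |logFC / t|.

    Returns NaN where t == 0 (the feature is excluded from the meta-analysis
    for that study; callers log the exclusion).
    """
    logfc = np.asarray(logfc, dtype=float)
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.abs(logfc / t)
    se = np.where((t == 0) | ~np.isfinite(t) | ~np.isfinite(se), np.nan, se)
    if se.ndim == 0:
        return float(se)
    return se


def cochran_q(es, se) -> tuple[float, float, int]:
    """Cochran's Q heterogeneity test for one feature across k >= 2 studies."""
    es = np.asarray(es, dtype=float)
    se = np.asarray(se, dtype=float)
    k = es.size
    if k < 2:
        raise ValueError("Cochran's Q needs >= 2 studies")
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / se**2
    es_fixed = float(np.sum(w * es) / np.sum(w))
    q = float(np.sum(w * (es - es_fixed) ** 2))
    df = k - 1
    return q, float(chi2.sf(q, df)), df


def dl_tau2(es, se) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance."""
    es = np.asarray(es, dtype=float)
    se = np.asarray(se, dtype=float)
    q, _, df = cochran_q(es, se)
    w = 1.0 / se**2
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        raise ValueError("degenerate weights: effective k < 2")
    return max(0.0, (q - df) / c)


def random_effects_combine(es, se, model: str = "random") -> dict:
    """Combine one feature's study effects; ``model`` is 'random', 'fixed'
    or 'q-gated' (fixed when Q_p >= 0.05, random otherwise)."""
    es = np.asarray(es, dtype=float)
    se = np.asarray(se, dtype=float)
    q, q_p, df = cochran_q(es, se)
    tau2 = dl_tau2(es, se)
    if model == "q-gated":
        used = "fixed" if q_p >= 0.05 else "random"
    elif model in ("random", "fixed"):
        used = model
    else:
        raise ValueError(f"unknown model '{model}'")
    t2 = tau2 if used == "random" else 0.0
    w = 1.0 / (se**2 + t2)
    es_meta = float(np.sum(w * es) / np.sum(w))
    se_meta = float(1.0 / np.sqrt(np.sum(w)))
    z = es_meta / se_meta
    return {
        "k": int(es.size),
        "es_meta": es_meta,
        "se_meta": se_meta,
        "z": z,
        "p": float(2.0 * norm.sf(abs(z))),
        "Q": q,
        "Q_p": q_p,
        "tau2": tau2,
        "model": used,
    }


# ---------------------------------------------------------------------------
# vectorised combine over a feature x study grid (NaN = absent)
# ---------------------------------------------------------------------------
def combine_grid(es: np.ndarray, se: np.ndarray, model: str = "random") -> pd.DataFrame:
    """DL combine row-wise over (features x studies) arrays with NaN gaps.

    Rows with fewer than two finite (es, se) pairs yield NaN throughout.
    """
    es = np.asarray(es, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(es) & np.isfinite(se) & (se > 0)
    esm = np.where(ok, es, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(ok, 1.0 / se**2, np.nan)
    k = ok.sum(axis=1)
    sw = np.nansum(w, axis=1)
    sw2 = np.nansum(w**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        es_fixed = np.nansum(w * esm, axis=1) / sw
        q = np.nansum(w * (esm - es_fixed[:, None]) ** 2, axis=1)
        dfq = k - 1.0
        q_p = chi2.sf(q, np.where(dfq > 0, dfq, 1.0))
        c = sw - sw2 / sw
        tau2 = np.maximum(0.0, (q - dfq) / c)
        if model == "random":
            t2 = tau2
        elif model == "fixed":
            t2 = np.zeros_like(tau2)
        elif model == "q-gated":
            t2 = np.where(q_p >= 0.05, 0.0, tau2)
        else:
            raise ValueError(f"unknown model '{model}'")
        ws = np.where(ok, 1.0 / (se**2 + t2[:, None]), np.nan)
        sws = np.nansum(ws, axis=1)
        es_meta = np.nansum(ws * esm, axis=1) / sws
        se_meta = 1.0 / np.sqrt(sws)
        z = es_meta / se_meta
    p = 2.0 * norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "k": k,
            "es_meta": es_meta,
            "se_meta": se_meta,
            "z": z,
            "p": p,
            "Q": q,
            "Q_p": q_p,
            "tau2": tau2,
        }
    )
    if model == "q-gated":
        out["model"] = np.where(q_p >= 0.05, "fixed", "random")
    else:
        out["model"] = model
    bad = k < 2
    out.loc[bad, out.columns.difference(["k", "model"])] = np.nan
    return out


# ---------------------------------------------------------------------------
# full meta stage
# ---------------------------------------------------------------------------
def _hedges_g(de: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Hedges-g SMD and its standard error from a two-group fit table."""
    n1 = de["n1"].astype(float)
    n2 = de["n2"].astype(float)
    df = n1 + n2 - 2.0
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = de["logFC"] / np.sqrt(de["s2"])
    g = j * d
    se = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2)))
    return g, se


def harmonize_feature_id(fid: str) -> str:
    """Exact-match harmonisation: lower-case and trim whitespace."""
    return fid.strip().lower()


def run_meta(
    de_results: Mapping[str, pd.DataFrame],
    model: str = "random",
    alpha: float = 0.05,
    effect: str = "lfc",
    use_moderated: bool = True,
) -> pd.DataFrame:
    """Meta-analyse per-study DE tables into one combined effect per feature.

    Parameters
    ----------
    de_results
        Mapping study id -> DE table (output of :func:`mirmeta.diffexpr.ebayes_moderate`
        or :func:`fit_two_group`), indexed by feature id.
    model
        'random' (always DerSimonian-Laird random effects, the default) or
        'q-gated' (fixed-effect unless Cochran's Q is significant at 0.05).
    effect
        'lfc' (log2 fold change, SE = |logFC/t|) or 'smd' (Hedges g).
    use_moderated
        Derive the SE from the moderated t when available, else ordinary t.

    Only features observed in >= 2 studies are combined; per-feature p-values
    are BH-adjusted across all combined features, and ``direction`` labels the
    sign of the combined effect.
    """
    if not de_results:
        raise ValueError("no DE tables given")
    frames = {}
    for sid, de in de_results.items():
        d = de.copy()
        d.index = [harmonize_feature_id(f) for f in d.index]
        dup = d.index.duplicated()
        if dup.any():
            logger.warning("%s: dropping %d duplicate harmonised ids", sid, dup.sum())
            d = d[~dup]
        if effect == "lfc":
            tcol = "t_moderated" if (use_moderated and "t_moderated" in d) else "t_ordinary"
            es = d["logFC"]
            se = pd.Series(derive_se(d["logFC"].to_numpy(), d[tcol].to_numpy()), index=d.index)
        elif effect == "smd":
            es, se = _hedges_g(d)
        else:
            raise ValueError(f"unknown effect scale '{effect}'")
        excluded = se.isna().sum()
        if excluded:
            logger.warning("%s: %d features excluded (t = 0 or undefined SE)", sid, excluded)
        frames[sid] = pd.DataFrame({"es": es, "se": se})

    features = sorted(set().union(*(f.index for f in frames.values())))
    study_ids = list(frames)
    es = np.full((len(features), len(study_ids)), np.nan)
    se = np.full_like(es, np.nan)
    for j, sid in enumerate(study_ids):
        f = frames[sid].reindex(features)
        es[:, j] = f["es"].to_numpy()
        se[:, j] = f["se"].to_numpy()

    grid = combine_grid(es, se, model=model)
    grid.index = pd.Index(features, name="feature_id")
    singles = int((grid["k"] < 2).sum())
    if singles:
        logger.info("%d features present in < 2 studies dropped from meta-analysis", singles)
    grid = grid[grid["k"] >= 2].copy()
    if grid.empty:
        raise ValueError("no feature present in >= 2 studies")
    grid["adj_p"] = bh_adjust(grid["p"].to_numpy())
    grid["direction"] = np.where(grid["es_meta"] > 0, "up", "down")
    grid["significant"] = grid["adj_p"] < alpha
    return grid.sort_values("p")
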