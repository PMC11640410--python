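"""Kaplan-Meier estimation, log-rank test and O/E hazard ratios for hub genes.

Patients are dichotomised on a gene's expression (median by default, or the
best cutoff in the inner 80% of the expression range, minimising the log-rank
p — reported uncorrected and flagged as such).  The two-group comparison uses
the standard log-rank chi-square

    chi2 = (O1 - E1)^2 / V,   V = sum_j d_j (n1j/nj) (1 - n1j/nj) (nj - d_j)/(nj - 1)

and the hazard ratio is the observed/expected approximation
HR = (O1/E1)/(O2/E2) with CI exp(ln HR +- 1.96 sqrt(1/E1 + 1/E2)), matching
the reporting convention of expression-based survival portals.  Group 1 is
the high-expression group throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

logger = logging.getLogger(__name__)


def split_by_expression(
    expression, rule: str = "median", times=None, events=None
) -> np.ndarray:
    """Label each subject 'high' or 'low' by the dichotomisation rule.

    ``median``: high when expression exceeds the median.  ``best_cutoff``:
    scan candidate cutpoints between the 10th and 90th expression percentiles
    and keep the one minimising the log-rank p (requires times/events; the
    selected p is not corrected for the scan).
    """
    expr = np.asarray(expression, dtype=float)
    if expr.size < 2:
        raise ValueError("need at least two subjects to split")
    if np.ptp(expr) == 0:
        raise ValueError("all expression values identical; cannot dichotomise")
    if rule == "median":
        return np.where(expr > np.median(expr), "high", "low")
    if rule == "best_cutoff":
        if times is None or events is None:
            raise ValueError("best_cutoff needs times and events")
        lo, hi = np.quantile(expr, [0.1, 0.9])
        cuts = np.unique(expr[(expr >= lo) & (expr <= hi)])
        best = None
        for c in cuts:
            lab = np.where(expr > c, "high", "low")
            if len(set(lab)) < 2:
                continue
            stat = _logrank(np.asarray(times, float), np.asarray(events, int), lab)
            if stat is None:
                continue
            p = stat["p"]
            if best is None or p < best[0]:
                best = (p, c)
        if best is None:
            raise ValueError("no admissible cutpoint found")
        logger.info("best_cutoff at expression=%g (p uncorrected for the scan)", best[1])
        return np.where(expr > best[1], "high", "low")
    raise ValueError(f"unknown split rule '{rule}'")


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve for one group.

    Censored subjects at an event time remain at risk for that time's events.
    Returns rows at event times: time, n_at_risk, n_events, survival.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t <= 0).any():
        raise ValueError("times must be positive")
    rows = []
    s = 1.0
    for ti in np.unique(t[e == 1]):
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        rows.append((float(ti), n_i, d_i, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def _logrank(t: np.ndarray, e: np.ndarray, groups: np.ndarray) -> dict | None:
    """O/E/V sums over pooled event times; group order (high, low)."""
    g1 = groups == "high"
    g2 = ~g1
    if g1.sum() == 0 or g2.sum() == 0:
        return None
    o1 = e1 = o2 = e2 = v = 0.0
    for ti in np.unique(t[e == 1]):
        at = t >= ti
        n1, n2 = int((at & g1).sum()), int((at & g2).sum())
        nj = n1 + n2
        d1 = int(((t == ti) & (e == 1) & g1).sum())
        d2 = int(((t == ti) & (e == 1) & g2).sum())
        dj = d1 + d2
        o1 += d1
        o2 += d2
        e1 += dj * n1 / nj
        e2 += dj * n2 / nj
        if nj > 1:
            v += dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / (nj - 1)
    if v == 0:
        chi2 = 0.0
    else:
        chi2 = (o1 - e1) ** 2 / v
    return {"O1": o1, "E1": e1, "O2": o2, "E2": e2, "V": v, "chi2": chi2,
            "p": float(chi2_dist.sf(chi2, 1))}


@dataclass
class SurvivalResult:
    """Two-group KM comparison: curves, log-rank statistic, O/E hazard ratio."""

    km_curves: dict = field(default_factory=dict)
    chi2: float = np.nan
    p: float = np.nan
    hr: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_high: int = 0
    n_low: int = 0

    def summary(self) -> dict:
        return {
            "chi2": self.chi2, "p": self.p, "hr": self.hr,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_high": self.n_high, "n_low": self.n_low,
        }


def logrank_hr(table: pd.DataFrame, groups) -> SurvivalResult:
    """Log-rank test and O/E hazard ratio (high vs low) for a survival table.

    ``table`` needs columns time and event; ``groups`` is the 'high'/'low'
    label array.  A group with zero events leaves the HR undefined (NaN, with
    a logged warning); the log-rank test is still reported.
    """
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    groups = np.asarray(groups)
    stat = _logrank(t, e, groups)
    if stat is None:
        raise ValueError("both expression groups must be non-empty")
    curves = {
        g: km_estimate(t[groups == g], e[groups == g]) for g in ("high", "low")
    }
    res = SurvivalResult(
        km_curves=curves,
        chi2=stat["chi2"],
        p=stat["p"],
        n_high=int((groups == "high").sum()),
        n_low=int((groups == "low").sum()),
    )
    if stat["O1"] == 0 or stat["O2"] == 0:
        logger.warning("a group has zero events; hazard ratio undefined")
        return res
    hr = (stat["O1"] / stat["E1"]) / (stat["O2"] / stat["E2"])
    half = 1.96 * np.sqrt(1.0 / stat["E1"] + 1.0 / stat["E2"])
    res.hr = float(hr)
    res.ci_low = float(hr * np.exp(-half))
    res.ci_high = float(hr * np.exp(half))
    return res


def analyze_gene(table: pd.DataFrame, rule: str = "median") -> SurvivalResult:
    """Dichotomise a survival table on expression and run the KM comparison."""
    groups = split_by_expression(
        table["expression"], rule=rule,
        times=table["time"], events=table["event"],
    )
    return logrank_hr(table, groups)
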