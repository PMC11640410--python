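"""Log2 transformation and iterative imputation of missing expression values.

The imputer follows the MissForest scheme: initialise missing cells with
feature means, then repeatedly regress each feature with missing values on all
other features (random forest by default; ridge or plain mean as cheaper
alternatives), visiting features in order of decreasing missingness, until the
normalised change in the imputed cells

    gamma = sum((new - old)^2) / sum(new^2)        (over imputed cells only)

falls below ``tol`` or ``max_iter`` is reached.  Observed cells are never
modified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np

from .studies import ExpressionStudy

logger = logging.getLogger(__name__)


def log2_transform(study: ExpressionStudy) -> ExpressionStudy:
    """Return a copy of ``study`` with values log2-transformed.

    Requires ``log_scale`` False and every observed value strictly positive;
    the offending feature/sample is named otherwise.  The missingness pattern
    is unchanged.
    """
    if study.log_scale:
        raise ValueError(f"study '{study.study_id}' is already on the log2 scale")
    vals = study.values.to_numpy(dtype=float)
    bad = np.where(~np.isnan(vals) & (vals <= 0))
    if bad[0].size:
        f = study.values.index[bad[0][0]]
        s = study.values.columns[bad[1][0]]
        raise ValueError(
            f"non-positive value {vals[bad[0][0], bad[1][0]]!r} at "
            f"feature '{f}', sample '{s}' cannot be log2-transformed"
        )
    out = study.copy()
    out.values = np.log2(study.values)
    return replace(out, log_scale=True)


def _make_regressor(method: str, seed: int):
    if method == "rf":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
    if method == "ridge":
        from sklearn.linear_model import Ridge

        return Ridge(alpha=1.0)
    raise ValueError(f"unknown imputation method '{method}'")


def impute_missing(
    study: ExpressionStudy,
    method: str = "rf",
    max_iter: int = 10,
    tol: float = 1e-4,
    seed: int = 0,
) -> ExpressionStudy:
    """Fill missing cells by iterative feature-wise regression.

    Parameters
    ----------
    study
        Log-scale study; every feature must have at least one observed value.
    method
        ``"rf"`` (random forest, 100 trees), ``"ridge"`` or ``"mean"``.
    max_iter, tol
        Stop when the normalised change gamma drops below ``tol`` or after
        ``max_iter`` sweeps; non-convergence logs a warning and returns the
        last iterate.
    seed
        Seeds the forest; the procedure is deterministic given it.
    """
    if not study.log_scale:
        raise ValueError("impute after log2 transformation")
    mask = study.missing_mask.to_numpy()
    if not mask.any():
        return study.copy()
    fully_missing = mask.all(axis=1)
    if fully_missing.any():
        raise ValueError(
            f"feature '{study.values.index[np.argmax(fully_missing)]}' has no observed values"
        )

    # samples are the observations, features the variables
    X = study.values.to_numpy(dtype=float).T.copy()   # samples x features
    miss = mask.T                                      # samples x features
    col_means = np.nanmean(X, axis=0)
    for j in range(X.shape[1]):
        X[miss[:, j], j] = col_means[j]

    if method == "mean":
        return _rebuild(study, X)

    # visit order: most missing first, ties by feature id
    counts = miss.sum(axis=0)
    order = sorted(
        (j for j in range(X.shape[1]) if counts[j] > 0),
        key=lambda j: (-counts[j], str(study.values.index[j])),
    )

    prev = X[miss].copy()
    converged = False
    for it in range(max_iter):
        for j in order:
            obs = ~miss[:, j]
            other = np.ones(X.shape[1], dtype=bool)
            other[j] = False
            # seed fixed per feature (not per sweep): the sweep is then a
            # deterministic fixed-point iteration and gamma can converge
            reg = _make_regressor(method, seed * 100003 + j)
            if np.ptp(X[obs, j]) == 0.0:
                # constant feature: regression is degenerate, impute the constant
                X[miss[:, j], j] = X[obs, j][0]
                continue
            reg.fit(X[np.ix_(obs, other)], X[obs, j])
            X[miss[:, j], j] = reg.predict(X[np.ix_(miss[:, j], other)])
        cur = X[miss]
        denom = float(np.sum(cur**2))
        gamma = float(np.sum((cur - prev) ** 2)) / denom if denom > 0 else 0.0
        prev = cur.copy()
        if gamma < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "imputation did not converge in %d iterations (gamma=%.3g); "
            "returning last iterate",
            max_iter,
            gamma,
        )
    return _rebuild(study, X)


def _rebuild(study: ExpressionStudy, X: np.ndarray) -> ExpressionStudy:
    out = study.copy()
    out.values.loc[:, :] = X.T
    return out
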