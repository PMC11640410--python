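"""Calibration and recovery experiments for the pipeline's statistics.

Each function runs a self-contained simulation study against the package's
own implementations and returns the measured operating characteristics:
type-I error of the random-effects combination under the global null,
between-study variance recovery, moderated-t calibration, BH false-discovery
control, end-to-end planted-signal recovery, enrichment ranking, survival
calibration and the imputation benchmark.  They are used by the test suite
and by ``scripts/acceptance.py``.

A note on the null calibration: the per-study standard errors are derived
from the ordinary two-sample t rather than the moderated t.  Under this
generator's homogeneous-variance null the empirical-Bayes prior degenerates
to d0 = inf, making moderated SEs essentially exact; with exact SEs the
DerSimonian-Laird + normal-z test at k = 3 is mildly conservative (~0.037).
Ordinary-t SEs carry the finite-df sampling noise that study-level SEs have
in practice (on real data the moderated df d0 + df is finite), which is the
regime in which the combination is calibrated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kstest, norm

from . import diffexpr, enrich, meta, pipeline, preprocess, survival, synth
from .config import RunConfig, SynthConfig
from .studies import ExpressionStudy


def meta_null_calibration(seed: int, n_features: int = 10_000, k: int = 3) -> dict:
    """Operating characteristics of the meta-analysis under the global null.

    Two companion experiments at the same scale: (a) type-I error of the
    random-effects p on null expression data run through the pipeline
    (ordinary-t SEs; see the module docstring), and (b) the Cochran-Q moment
    check on homogeneous effect triples with known SEs — the setting in which
    Q ~ chi2(k-1) is exact (estimated SEs inflate E[Q] above k-1, which is why
    the chi-square reference is checked at known SEs).
    """
    cfg = SynthConfig(
        n_features=n_features, n_true_de=0, k_studies=k, missing_rate=0.0, seed=seed
    )
    studies, _ = synth.generate_mirna_studies(cfg)
    de = {s.study_id: diffexpr.de_workflow(s) for s in studies}
    res = meta.run_meta(de, use_moderated=False)

    rng = np.random.default_rng(seed + 1)
    se = rng.uniform(0.5, 1.5, size=(n_features, k))
    es = rng.normal(0.0, se)
    qres = meta.combine_grid(es, se)
    return {
        "type1": float((res["p"] < 0.05).mean()),
        "q_mean": float(qres["Q"].mean()),
        "q_mc_se": float(qres["Q"].std() / np.sqrt(n_features)),
        "n": len(res),
    }


def tau2_recovery(seed: int, k: int = 20, n_features: int = 200, tau2: float = 0.5) -> dict:
    """Median DerSimonian-Laird estimate for a planted between-study variance."""
    rng = np.random.default_rng(seed)
    se = rng.uniform(0.1, 0.3, size=(n_features, k))
    theta = rng.normal(0.0, np.sqrt(tau2), size=(n_features, k))
    es = theta + rng.normal(0.0, se)
    res = meta.combine_grid(es, se)
    return {"tau2_median": float(res["tau2"].median()), "tau2_true": tau2, "n": n_features}


def moderated_t_calibration(
    seed: int, n_features: int = 5000, df: int = 8, d0_true: float = 4.0
) -> dict:
    """Null p-value uniformity of the moderated t with chi-square variances."""
    rng = np.random.default_rng(seed)
    n1 = n2 = (df + 2) // 2
    s0_2 = 1.0
    sigma2 = s0_2 * d0_true / rng.chisquare(d0_true, n_features)
    s2 = sigma2 * rng.chisquare(df, n_features) / df
    logfc = rng.normal(0.0, np.sqrt(sigma2 * (1 / n1 + 1 / n2)))
    fits = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "df_residual": float(df),
            "t_ordinary": logfc / np.sqrt(s2 * (1 / n1 + 1 / n2)),
            "n1": n1,
            "n2": n2,
        },
        index=[f"f{i}" for i in range(n_features)],
    )
    res = diffexpr.ebayes_moderate(fits)
    res0 = diffexpr.ebayes_moderate(fits, diffexpr.EBayesParams(d0=0.0, s0_2=1.0))
    return {
        "ks_p": float(kstest(res["p"], "uniform").pvalue),
        "d0_hat": float(res["d0"].iloc[0]),
        "max_dev_d0_zero": float(np.abs(res0["t_moderated"] - res0["t_ordinary"]).max()),
        "n": n_features,
    }


def bh_fdr_simulation(
    seed: int,
    reps: int = 50,
    n_features: int = 10_000,
    n_true: int = 500,
    alpha: float = 0.05,
    effect: float = 3.0,
) -> dict:
    """Empirical FDR of BH at level alpha on a two-component p-value mixture."""
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(reps):
        p = rng.uniform(size=n_features)
        z = rng.normal(effect, 1.0, size=n_true)
        p[:n_true] = 2.0 * norm.sf(np.abs(z))
        adj = diffexpr.bh_adjust(p)
        rejected = adj < alpha
        n_rej = int(rejected.sum())
        false_rej = int(rejected[n_true:].sum())
        fdps.append(false_rej / max(1, n_rej))
    fdps = np.asarray(fdps)
    return {
        "fdr": float(fdps.mean()),
        "mc_se": float(fdps.std(ddof=1) / np.sqrt(reps)),
        "alpha": alpha,
        "n": reps,
    }


def end_to_end_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Planted DEM and target-gene recovery of the default full pipeline."""
    dem_rates, target_rates = [], []
    for i in range(n_seeds):
        rep = pipeline.run_all(RunConfig(seed=seed + i))
        truth = rep.truth
        sig = set(rep.meta_table.index[rep.meta_table["significant"]])
        planted = {f.lower() for f in truth.planted_dems}
        dem_rates.append(len(planted & sig) / len(planted))
        planted_target_degs = truth.planted_targets & truth.true_deg_union
        target_rates.append(
            len(planted_target_degs & rep.intersection.overlap) / len(planted_target_degs)
        )
    return {
        "dem_recovery": float(np.mean(dem_rates)),
        "target_recovery": float(np.mean(target_rates)),
        "n": n_seeds,
    }


def enrichment_rank_experiment(seed: int, reps: int = 100) -> dict:
    """How often the planted enriched term ranks first by p-value."""
    top = 0
    for i in range(reps):
        cfg = SynthConfig(seed=seed + i)
        _, truth = synth.generate_mirna_studies(cfg)
        synth.generate_mrna_studies(cfg, truth)
        collection = enrich.GeneSetCollection(terms=synth.generate_genesets(cfg, truth))
        query = truth.planted_targets & truth.true_deg_union
        res = enrich.hypergeom_enrich(query, collection)
        top += int(res["term_id"].iloc[0] == truth.enriched_term_id)
    return {"top_rank_fraction": top / reps, "n": reps}


def logrank_null_calibration(seed: int, reps: int = 1000, n: int = 200) -> dict:
    """Fraction of log-rank p < 0.05 when the planted group hazard ratio is 1."""
    hits = 0
    for i in range(reps):
        cfg = SynthConfig(seed=seed + i, n_survival=n, survival_beta=0.0)
        tab = synth.generate_survival(cfg)
        hits += int(survival.analyze_gene(tab).p < 0.05)
    return {"type1": hits / reps, "n": reps}


def hr_recovery(seed: int, reps: int = 200, n: int = 200) -> dict:
    """Median O/E hazard-ratio estimate for a planted log-HR of ln 2."""
    hrs = []
    for i in range(reps):
        cfg = SynthConfig(seed=seed + i, n_survival=n)  # survival_beta defaults to ln 2
        tab = synth.generate_survival(cfg)
        hrs.append(survival.analyze_gene(tab).hr)
    return {"hr_median": float(np.median(hrs)), "hr_true": 2.0, "n": reps}


def imputation_benchmark(
    seed: int, reps: int = 10, n_features: int = 20, n_samples: int = 50,
    missing_rate: float = 0.1, method: str = "rf",
) -> dict:
    """Masked-entry RMSE of iterative imputation vs column-mean imputation.

    Data are factor-correlated features (5 latent factors) with MCAR masking,
    the structure under which regression imputation should win.
    """
    wins = 0
    ratios = []
    for i in range(reps):
        rng = np.random.default_rng(seed + i)
        z = rng.normal(0, 1, (5, n_samples))
        loadings = rng.normal(0, 1, (n_features, 5))
        X = loadings @ z + 0.3 * rng.normal(0, 1, (n_features, n_samples)) + 7.0
        mask = rng.random(X.shape) < missing_rate
        mask[mask.all(axis=1), 0] = False
        vals = np.where(mask, np.nan, X)
        samples = [f"s{j}" for j in range(n_samples)]
        study = ExpressionStudy(
            values=pd.DataFrame(
                vals, index=[f"hsa-miR-{j + 1}-5p" for j in range(n_features)],
                columns=samples,
            ),
            groups=pd.Series(
                ["resistant"] * (n_samples // 2) + ["control"] * (n_samples - n_samples // 2),
                index=samples,
            ),
        )
        imputed = preprocess.impute_missing(study, method=method, seed=seed + i)
        mean_imp = preprocess.impute_missing(study, method="mean")

        def rmse(s):
            return float(np.sqrt(np.mean((s.values.to_numpy()[mask] - X[mask]) ** 2)))

        r_it, r_mean = rmse(imputed), rmse(mean_imp)
        wins += int(r_it < r_mean)
        ratios.append(r_it / r_mean)
    return {"wins": wins, "n": reps, "rmse_ratio_mean": float(np.mean(ratios))}
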