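import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirmeta import diffexpr, meta, synth
from mirmeta.config import SynthConfig
from tests.conftest import two_group_study


def dl_oracle(es, se):
    """Independently coded DerSimonian-Laird closed forms (plain Python)."""
    k = len(es)
    w = [1.0 / s**2 for s in se]
    sw = sum(w)
    es_fixed = sum(wi * ei for wi, ei in zip(w, es)) / sw
    q = sum(wi * (ei - es_fixed) ** 2 for wi, ei in zip(w, es))
    c = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - (k - 1)) / c)
    ws = [1.0 / (s**2 + tau2) for s in se]
    sws = sum(ws)
    es_meta = sum(wi * ei for wi, ei in zip(ws, es)) / sws
    return es_meta, 1.0 / math.sqrt(sws), tau2, q


def test_derive_se_examples():
    assert meta.derive_se(1.0, 4.0) == pytest.approx(0.25)
    assert meta.derive_se(-2.0, -4.0) == pytest.approx(0.5)
    assert np.isnan(meta.derive_se(1.0, 0.0))


def test_cochran_q_examples():
    q, qp, df = meta.cochran_q([0.8, 0.8, 0.8], [0.2, 0.2, 0.2])
    assert q == pytest.approx(0.0, abs=1e-12)
    assert qp == pytest.approx(1.0)
    assert df == 2
    q, _, df = meta.cochran_q([1.0, -1.0], [1.0, 1.0])
    assert q == pytest.approx(2.0)
    assert df == 1
    with pytest.raises(ValueError):
        meta.cochran_q([1.0], [1.0])


def test_q_null_moments():
    # homogeneous triples: Q ~ chi2(2), so the empirical mean is ~2
    rng = np.random.default_rng(8)
    n = 10_000
    se = rng.uniform(0.5, 1.5, size=(n, 3))
    es = rng.normal(0.0, se)
    res = meta.combine_grid(es, se)
    mc_se = res["Q"].std() / np.sqrt(n)
    assert abs(res["Q"].mean() - 2.0) < 3 * mc_se
    assert abs(np.quantile(res["Q"], 0.95) - 5.991) < 0.25


def test_dl_hand_computations():
    r = meta.random_effects_combine([0.8, 0.8, 0.8], [0.2, 0.2, 0.2])
    assert r["tau2"] == pytest.approx(0.0)
    assert r["es_meta"] == pytest.approx(0.8)
    assert r["se_meta"] == pytest.approx(0.2 / math.sqrt(3))

    r = meta.random_effects_combine([1.0, -1.0], [1.0, 1.0])
    assert r["tau2"] == pytest.approx(1.0)
    assert r["es_meta"] == pytest.approx(0.0, abs=1e-12)
    assert r["Q"] == pytest.approx(2.0)


def test_dl_matches_independent_oracle_on_random_tables():
    rng = np.random.default_rng(11)
    for _ in range(100):
        k = int(rng.integers(2, 8))
        es = rng.normal(0, 1, k)
        se = rng.uniform(0.1, 2.0, k)
        r = meta.random_effects_combine(es, se)
        es_o, se_o, tau2_o, q_o = dl_oracle(list(es), list(se))
        assert r["es_meta"] == pytest.approx(es_o, abs=1e-10)
        assert r["se_meta"] == pytest.approx(se_o, abs=1e-10)
        assert r["tau2"] == pytest.approx(tau2_o, abs=1e-10)
        assert r["Q"] == pytest.approx(q_o, abs=1e-10)


def test_dl_matches_metafor(tmp_path):
    """Cross-check the DL estimate, tau2 and Q against R metafor."""
    import shutil
    import subprocess

    rng = np.random.default_rng(21)
    rows = []
    for f in range(5):
        k = int(rng.integers(3, 6))
        for s in range(k):
            rows.append((f, rng.normal(0, 1), float(rng.uniform(0.2, 1.0))))
    df = pd.DataFrame(rows, columns=["feature", "es", "se"])
    csv = tmp_path / "effects.csv"
    out = tmp_path / "metafor.csv"
    df.to_csv(csv, index=False)
    script = f"""
suppressMessages(library(metafor))
d <- read.csv("{csv}")
res <- do.call(rbind, lapply(split(d, d$feature), function(s) {{
  r <- rma(yi = s$es, sei = s$se, method = "DL", test = "z")
  data.frame(feature = s$feature[1], b = as.numeric(r$b), se = r$se,
             tau2 = r$tau2, Q = r$QE)
}}))
write.csv(res, "{out}", row.names = FALSE)
"""
    rscript = shutil.which("Rscript")
    assert rscript, "Rscript not on PATH"
    subprocess.run([rscript, "-e", script], check=True, capture_output=True)
    ref = pd.read_csv(out).set_index("feature")
    for f, grp in df.groupby("feature"):
        r = meta.random_effects_combine(grp["es"].to_numpy(), grp["se"].to_numpy())
        assert r["es_meta"] == pytest.approx(ref.loc[f, "b"], abs=1e-6)
        assert r["se_meta"] == pytest.approx(ref.loc[f, "se"], abs=1e-6)
        assert r["tau2"] == pytest.approx(ref.loc[f, "tau2"], abs=1e-6)
        assert r["Q"] == pytest.approx(ref.loc[f, "Q"], abs=1e-6)


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=-5, max_value=5),
            st.floats(min_value=0.05, max_value=3.0),
        ),
        min_size=2,
        max_size=8,
    )
)
def test_combined_effect_is_convex_combination(table):
    es = [t[0] for t in table]
    se = [t[1] for t in table]
    r = meta.random_effects_combine(es, se)
    assert min(es) - 1e-9 <= r["es_meta"] <= max(es) + 1e-9
    assert r["tau2"] >= 0
    assert r["Q"] >= -1e-12


def test_random_equals_fixed_when_tau2_zero():
    es = [0.5, 0.5, 0.5]
    se = [0.1, 0.2, 0.3]
    rnd = meta.random_effects_combine(es, se, model="random")
    fix = meta.random_effects_combine(es, se, model="fixed")
    assert rnd["tau2"] == 0.0
    assert rnd["es_meta"] == pytest.approx(fix["es_meta"], abs=1e-14)
    assert rnd["se_meta"] == pytest.approx(fix["se_meta"], abs=1e-14)


def _de_tables(rng, effects, k=3, n=10, sigma=0.5):
    tables = {}
    for s in range(k):
        study = two_group_study(
            rng, n_features=len(effects), n1=n, n2=n,
            effects=effects, sigma=sigma, study_id=f"st{s}",
        )
        tables[f"st{s}"] = diffexpr.ebayes_moderate(diffexpr.fit_two_group(study))
    return tables


def test_run_meta_sign_recovery(rng):
    effects = np.array([3.0] * 5 + [-3.0] * 5 + [0.0] * 30)
    res = meta.run_meta(_de_tables(rng, effects), alpha=0.05)
    sig = res[res["significant"]]
    up = sig[sig["direction"] == "up"]
    down = sig[sig["direction"] == "down"]
    planted_up = {f"hsa-mir-{i + 1}-5p" for i in range(5)}
    planted_down = {f"hsa-mir-{i + 1}-5p" for i in range(5, 10)}
    assert planted_up <= set(up.index)
    assert planted_down <= set(down.index)


def test_run_meta_drops_features_absent_from_two_studies(rng):
    tables = _de_tables(rng, np.zeros(6))
    only_once = tables["st0"].index[0]
    for sid in ["st1", "st2"]:
        tables[sid] = tables[sid].drop(index=only_once)
    res = meta.run_meta(tables)
    assert only_once.lower() not in res.index
    assert res["k"].min() >= 2


def test_run_meta_power_for_single_planted_dem():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        effects = np.zeros(30)
        effects[0] = 2.0  # planted DEM at the default effect size
        tables = {}
        for s in range(3):
            theta = rng.normal(2.0, np.sqrt(0.05))
            eff = effects.copy()
            eff[0] = theta
            study = two_group_study(rng, n_features=30, n1=10, n2=10,
                                    effects=eff, study_id=f"st{s}")
            tables[f"st{s}"] = diffexpr.ebayes_moderate(diffexpr.fit_two_group(study))
        res = meta.run_meta(tables)
        hits += bool(res.loc["hsa-mir-1-5p", "adj_p"] < 0.05)
    assert hits >= 95


def test_smd_effect_scale_runs_and_agrees_in_sign(rng):
    effects = np.array([2.5] * 3 + [0.0] * 17)
    tables = _de_tables(rng, effects)
    lfc = meta.run_meta(tables, effect="lfc")
    smd = meta.run_meta(tables, effect="smd")
    shared = lfc.index.intersection(smd.index)
    agree = np.sign(lfc.loc[shared, "es_meta"]) == np.sign(smd.loc[shared, "es_meta"])
    assert agree.mean() > 0.9
    assert (smd.loc[[f"hsa-mir-{i+1}-5p" for i in range(3)], "adj_p"] < 0.05).all()
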