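import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from mirmeta import synth
from mirmeta.config import SynthConfig


def _small_cfg(**kw):
    defaults = dict(n_features=60, n_true_de=8, n_genes=200, seed=3)
    defaults.update(kw)
    return SynthConfig(**defaults)


def test_seed_determinism_across_all_generators():
    outs = []
    for _ in range(2):
        cfg = _small_cfg()
        studies, truth = synth.generate_mirna_studies(cfg)
        mrna = synth.generate_mrna_studies(cfg, truth)
        inter = synth.generate_interactions(truth, cfg)
        terms = synth.generate_genesets(cfg, truth)
        edges = synth.generate_edgelist(cfg, truth)
        surv = synth.generate_survival(cfg, truth)
        outs.append((studies, mrna, inter, terms, edges, surv))
    for s1, s2 in zip(outs[0][0] + outs[0][1], outs[1][0] + outs[1][1]):
        pd.testing.assert_frame_equal(s1.values, s2.values)
    pd.testing.assert_frame_equal(outs[0][2], outs[1][2])
    assert outs[0][3] == outs[1][3]
    pd.testing.assert_frame_equal(outs[0][4], outs[1][4])
    pd.testing.assert_frame_equal(outs[0][5], outs[1][5])


def test_missingness_and_decoys():
    cfg = _small_cfg(missing_rate=0.0)
    studies, _ = synth.generate_mirna_studies(cfg)
    assert all(not s.missing_mask.to_numpy().any() for s in studies)

    cfg = _small_cfg(missing_rate=0.2)
    studies, truth = synth.generate_mirna_studies(cfg)
    rate = np.mean([s.missing_mask.to_numpy().mean() for s in studies])
    assert 0.1 < rate < 0.3
    # no feature entirely missing, by construction
    for s in studies:
        assert not s.missing_mask.all(axis=1).any()

    ids = studies[0].feature_ids
    n_decoy = sum(not f.startswith("hsa") for f in ids)
    assert n_decoy == round(cfg.decoy_fraction * cfg.n_features)
    # planted DEMs are always human-prefixed
    assert all(f.startswith("hsa") for f in truth.planted_dems)


def test_rejects_degenerate_group_size():
    with pytest.raises(ValueError, match="samples_per_group"):
        SynthConfig(samples_per_group=1)


def test_every_planted_dem_has_a_target():
    _, truth = synth.generate_mirna_studies(_small_cfg())
    assert set(truth.target_map) == truth.planted_dems
    assert all(len(g) >= 1 for g in truth.target_map.values())


def test_null_feature_variance_approaches_sigma2():
    cfg = _small_cfg(n_true_de=0, samples_per_group=200, missing_rate=0.0, sigma2=0.25)
    studies, _ = synth.generate_mirna_studies(cfg)
    v = studies[0].group_matrix("control").var(axis=1, ddof=1)
    assert abs(v.mean() - cfg.sigma2) < 0.02


def test_realized_effect_variance_consistent_with_tau2():
    # 300 realized deviations theta_is - mu_i; their variance should sit in a
    # chi-square interval around tau2
    cfg = _small_cfg(n_features=100, n_true_de=15, k_studies=20, tau2=0.3,
                     missing_rate=0.0, seed=7)
    _, truth = synth.generate_mirna_studies(cfg)
    devs = []
    for fid, rec in truth.de_features.items():
        devs.extend(t - rec["mu"] for t in rec["per_study"].values())
    devs = np.asarray(devs)
    n = devs.size
    assert n == 300
    s2 = devs.var(ddof=0)
    lo = cfg.tau2 * chi2.ppf(0.005, n) / n
    hi = cfg.tau2 * chi2.ppf(0.995, n) / n
    assert lo < s2 < hi


def test_raw_scale_emits_positive_intensities():
    cfg = _small_cfg(raw_scale=True, missing_rate=0.0)
    studies, _ = synth.generate_mirna_studies(cfg)
    assert not studies[0].log_scale
    assert (studies[0].values.to_numpy() > 0).all()


@pytest.mark.parametrize("fraction,expect_any", [(1.0, True), (0.0, False)])
def test_target_de_fraction_extremes(fraction, expect_any):
    cfg = _small_cfg(target_de_fraction=fraction)
    _, truth = synth.generate_mirna_studies(cfg)
    synth.generate_mrna_studies(cfg, truth)
    overlap = truth.planted_targets & truth.true_deg_union
    if expect_any:
        assert overlap == truth.planted_targets  # every target DE in >= 1 study
    else:
        assert not overlap


def test_interactions_contain_planted_pairs_without_duplicates():
    cfg = _small_cfg(n_decoy_interactions=0)
    _, truth = synth.generate_mirna_studies(cfg)
    table = synth.generate_interactions(truth, cfg)
    pairs = set(zip(table["mirna_id"], table["gene_symbol"]))
    planted = {(m, g) for m, genes in truth.target_map.items() for g in genes}
    assert pairs == planted
    assert (table["validated"] == 1).all()

    cfg2 = _small_cfg(n_decoy_interactions=150)
    _, truth2 = synth.generate_mirna_studies(cfg2)
    table2 = synth.generate_interactions(truth2, cfg2)
    assert not table2.duplicated(["mirna_id", "gene_symbol"]).any()
    assert len(table2) == len(planted) + 150


def test_edgelist_hub_degree_strictly_maximal():
    cfg = _small_cfg()
    _, truth = synth.generate_mirna_studies(cfg)
    synth.generate_mrna_studies(cfg, truth)
    edges = synth.generate_edgelist(cfg, truth)
    deg = pd.concat([edges["node_a"], edges["node_b"]]).value_counts()
    hub = truth.hub_gene
    assert deg.idxmax() == hub
    assert (deg.drop(hub) < deg[hub]).all()


def test_survival_table_shape_and_grouping():
    cfg = _small_cfg(n_survival=50)
    surv = synth.generate_survival(cfg)
    assert len(surv) == 50
    assert set(surv["event"].unique()) <= {0, 1}
    assert (surv["time"] > 0).all()
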