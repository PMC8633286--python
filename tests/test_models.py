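"""Multivariate models: imputation, splitting, forest evaluation, leakage."""

import numpy as np
import pandas as pd
import pytest

from csfpanel.models import (EMNormalImputer, ModelSpec, fit_and_evaluate,
                             impute_missing, run_model_suite, select_features,
                             split_cohort)
from csfpanel.synthetic import generate_feature_table


def test_impute_complete_table_is_noop():
    t = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    out = impute_missing(t)
    pd.testing.assert_frame_equal(out[0], t)


def test_impute_correlated_pair_tracks_partner():
    rng = np.random.default_rng(0)
    z = rng.standard_normal(300)
    full = pd.DataFrame({"a": z, "b": 2 * z + 0.05 * rng.standard_normal(300)})
    obs = full.copy()
    obs.iloc[:80, 1] = np.nan
    comp = impute_missing(obs)[0]
    err = np.abs(comp.iloc[:80, 1] - full.iloc[:80, 1])
    assert err.mean() < 0.2  # partner carries nearly all the information


def test_impute_mcar_rmse_near_oracle():
    """EM imputation within 1.3x the RMSE of the true-covariance oracle."""
    rng = np.random.default_rng(1)
    p = 4
    a = rng.normal(size=(p, p))
    cov = a @ a.T + np.eye(p)
    mean = np.array([1.0, -1.0, 0.5, 0.0])
    x = rng.multivariate_normal(mean, cov, size=400)
    mask = rng.uniform(size=x.shape) < 0.10
    for j in range(p):  # keep every column partially observed
        mask[0, j] = False
    obs = x.copy()
    obs[mask] = np.nan
    comp = impute_missing(pd.DataFrame(obs))[0].to_numpy()
    # oracle: conditional mean under the true MVN parameters
    oracle = obs.copy()
    for i in range(len(obs)):
        miss = np.isnan(obs[i])
        if miss.any():
            o = ~miss
            sol = np.linalg.solve(cov[np.ix_(o, o)], obs[i, o] - mean[o])
            oracle[i, miss] = mean[miss] + cov[np.ix_(miss, o)] @ sol
    rmse_em = np.sqrt(np.mean((comp[mask] - x[mask]) ** 2))
    rmse_oracle = np.sqrt(np.mean((oracle[mask] - x[mask]) ** 2))
    assert rmse_em <= 1.3 * rmse_oracle


def test_impute_rejects_fully_missing_column():
    t = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
    with pytest.raises(ValueError, match="fully missing|column"):
        impute_missing(t)


def test_multiple_imputations_vary_but_preserve_observed():
    rng = np.random.default_rng(2)
    t = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
    t.iloc[:10, 0] = np.nan
    outs = impute_missing(t, n_imputations=3, seed=5)
    assert len(outs) == 3
    for out in outs:
        assert not out.isna().any().any()
        pd.testing.assert_frame_equal(out.iloc[10:], t.iloc[10:])
    assert not np.allclose(outs[0].iloc[:10, 0], outs[1].iloc[:10, 0])


def test_split_counts_stratification_determinism():
    t, labels = generate_feature_table(n_pd=70, n_ap=30, seed=0)
    train, test = split_cohort(t, labels, fraction=0.7, seed=1)
    assert len(train) == 70 and len(test) == 30
    assert set(train).isdisjoint(test)
    assert set(train) | set(test) == set(t.index)
    # 46 PD + 25 AP stratified: class ratio preserved within one sample
    t2, l2 = generate_feature_table(n_pd=46, n_ap=25, seed=0)
    tr, te = split_cohort(t2, l2, fraction=0.7, seed=3)
    frac_tr = (l2.loc[tr] == "PD").mean()
    assert abs(frac_tr - 46 / 71) <= 1 / len(tr)
    tr2, te2 = split_cohort(t2, l2, fraction=0.7, seed=3)
    assert list(tr) == list(tr2) and list(te) == list(te2)


def test_split_rejects_single_class():
    t, labels = generate_feature_table(n_pd=10, n_ap=5, seed=0)
    with pytest.raises(ValueError):
        split_cohort(t, pd.Series("PD", index=t.index), fraction=0.7, seed=0)


def test_select_features_families():
    t, _ = generate_feature_table(seed=0)
    f1 = select_features(t, ("peptides",))
    assert all(c.startswith("pep_") for c in f1) and len(f1) == 14
    f2 = select_features(t, ("peptides", "markers", "age"))
    assert "NfL" in f2 and "age" in f2 and "UPDRS" not in f2
    f4 = select_features(t, ("markers", "clinical", "age"))
    assert "UPDRS" in f4 and not any(c.startswith("pep_") for c in f4)
    with pytest.raises(ValueError):
        select_features(t[["age"]], ("peptides",))


def test_single_discriminating_feature_gives_perfect_auc():
    t, labels = generate_feature_table(n_pd=30, n_ap=20, n_peptides=1, seed=0)
    t["pep_01"] = np.where(labels == "AP", 0.1, 1.0)
    res = fit_and_evaluate(ModelSpec(dataset_id=1, seed=0, n_trees=50),
                           t, labels)
    assert res.held_out_auc == pytest.approx(1.0)


def test_no_leakage_from_test_fold():
    """At a fixed split, perturbing test labels changes nothing fitted."""
    t, labels = generate_feature_table(n_pd=40, n_ap=25, missing_rate=0.1,
                                       seed=4)
    spec = ModelSpec(dataset_id=2, seed=7, n_trees=50)
    split = split_cohort(t, labels, fraction=0.7, seed=7)
    res1 = fit_and_evaluate(spec, t, labels, split=split)
    flipped = labels.copy()
    # flip one test-fold label; train fold and fitted pipeline are untouched
    tid = res1.test_ids[0]
    flipped.loc[tid] = "PD" if flipped.loc[tid] == "AP" else "AP"
    res2 = fit_and_evaluate(spec, t, flipped, split=split)
    assert res1.train_ids == res2.train_ids
    assert res1.feature_importances == res2.feature_importances


def test_null_data_auc_near_chance():
    aucs = []
    for seed in range(20):
        t, labels = generate_feature_table(seed=seed)
        res = fit_and_evaluate(ModelSpec(dataset_id=1, seed=seed, n_trees=100),
                               t, labels)
        aucs.append(res.held_out_auc)
    assert 0.35 <= np.mean(aucs) <= 0.65


def test_noise_feature_barely_moves_planted_auc():
    effects = {f"pep_{i:02d}": 1.6 for i in range(1, 7)}
    base, noisy = [], []
    for seed in range(10):
        t, labels = generate_feature_table(seed=seed, peptide_effects=effects)
        r1 = fit_and_evaluate(ModelSpec(1, seed=seed, n_trees=100), t, labels)
        t2 = t.copy()
        t2["pep_15"] = np.random.default_rng(seed).normal(size=len(t2))
        r2 = fit_and_evaluate(ModelSpec(1, seed=seed, n_trees=100), t2, labels)
        base.append(r1.held_out_auc)
        noisy.append(r2.held_out_auc)
    assert abs(np.mean(base) - np.mean(noisy)) < 0.05


def test_importance_selection_retains_signal_feature():
    t, labels = generate_feature_table(n_pd=40, n_ap=25, n_peptides=4, seed=0)
    t["pep_01"] = np.where(labels == "AP", 0.1, 1.0) \
        + np.random.default_rng(0).normal(0, 0.01, len(t))
    spec = ModelSpec(dataset_id=1, seed=0, n_trees=50,
                     importance_selection=True, importance_quantile=0.75)
    res = fit_and_evaluate(spec, t, labels)
    assert "pep_01" in res.retained_features
    assert len(res.retained_features) < 4


def test_run_model_suite_shapes_and_determinism():
    effects = {f"pep_{i:02d}": 1.3 for i in range(1, 7)}
    t, labels = generate_feature_table(seed=0, peptide_effects=effects,
                                       marker_effects={"NfL": 1.5})
    specs = [ModelSpec(dataset_id=d, seed=3, n_trees=60) for d in (1, 2, 3, 4)]
    results, comparison = run_model_suite(t, labels, specs)
    assert [r.dataset_id for r in results] == [1, 2, 3, 4]
    assert comparison["held_out_auc"].notna().all()
    results2, comparison2 = run_model_suite(t, labels, specs)
    pd.testing.assert_frame_equal(comparison, comparison2)


def test_run_model_suite_markers_add_signal():
    """Dataset 2 (peptides+markers) beats dataset 1 when a marker is strong."""
    a1, a2 = [], []
    effects = {f"pep_{i:02d}": 1.2 for i in range(1, 7)}
    for seed in range(10):
        t, labels = generate_feature_table(seed=seed, peptide_effects=effects,
                                           marker_effects={"NfL": 2.0})
        r, _ = run_model_suite(t, labels,
                               [ModelSpec(1, seed=seed, n_trees=100),
                                ModelSpec(2, seed=seed, n_trees=100)])
        a1.append(r[0].held_out_auc)
        a2.append(r[1].held_out_auc)
    assert np.mean(a2) >= np.mean(a1)


def test_run_model_suite_missing_family_errors_but_continues():
    t, labels = generate_feature_table(seed=0)
    t = t[[c for c in t.columns if c.startswith("pep_")]]
    results, comparison = run_model_suite(
        t, labels, [ModelSpec(1, seed=0, n_trees=30),
                    ModelSpec(4, seed=0, n_trees=30)])
    assert results[0].error is None
    assert results[1].error is not None
    assert np.isnan(results[1].held_out_auc)


def test_run_model_suite_empty_specs():
    t, labels = generate_feature_table(seed=0)
    results, comparison = run_model_suite(t, labels, [])
    assert results == [] and comparison.empty


def test_em_imputer_requires_fit():
    with pytest.raises(RuntimeError):
        EMNormalImputer().transform(np.zeros((2, 2)))
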