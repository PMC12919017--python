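"""Cohort statistics: NCI rule, group models, mediation, Fisher, LME."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import neuroage as na
from neuroage.inference import DesignError


# ---------------------------------------------------------------- NCI rule
def test_classify_nci_boundary_and_counts():
    table = pd.DataFrame(
        {
            "participant_id": ["a", "b", "c", "d"],
            "d1": [50.0, 40.0, 20.0, 40.0],
            "d2": [50.0, 40.0, 55.0, 39.9],
            "d3": [50.0, 55.0, 55.0, 55.0],
        }
    )
    flags, rejected = na.classify_nci(table)
    assert not rejected
    # all-average -> unimpaired; exactly two domains at the inclusive
    # boundary (T = 40 = mean - 1 SD) -> impaired; one extreme domain -> not
    assert list(flags) == [False, True, False, True]


def test_classify_nci_rejects_incomplete_rows():
    table = pd.DataFrame(
        {"participant_id": ["a", "b"], "d1": [50.0, np.nan], "d2": [50.0, 30.0]}
    )
    flags, rejected = na.classify_nci(table)
    assert rejected == ["b"] and list(flags) == [False]
    with pytest.raises(ValueError):
        na.classify_nci(table[["participant_id", "d1"]])


# ---------------------------------------------------------------- FDR
def test_fdr_adjust_hand_computed():
    np.testing.assert_allclose(na.fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert na.fdr_adjust([0.2])[0] == pytest.approx(0.2)
    np.testing.assert_allclose(na.fdr_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        na.fdr_adjust([0.5, 1.5])


# ---------------------------------------------------------------- Fisher
def test_fisher_exact_hand_enumeration():
    # 2x2 [[3,1],[1,3]]: two-sided tail = 2*(C(4,3)C(4,1)+C(4,4)C(4,0))/C(8,4)
    assert na.fisher_exact_rxc([[3, 1], [1, 3]]) == pytest.approx(34.0 / 70.0, abs=1e-12)
    # degenerate margin: only one table possible
    assert na.fisher_exact_rxc([[34, 0], [34, 0]]) == 1.0
    with pytest.raises(ValueError):
        na.fisher_exact_rxc([[1.5, 2.0], [1.0, 1.0]])
    with pytest.raises(ValueError):
        na.fisher_exact_rxc([[-1, 2], [1, 1]])


@given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
@settings(deadline=None, max_examples=40, derandomize=True)
def test_fisher_matches_classic_two_by_two(cells):
    a, b, c, d = cells
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=1).min() <= 0 or table.sum() == 0:
        return
    mine = na.fisher_exact_rxc(table)
    theirs = stats.fisher_exact(table)[1]
    assert mine == pytest.approx(theirs, abs=1e-10)


def test_fisher_two_by_three_matches_r_reference():
    """Frozen oracle values computed with R's conditional exact test."""
    # fisher.test(matrix(c(8,2,5, 1,9,4), nrow=2, byrow=TRUE)) -> 0.007191296
    assert na.fisher_exact_rxc([[8, 2, 5], [1, 9, 4]]) == pytest.approx(
        0.007191296, abs=1e-8
    )


# ---------------------------------------------------------------- group model
def _covariates(rng, n):
    return pd.DataFrame(
        {
            "age": rng.uniform(35, 77, n),
            "sex": rng.integers(0, 2, n),
            "zung": rng.normal(41, 8, n),
        }
    )


def test_group_model_recovers_planted_differences(rng):
    g = np.repeat([0, 1, 2], 200)
    bag = np.array([0.0, 3.5, 6.3])[g] + rng.normal(0, 4, 600)
    res = na.bag_group_model(bag, g, _covariates(rng, 600))
    assert res.p_value < 1e-6
    planted = {"1-0": 3.5, "2-0": 6.3, "2-1": 2.8}
    for _, row in res.contrasts.iterrows():
        assert abs(row["estimate"] - planted[row["contrast"]]) < 3 * row["se"]
        assert row["q"] < 0.05 and row["q"] >= row["p"]


def test_group_model_equals_one_way_anova_when_unadjusted(rng):
    g = np.repeat([0, 1, 2], 50)
    y = rng.normal(0, 1, 150) + 0.5 * g
    res = na.bag_group_model(y, g)
    f, p = stats.f_oneway(y[g == 0], y[g == 1], y[g == 2])
    assert res.f_stat == pytest.approx(f, rel=1e-10)
    assert res.p_value == pytest.approx(p, rel=1e-8)
    assert (res.df_num, res.df_den) == (2, 147)


def test_morphometric_validation_shares_group_model_machinery(rng):
    g = np.repeat([0, 1, 2], 60)
    feat = -0.05 * g + rng.normal(2.5, 0.08, 180)
    cov = _covariates(rng, 180)
    a = na.morphometric_validation_model(feat, g, cov)
    b = na.bag_group_model(feat, g, cov, outcome_name="feature")
    assert a.f_stat == pytest.approx(b.f_stat)
    pd.testing.assert_frame_equal(a.contrasts, b.contrasts)
    assert a.p_value < 0.01
    order = dict(zip(a.contrasts["contrast"], a.contrasts["estimate"]))
    assert order["2-0"] < order["1-0"] < 0  # progressive thinning


# ---------------------------------------------------------------- logistic
def test_burden_logistic_matches_cross_product_odds_ratio():
    # 2x2 collapse: outcome by exposure counts (30,10,20,40) -> OR = 6
    nci = np.r_[np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)]
    group = np.r_[np.ones(40), np.zeros(60)]
    res = na.nci_burden_logistic(nci, group, n_boot=10, seed=0)
    assert res.odds_ratios["or"].iloc[0] == pytest.approx(6.0, abs=1e-8)
    # marginal standardization with no covariates collapses to raw rates
    probs = dict(zip(res.adjusted_probabilities["group"],
                     res.adjusted_probabilities["probability"]))
    assert probs[0.0] == pytest.approx(20 / 60, abs=1e-8)
    assert probs[1.0] == pytest.approx(30 / 40, abs=1e-8)


def test_bag_logistic_recovery_and_reparameterization(rng):
    n = 2000
    bag = rng.normal(3, 6, n)
    p = 1 / (1 + np.exp(-(-1.2 + 0.08 * bag)))
    nci = (rng.random(n) < p).astype(float)
    res = na.nci_bag_logistic(nci, bag)
    assert 1.05 <= res.odds_ratios["or"].iloc[0] <= 1.11
    assert res.lr_p < 0.05
    scaled = na.nci_bag_logistic(nci, bag * 10)
    assert scaled.coefficients["bag"] == pytest.approx(
        res.coefficients["bag"] / 10, rel=1e-6
    )
    with pytest.raises(DesignError):
        na.nci_bag_logistic(nci, np.zeros(n))
    with pytest.raises(DesignError):
        na.nci_bag_logistic(np.ones(n), bag)


# ---------------------------------------------------------------- factorial
def test_factorial_interaction_power_and_errors(rng):
    detected = 0
    reps = 30
    for r in range(reps):
        hiv = np.repeat([0, 1, 0, 1], 400)
        cu = np.repeat([0, 0, 1, 1], 400)
        y = 2.0 * hiv + 2.0 * cu + 2.0 * hiv * cu + rng.normal(0, 4, 1600)
        res = na.factorial_hiv_cu(y, hiv, cu, family="linear")
        pvals = dict(zip(res.terms["term"], res.terms["p"]))
        detected += pvals["hiv:cu"] < 0.05
    assert detected / reps > 0.9
    with pytest.raises(DesignError):
        na.factorial_hiv_cu(y, hiv, hiv)


def test_factorial_logistic_detects_main_effects(rng):
    hiv = np.repeat([0, 1, 0, 1], 150)
    cu = np.repeat([0, 0, 1, 1], 150)
    p = 1 / (1 + np.exp(-(-1.5 + 1.2 * hiv + 0.8 * cu)))
    y = (rng.random(600) < p).astype(float)
    res = na.factorial_hiv_cu(y, hiv, cu, family="logistic")
    pvals = dict(zip(res.terms["term"], res.terms["p"]))
    assert pvals["hiv"] < 0.01 and pvals["cu"] < 0.05


# ---------------------------------------------------------------- mediation
def test_mediation_identity_and_recovery():
    cfg = na.SimulationConfig(
        n_per_group=(200, 200, 200), nci_link="linear", nci_intercept=0.15,
        mediation_b=0.02, direct_c=0.05, nci_zung=0.0, seed=41,
    )
    table, truth = na.simulate_clinical_cohort(cfg)
    med = na.mediation_model(
        table["group"], truth.rows["true_bag"], table["nci"], n_boot=500, seed=2
    )
    # exact decomposition: total from the outcome-only regression equals
    # direct + indirect by OLS algebra
    g = table["group"].to_numpy()
    X3 = np.column_stack([np.ones(len(g)), (g == 1).astype(float), (g == 2).astype(float)])
    c_tot = np.linalg.lstsq(X3, table["nci"].to_numpy(float), rcond=None)[0][1:]
    np.testing.assert_allclose(
        med.paths["total"], med.paths["direct"] + med.paths["indirect"], atol=1e-12
    )
    np.testing.assert_allclose(med.paths["total"], c_tot, atol=1e-12)
    for _, row in med.paths.iterrows():
        planted = {"1-0": 3.5 * 0.02, "2-0": 6.3 * 0.02}[row["contrast"]]
        assert abs(row["indirect"] - planted) < 3 * row["indirect_se"]
    assert med.indirect_difference == pytest.approx(
        med.paths["indirect"].iloc[1] - med.paths["indirect"].iloc[0]
    )


def test_mediation_null_path_covers_zero():
    cfg = na.SimulationConfig(
        n_per_group=(200, 200, 200), nci_link="linear", nci_intercept=0.3,
        mediation_b=0.0, direct_c=0.05, nci_zung=0.0, seed=43,
    )
    table, truth = na.simulate_clinical_cohort(cfg)
    med = na.mediation_model(
        table["group"], truth.rows["true_bag"], table["nci"], n_boot=400, seed=3
    )
    for _, row in med.paths.iterrows():
        assert row["indirect_lo"] <= 0.0 <= row["indirect_hi"]


def test_mediation_degenerate_inputs(clinical_table):
    table, truth = clinical_table
    with pytest.raises(DesignError):
        na.mediation_model(table["group"], np.zeros(len(table)), table["nci"])
    with pytest.raises(DesignError):
        na.mediation_model(np.zeros(len(table)), truth.rows["true_bag"], table["nci"])
    with pytest.raises(ValueError):
        na.mediation_model(table["group"], truth.rows["true_bag"], table["nci"],
                           n_boot=50)


# ---------------------------------------------------------------- LME
def _shap_long(rng, n_sub=45, subject_sd=0.3, effect=0.0, nets=("VIS", "VAN")):
    rows = []
    for i in range(n_sub):
        g = i % 3
        age, zung = rng.uniform(35, 77), rng.normal(41, 8)
        intercept = rng.normal(0, subject_sd)
        for meas in na.MEASURES:
            for net in na.NETWORKS:
                planted = effect * g if (meas == "thickness" and net in nets) else 0.0
                rows.append(
                    dict(participant_id=f"p{i:03d}", group=g, measure=meas,
                         network=net, shap=planted + intercept + rng.normal(0, 0.5),
                         age=age, sex=i % 2, education=int(rng.random() < 0.2),
                         zung=zung, euler=int(rng.normal(-40, 15)),
                         motion=abs(rng.normal(0.15, 0.07)))
                )
    return pd.DataFrame(rows)


def test_lme_zero_subject_variance_matches_ols(rng):
    long = _shap_long(rng, n_sub=30, subject_sd=0.0)
    res = na.signed_shap_lme(long)
    assert res.variance_components["participant"] < 0.01 * res.variance_components["residual"]
    import statsmodels.formula.api as smf

    covs = " + age + sex + education + zung + euler + motion"
    ols = smf.ols("shap ~ C(group)*C(network)*C(measure)" + covs, data=long).fit()
    shared = [k for k in res.fixed_effects.index if k in ols.params.index]
    # the intercept-variance estimate sits at (not exactly on) the boundary,
    # so GLS weights differ from OLS by the tiny residual variance ratio
    np.testing.assert_allclose(
        res.fixed_effects[shared], ols.params[shared], atol=5e-3
    )


def test_lme_recovers_planted_variance_components(rng):
    long = _shap_long(rng, n_sub=60, subject_sd=2.0)
    res = na.signed_shap_lme(long)
    tau_sq = res.variance_components["participant"]
    # sampling SE of the variance of 60 subject intercepts ~ tau^2*sqrt(2/59)
    assert abs(tau_sq - 4.0) < 3 * 4.0 * np.sqrt(2.0 / 59)
    assert res.variance_components["residual"] == pytest.approx(0.25, abs=0.05)


def test_lme_detects_planted_burden_network_interaction(rng):
    long = _shap_long(rng, n_sub=60, effect=0.5)
    res = na.signed_shap_lme(long)
    lrt = dict(zip(res.lrt["term"], res.lrt["p"]))
    assert lrt["group:network:measure"] < 0.05 or lrt["group:network"] < 0.05
    follow = na.shap_followup_by_measure(long, "thickness")
    assert follow["interaction"]["p"] < 0.01
    vis = follow["pairwise"].query("network == 'VIS' and contrast == '2-0'")
    assert vis["estimate"].iloc[0] > 0 and vis["q"].iloc[0] < 0.05
    flat = na.shap_followup_by_measure(long, "surface_area")
    assert flat["interaction"]["p"] > 0.01
    with pytest.raises(ValueError):
        na.shap_followup_by_measure(long, "nonexistent")
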