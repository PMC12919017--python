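"""Cohort-level statistics for brain-age-gap and impairment analyses.

Covers the full inferential toolkit of the pipeline: the neurocognitive
impairment (NCI) classification rule, covariate-adjusted group models for
the brain-age gap (Type III tests with FDR-corrected pairwise contrasts),
logistic models for impairment with marginal-standardization adjusted
probabilities, HIV x cocaine-use factorial models, a bootstrap two-equation
path (mediation) model, exact Fisher tests for 2 x C contingency tables,
and linear mixed-effects tests on signed Shapley values.

Model fitting is delegated to statsmodels; the mediation bootstrap and the
exact Fisher enumeration are implemented here directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import lgamma

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupModelResult",
    "LogisticResult",
    "MediationResult",
    "LmeResult",
    "classify_nci",
    "fdr_adjust",
    "bag_group_model",
    "morphometric_validation_model",
    "nci_burden_logistic",
    "nci_bag_logistic",
    "factorial_hiv_cu",
    "mediation_model",
    "fisher_exact_rxc",
    "signed_shap_lme",
    "shap_followup_by_measure",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "zung", "euler", "motion")


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable model design."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge."""


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_nci(
    domain_tscores: pd.DataFrame,
    mean: float = 50.0,
    sd: float = 10.0,
    threshold_sd: float = 1.0,
    min_domains: int = 2,
) -> tuple[pd.Series, list]:
    """Impairment rule: >= ``min_domains`` domains at or below mean - 1 SD.

    The boundary is inclusive (a T-score exactly at mean - threshold_sd*sd
    counts as impaired). Rows with any missing domain score are rejected
    and reported in the second return value.
    """
    domains = [c for c in domain_tscores.columns if c != "participant_id"]
    if len(domains) < 2:
        raise ValueError("need at least two cognitive domains")
    scores = domain_tscores[domains].apply(pd.to_numeric, errors="coerce")
    complete = ~scores.isna().any(axis=1)
    rejected = list(
        domain_tscores.loc[~complete, "participant_id"]
        if "participant_id" in domain_tscores.columns
        else domain_tscores.index[~complete]
    )
    cutoff = mean - threshold_sd * sd
    flags = (scores[complete] <= cutoff).sum(axis=1) >= min_domains
    return flags.rename("nci"), rejected


def _assemble(outcome_name, outcome, covariates, **extra) -> tuple[pd.DataFrame, list]:
    data = pd.DataFrame({outcome_name: np.asarray(outcome, float)})
    for name, vals in extra.items():
        data[name] = np.asarray(vals)
    cov_cols: list = []
    if covariates is not None and len(covariates):
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            data[c] = cov[c].to_numpy(float)
        cov_cols = list(cov.columns)
    return data, cov_cols


@dataclass
class GroupModelResult:
    """Type III group test with FDR-adjusted pairwise contrasts."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    contrasts: pd.DataFrame  # contrast, estimate, se, p, q
    coefficients: pd.Series


def bag_group_model(bag, group, covariates=None, outcome_name: str = "bag") -> GroupModelResult:
    """OLS of an outcome on a 3-level disorder-burden factor plus covariates.

    Uses sum-to-zero contrasts so the group term's Type III F is the test
    of any group difference adjusted for all covariates; all three
    pairwise mean differences are reported with Benjamini-Hochberg
    adjusted q-values.
    """
    data, cov_cols = _assemble(outcome_name, bag, covariates, group=np.asarray(group))
    levels = sorted(data["group"].unique())
    if len(levels) < 2:
        raise DesignError("need at least two groups")
    formula = f"{outcome_name} ~ C(group, Sum)" + "".join(f" + {c}" for c in cov_cols)
    res = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise DesignError("rank-deficient design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(res, typ=3)
    row = table.loc["C(group, Sum)"]
    names = res.model.exog_names

    def effect_vector(level):
        v = np.zeros(len(names))
        name = f"C(group, Sum)[S.{level}]"
        if name in names:
            v[names.index(name)] = 1.0
        else:  # reference (last) level: minus the sum of the others
            for lvl in levels[:-1]:
                v[names.index(f"C(group, Sum)[S.{lvl}]")] = -1.0
        return v

    rows = []
    for lo, hi in combinations(levels, 2):
        t = res.t_test(effect_vector(hi) - effect_vector(lo))
        rows.append(
            {
                "contrast": f"{hi}-{lo}",
                "estimate": float(np.squeeze(t.effect)),
                "se": float(np.squeeze(t.sd)),
                "p": float(np.squeeze(t.pvalue)),
            }
        )
    contrasts = pd.DataFrame(rows)
    contrasts["q"] = fdr_adjust(contrasts["p"])
    return GroupModelResult(
        f_stat=float(row["F"]),
        df_num=int(row["df"]),
        df_den=int(res.df_resid),
        p_value=float(row["PR(>F)"]),
        contrasts=contrasts,
        coefficients=res.params,
    )


def morphometric_validation_model(feature, group, covariates=None) -> GroupModelResult:
    """Group model applied to a single network x measure morphometric feature.

    Identical machinery to :func:`bag_group_model`; used to check whether
    attribution-identified burden effects correspond to measurable
    univariate differences in the raw morphometry.
    """
    return bag_group_model(feature, group, covariates, outcome_name="feature")


@dataclass
class LogisticResult:
    """Logistic model summary with LR test and adjusted probabilities."""

    coefficients: pd.Series
    odds_ratios: pd.DataFrame  # term, or, lo, hi, p
    lr_chi2: float
    lr_df: int
    lr_p: float
    adjusted_probabilities: pd.DataFrame = field(default_factory=pd.DataFrame)
    penalized: bool = False


def _fit_logit(formula: str, data: pd.DataFrame):
    model = smf.logit(formula, data=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # singular Hessian step (small cells / quasi-separation):
            # gradient-only optimization is slower but far more robust
            return model.fit(method="bfgs", disp=0, maxiter=500)


def _logistic(
    data: pd.DataFrame,
    formula_full: str,
    formula_reduced: str,
    lr_df: int,
    or_terms: list,
):
    full = _fit_logit(formula_full, data)
    reduced = _fit_logit(formula_reduced, data)
    lr = 2.0 * (full.llf - reduced.llf)
    lr_p = float(stats.chi2.sf(lr, lr_df))
    ci = full.conf_int()
    rows = []
    for term in or_terms:
        rows.append(
            {
                "term": term,
                "or": float(np.exp(full.params[term])),
                "lo": float(np.exp(ci.loc[term, 0])),
                "hi": float(np.exp(ci.loc[term, 1])),
                "p": float(full.pvalues[term]),
            }
        )
    return full, LogisticResult(
        coefficients=full.params,
        odds_ratios=pd.DataFrame(rows),
        lr_chi2=float(lr),
        lr_df=lr_df,
        lr_p=lr_p,
    )


def nci_burden_logistic(
    nci, group, covariates=None, n_boot: int = 500, seed: int = 0
) -> LogisticResult:
    """Logistic model of impairment on disorder burden with covariates.

    Reports the likelihood-ratio chi-square for the burden factor, odds
    ratios versus the no-disorder group, and marginal-standardization
    (G-computation) adjusted impairment probabilities per group with
    percentile bootstrap confidence intervals.
    """
    data, cov_cols = _assemble("nci", nci, covariates, group=np.asarray(group))
    if data["nci"].nunique() < 2:
        raise DesignError("outcome must have both classes")
    levels = sorted(data["group"].unique())
    covs = "".join(f" + {c}" for c in cov_cols)
    full_f = "nci ~ C(group)" + covs
    red_f = "nci ~ 1" + covs
    or_terms = [f"C(group)[T.{lvl}]" for lvl in levels[1:]]
    full, result = _logistic(data, full_f, red_f, len(levels) - 1, or_terms)

    def adjusted_probs(res, frame):
        probs = []
        for lvl in levels:
            counter = frame.copy()
            counter["group"] = lvl
            probs.append(float(res.predict(counter).mean()))
        return np.array(probs)

    point = adjusted_probs(full, data)
    rng = np.random.default_rng(seed)
    draws = np.full((n_boot, len(levels)), np.nan)
    for b in range(n_boot):
        sample = data.sample(n=len(data), replace=True, random_state=rng.integers(2**31))
        if sample["nci"].nunique() < 2 or sample["group"].nunique() < len(levels):
            continue
        try:
            draws[b] = adjusted_probs(_fit_logit(full_f, sample), sample)
        except Exception:
            continue
    ok = ~np.isnan(draws).any(axis=1)
    lo, hi = np.nanpercentile(draws[ok], [2.5, 97.5], axis=0) if ok.any() else (point, point)
    result.adjusted_probabilities = pd.DataFrame(
        {"group": levels, "probability": point, "lo": lo, "hi": hi}
    )
    return result


def nci_bag_logistic(nci, bag, covariates=None) -> LogisticResult:
    """Logistic model of impairment on the (continuous) brain-age gap."""
    bag = np.asarray(bag, float)
    if np.ptp(bag) == 0:
        raise DesignError("brain-age gap has zero variance; coefficient undefined")
    data, cov_cols = _assemble("nci", nci, covariates, bag=bag)
    if data["nci"].nunique() < 2:
        raise DesignError("outcome must have both classes")
    covs = "".join(f" + {c}" for c in cov_cols)
    _, result = _logistic(data, "nci ~ bag" + covs, "nci ~ 1" + covs, 1, ["bag"])
    return result


@dataclass
class FactorialResult:
    """Main effects and interaction of the HIV x cocaine-use factorial."""

    terms: pd.DataFrame  # term, stat, df, p
    warnings: list = field(default_factory=list)


def factorial_hiv_cu(outcome, hiv, cu, covariates=None, family: str = "linear") -> FactorialResult:
    """Factorial model ``outcome ~ hiv * cu + covariates``.

    The binary factors are centered (effect coding), so each term's test
    is adjusted for the others (Type III). Linear family reports partial-F
    Wald chi-squares; logistic family reports likelihood-ratio chi-squares
    from nested refits.
    """
    hiv = np.asarray(hiv, float)
    cu = np.asarray(cu, float)
    if np.all(hiv == cu) or np.ptp(hiv) == 0 or np.ptp(cu) == 0:
        raise DesignError("hiv and cu factors are collinear or constant")
    data, cov_cols = _assemble("y", outcome, covariates,
                               hiv_c=hiv - hiv.mean(), cu_c=cu - cu.mean())
    notes = []
    cells = pd.crosstab(hiv, cu)
    if cells.shape != (2, 2) or (cells.to_numpy() == 0).any():
        notes.append("empty factorial cell: interaction not fully estimable")
        warnings.warn(notes[-1])
    covs = "".join(f" + {c}" for c in cov_cols)
    full_f = "y ~ hiv_c + cu_c + hiv_c:cu_c" + covs
    term_map = {"hiv": "hiv_c", "cu": "cu_c", "hiv:cu": "hiv_c:cu_c"}
    rows = []
    if family == "linear":
        res = smf.ols(full_f, data=data).fit()
        for term, col in term_map.items():
            t = float(res.tvalues[col])
            rows.append({"term": term, "stat": t**2, "df": 1,
                         "p": float(stats.chi2.sf(t**2, 1))})
    elif family == "logistic":
        full = _fit_logit(full_f, data)
        for term, col in term_map.items():
            reduced_terms = [c for c in term_map.values() if c != col]
            red_f = "y ~ " + " + ".join(reduced_terms) + covs
            red = _fit_logit(red_f, data)
            chi2 = 2.0 * (full.llf - red.llf)
            rows.append({"term": term, "stat": float(chi2), "df": 1,
                         "p": float(stats.chi2.sf(chi2, 1))})
    else:
        raise ValueError("family must be 'linear' or 'logistic'")
    return FactorialResult(terms=pd.DataFrame(rows), warnings=notes)


@dataclass
class MediationResult:
    """Two-equation path model with percentile-bootstrap inference.

    ``paths`` has one row per contrast (1 vs 0, 2 vs 0) with the exposure
    to mediator path (a, years), mediator to outcome path (b, outcome
    units per year), direct, indirect (a*b) and total effects, their
    standardized versions, bootstrap CIs, SEs and p-values. The linear
    outcome equation makes total = direct + indirect an exact identity on
    every draw.
    """

    paths: pd.DataFrame
    indirect_difference: float
    indirect_difference_ci: tuple
    indirect_difference_p: float
    n_boot: int
    seed: int


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def mediation_model(
    group, bag, nci, covariates=None, n_boot: int = 2000, seed: int = 0
) -> MediationResult:
    """Bootstrap path model: burden -> brain-age gap -> impairment.

    Equation (i) regresses the gap on two burden dummies (1 vs 0, 2 vs 0)
    plus covariates; equation (ii) regresses the outcome on the gap, the
    dummies, and covariates with a linear-probability link, so the
    product-of-coefficients indirect effect and the difference-in-totals
    decomposition coincide exactly. Inference is by percentile bootstrap
    over participants.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    g = np.asarray(group)
    bag = np.asarray(bag, float)
    y = np.asarray(nci, float)
    if np.ptp(bag) == 0:
        raise DesignError("mediator has zero variance")
    d1 = (g == 1).astype(float)
    d2 = (g == 2).astype(float)
    if d1.sum() == 0 or d2.sum() == 0 or (d1 + d2 == 1).all():
        raise DesignError("all three burden groups must be present")
    C = (
        pd.DataFrame(covariates).to_numpy(float)
        if covariates is not None and len(covariates)
        else np.empty((len(bag), 0))
    )
    n = len(bag)

    def estimate(idx):
        b_, y_, d1_, d2_, C_ = bag[idx], y[idx], d1[idx], d2[idx], C[idx]
        one = np.ones(len(idx))
        X1 = np.column_stack([one, d1_, d2_, C_])
        a1, a2 = _ols(b_, X1)[1:3]
        X2 = np.column_stack([one, b_, d1_, d2_, C_])
        beta2 = _ols(y_, X2)
        b_path, c1p, c2p = beta2[1], beta2[2], beta2[3]
        ind1, ind2 = a1 * b_path, a2 * b_path
        tot1, tot2 = c1p + ind1, c2p + ind2
        sd_y = y_.std()
        sd = lambda v: v.std() if v.std() > 0 else np.nan
        return np.array([
            a1, a2, b_path, c1p, c2p, ind1, ind2, tot1, tot2,
            ind1 * sd(d1_) / sd_y, ind2 * sd(d2_) / sd_y,
            tot1 * sd(d1_) / sd_y, tot2 * sd(d2_) / sd_y,
            ind2 - ind1,
        ])

    point = estimate(np.arange(n))
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, point.size))
    for i in range(n_boot):
        draws[i] = estimate(rng.integers(0, n, n))
    lo, hi = np.nanpercentile(draws, [2.5, 97.5], axis=0)
    se = np.nanstd(draws, axis=0, ddof=1)

    def boot_p(col):
        d = draws[:, col]
        d = d[np.isfinite(d)]
        return float(max(2.0 * min((d <= 0).mean(), (d >= 0).mean()), 1.0 / n_boot))

    names = ["a", "b", "direct", "indirect", "total", "indirect_std", "total_std"]
    paths = pd.DataFrame(
        {
            "contrast": ["1-0", "2-0"],
            "a": point[[0, 1]],
            "b": point[2],
            "direct": point[[3, 4]],
            "indirect": point[[5, 6]],
            "indirect_lo": lo[[5, 6]],
            "indirect_hi": hi[[5, 6]],
            "indirect_se": se[[5, 6]],
            "indirect_p": [boot_p(5), boot_p(6)],
            "total": point[[7, 8]],
            "total_lo": lo[[7, 8]],
            "total_hi": hi[[7, 8]],
            "total_p": [boot_p(7), boot_p(8)],
            "indirect_std": point[[9, 10]],
            "total_std": point[[11, 12]],
        }
    )
    return MediationResult(
        paths=paths,
        indirect_difference=float(point[13]),
        indirect_difference_ci=(float(lo[13]), float(hi[13])),
        indirect_difference_p=boot_p(13),
        n_boot=n_boot,
        seed=seed,
    )


def _log_choose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_rxc(counts) -> float:
    """Exact conditional p-value for a 2 x C contingency table.

    Two-sided by probability ordering: the p-value sums the hypergeometric
    probabilities of every table with the observed margins whose
    probability does not exceed that of the observed table. Tables with
    total count <= 500 are fully enumerated; larger tables fall back to
    the network algorithm (scipy).
    """
    t = np.asarray(counts)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x C table")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    col = t.sum(axis=0)
    row = t.sum(axis=1)
    if (row <= 0).any() or col.sum() <= 0:
        raise ValueError("both row margins must be positive")
    n_total = int(t.sum())
    if n_total > 500:
        return float(stats.fisher_exact(t).pvalue)
    r1 = int(row[0])
    denom = _log_choose(n_total, r1)

    def log_prob(a):
        return sum(_log_choose(int(c), int(x)) for c, x in zip(col, a)) - denom

    lp_obs = log_prob(t[0])
    total = 0.0
    ncol = len(col)
    suffix_max = np.concatenate([np.cumsum(col[::-1])[::-1][1:], [0]])

    def recurse(j, rem, lp):
        nonlocal total
        if j == ncol - 1:
            if 0 <= rem <= col[j]:
                lp_full = lp + _log_choose(int(col[j]), int(rem)) - denom
                if lp_full <= lp_obs + 1e-7:
                    total += np.exp(lp_full)
            return
        lo = max(0, rem - int(suffix_max[j]))
        hi = min(int(col[j]), rem)
        for a in range(lo, hi + 1):
            recurse(j + 1, rem - a, lp + _log_choose(int(col[j]), a))

    recurse(0, r1, 0.0)
    return float(min(total, 1.0))


@dataclass
class LmeResult:
    """Random-intercept mixed-model summary with likelihood-ratio tests."""

    fixed_effects: pd.Series
    variance_components: dict  # participant intercept and residual variances
    lrt: pd.DataFrame  # term, chi2, df, p
    converged: bool = True


def _fit_lme(formula: str, data: pd.DataFrame, groups, reml: bool):
    model = smf.mixedlm(formula, data=data, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            res = model.fit(reml=reml, method="powell")
    if not np.isfinite(res.llf):
        raise ConvergenceError(f"mixed-model likelihood not finite for: {formula}")
    return res


def _lrt(full_f: str, reduced_f: str, data: pd.DataFrame, groups) -> dict:
    full = _fit_lme(full_f, data, groups, reml=False)
    red = _fit_lme(reduced_f, data, groups, reml=False)
    chi2 = max(0.0, 2.0 * (full.llf - red.llf))
    df = len(full.fe_params) - len(red.fe_params)
    return {"chi2": float(chi2), "df": int(df), "p": float(stats.chi2.sf(chi2, df))}


def signed_shap_lme(long_table: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> LmeResult:
    """Mixed-effects tests of burden x network x measure on signed values.

    Fits ``shap ~ burden * network * measure + covariates`` with a random
    intercept per participant (REML for the reported estimates). Fixed
    terms are tested by likelihood-ratio tests of ML-fitted nested models:
    the three-way interaction against the all-two-way model, each two-way
    interaction within the two-way model, and each main effect within the
    additive model.
    """
    if long_table.groupby("participant_id").size().min() < 2:
        raise ValueError("need at least two rows per participant")
    covs = "".join(
        f" + {c}" for c in covariates
        if c in long_table.columns and long_table[c].nunique() > 1
    )
    groups = long_table["participant_id"]
    g, n_, m_ = "C(group)", "C(network)", "C(measure)"
    full = f"shap ~ {g}*{n_}*{m_}" + covs
    twoway = f"shap ~ ({g}+{n_}+{m_})**2" + covs
    additive = f"shap ~ {g}+{n_}+{m_}" + covs
    res = _fit_lme(full, long_table, groups, reml=True)
    if not res.converged:
        raise ConvergenceError("REML variance optimization did not converge")
    tests = {"group:network:measure": _lrt(full, twoway, long_table, groups)}
    pairs = {
        "group:network": f"{g}:{n_}",
        "group:measure": f"{g}:{m_}",
        "network:measure": f"{n_}:{m_}",
    }
    all_pair_terms = list(pairs.values())
    for label, term in pairs.items():
        kept = [t for t in all_pair_terms if t != term]
        reduced = f"shap ~ {g}+{n_}+{m_} + " + " + ".join(kept) + covs
        tests[label] = _lrt(twoway, reduced, long_table, groups)
    mains = {"group": g, "network": n_, "measure": m_}
    for label, term in mains.items():
        kept = [t for t in mains.values() if t != term]
        reduced = "shap ~ " + " + ".join(kept) + covs
        tests[label] = _lrt(additive, reduced, long_table, groups)
    lrt = pd.DataFrame(
        [{"term": k, **v} for k, v in tests.items()]
    )
    return LmeResult(
        fixed_effects=res.fe_params,
        variance_components={
            "participant": float(res.cov_re.iloc[0, 0]),
            "residual": float(res.scale),
        },
        lrt=lrt,
        converged=bool(res.converged),
    )


def shap_followup_by_measure(
    long_table: pd.DataFrame, measure: str, covariates=DEFAULT_COVARIATES
) -> dict:
    """Follow-up within one morphometric measure: burden x network, then
    FDR-corrected pairwise burden contrasts within each network.

    Within a single network x measure cell each participant contributes
    one row, so the pairwise contrasts use the ordinary covariate-adjusted
    group model.
    """
    sub = long_table[long_table["measure"] == measure]
    if sub.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    cov_cols = [c for c in covariates if c in sub.columns and sub[c].nunique() > 1]
    covs = "".join(f" + {c}" for c in cov_cols)
    full = f"shap ~ C(group)*C(network)" + covs
    reduced = f"shap ~ C(group)+C(network)" + covs
    interaction = _lrt(full, reduced, sub, sub["participant_id"])
    rows = []
    for network, cell in sub.groupby("network"):
        gm = bag_group_model(
            cell["shap"], cell["group"],
            cell[cov_cols] if cov_cols else None, outcome_name="shap",
        )
        for _, r in gm.contrasts.iterrows():
            rows.append({"network": network, "contrast": r["contrast"],
                         "estimate": r["estimate"], "p": r["p"], "q": r["q"],
                         "cell_f": gm.f_stat, "cell_p": gm.p_value})
    return {"interaction": interaction, "pairwise": pd.DataFrame(rows)}
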