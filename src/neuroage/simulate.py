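"""Synthetic training and clinical cohorts with known ground truth.

The generator emulates the data a morphometry-based brain-age study works
with: a large healthy "normative" cohort for model training and a smaller
clinical cohort stratified by disorder burden (0, 1, or 2 of HIV infection
and chronic cocaine use). Every planted effect is recorded so downstream
stages have a recovery test:

* smooth age trajectories per feature (linear + quadratic in age),
* an individual latent brain-age deviation: features are evaluated at the
  *effective* age = chronological age + deviation, so the deviation is
  mechanically encoded in the morphometry and recoverable by a normative
  model (in the clinical cohort the deviation mean increases with disorder
  burden -- the planted brain-age-gap dose effect),
* additive/multiplicative scanner (site) effects in units of feature SD,
* disorder-burden offsets on specific network x measure features
  (thickness down in VIS/VAN/FPN, sulcal depth up in SMN),
* a binary neurocognitive-impairment (NCI) outcome generated from the
  latent deviation and the disorder count, so impairment is partially
  mediated by the brain-age gap by construction.

Scales are conventions chosen to be anatomically plausible (thickness
~2.5 mm, sulcal depth ~10 units, area ~1.1e4 mm^2, volume ~1.4e4 mm^3);
the four measure types deliberately differ by orders of magnitude so that
standardization and harmonization are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import FEATURE_COLUMNS, MEASURES, NETWORKS, feature_key

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigError",
    "simulate_training_cohort",
    "simulate_clinical_cohort",
    "simulate_domain_tscores",
    "simulate_recruitment_roster",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


_BASELINE = {"thickness": 2.5, "sulcal_depth": 10.0, "surface_area": 1.1e4, "volume": 1.4e4}
_SLOPE = {"thickness": -0.005, "sulcal_depth": 0.010, "surface_area": -15.0, "volume": -40.0}
_CURVATURE = {"thickness": -2e-5, "sulcal_depth": 5e-5, "surface_area": 0.0, "volume": -0.3}
_NOISE_SD = {"thickness": 0.06, "sulcal_depth": 0.25, "surface_area": 250.0, "volume": 350.0}
# deterministic per-network spread so the 28 trajectories are not identical
_NET_FACTOR = {"VIS": 0.90, "SMN": 1.00, "DAN": 0.95, "VAN": 1.05,
               "LIM": 1.10, "FPN": 1.15, "DMN": 1.20}
# planted disorder-burden offsets (feature units per disorder): cortical
# thinning in visual / ventral-attention / frontoparietal networks and
# sulcal deepening in the somatomotor network
_BURDEN = {
    feature_key("thickness", "VIS"): -0.012,
    feature_key("thickness", "VAN"): -0.012,
    feature_key("thickness", "FPN"): -0.012,
    feature_key("sulcal_depth", "SMN"): 0.06,
}


def _full_map(defaults_by_measure: dict, overrides: dict | None) -> dict:
    full = {
        feature_key(m, n): defaults_by_measure[m] * _NET_FACTOR[n]
        for m in MEASURES
        for n in NETWORKS
    }
    if overrides:
        for key, value in overrides.items():
            if key not in full:
                raise ConfigError(f"unknown feature key {key!r}")
            full[key] = value
    return full


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with study-scale defaults.

    Defaults mirror the study design this generator emulates: 725 healthy
    training participants aged 36-100 years scanned at multiple sites, and
    a clinical cohort of 34/72/80 participants with 0/1/2 disorders aged
    35-76.6 years on a single scanner. The latent brain-age deviation has
    SD 6.5 years in the training cohort (so a normative model attains a
    cross-validated MAE in the 5-6 year range) and group means of
    0/3.5/6.3 years in the clinical cohort (the planted dose effect), with
    2 years of residual spread.
    """

    n_training: int = 725
    n_per_group: tuple[int, int, int] = (34, 72, 80)
    age_range: tuple[float, float] = (36.0, 100.0)
    age_range_clinical: tuple[float, float] = (35.0, 76.6)
    n_sites: int = 2
    site_shift: tuple[float, ...] = (0.3, -0.3)
    site_scale: tuple[float, ...] = (1.0, 1.3)
    clinical_site_shift: float = 0.5
    clinical_site_scale: float = 1.2
    training_bag_sd: float = 6.5
    clinical_bag_sd: float = 2.0
    mediation_a: tuple[float, float, float] = (0.0, 3.5, 6.3)
    mediation_b: float = 0.08
    direct_c: float = 0.6
    nci_intercept: float = -1.8
    nci_zung: float = 0.02
    nci_link: str = "logistic"
    slope_map: dict | None = None
    curvature_map: dict | None = None
    burden_effect_map: dict | None = field(default_factory=lambda: dict(_BURDEN))
    noise_sd_map: dict | None = None
    baseline_map: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.age_range
        if not lo < hi or lo <= 0:
            raise ConfigError("age_range must satisfy 0 < lo < hi")
        lo, hi = self.age_range_clinical
        if not lo < hi or lo <= 0:
            raise ConfigError("age_range_clinical must satisfy 0 < lo < hi")
        if self.n_sites < 1 or len(self.site_shift) < self.n_sites or len(self.site_scale) < self.n_sites:
            raise ConfigError("need site_shift/site_scale for every site")
        if any(s <= 0 for s in self.site_scale[: self.n_sites]) or self.clinical_site_scale <= 0:
            raise ConfigError("site variance factors must be > 0")
        if any(v < 0 for v in self.noise_sds().values()):
            raise ConfigError("noise SDs must be >= 0")
        if self.training_bag_sd < 0 or self.clinical_bag_sd < 0:
            raise ConfigError("latent deviation SDs must be >= 0")
        if self.nci_link not in ("logistic", "linear"):
            raise ConfigError("nci_link must be 'logistic' or 'linear'")

    # resolved per-feature maps (defaults merged with overrides)
    def baselines(self) -> dict:
        return _full_map(_BASELINE, self.baseline_map)

    def slopes(self) -> dict:
        return _full_map(_SLOPE, self.slope_map)

    def curvatures(self) -> dict:
        return _full_map(_CURVATURE, self.curvature_map)

    def noise_sds(self) -> dict:
        return _full_map(_NOISE_SD, self.noise_sd_map)

    def burden_effects(self) -> dict:
        full = dict.fromkeys(FEATURE_COLUMNS, 0.0)
        if self.burden_effect_map:
            for key, value in self.burden_effect_map.items():
                if key not in full:
                    raise ConfigError(f"unknown feature key {key!r}")
                full[key] = value
        return full

    @property
    def age_center(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted quantities aligned 1:1 with a generated feature table."""

    rows: pd.DataFrame  # participant_id, true_bag, effective_age, nci_p
    site_offsets: dict  # site -> {feature -> additive offset, feature units}
    burden_offsets: dict  # feature -> offset per disorder (feature units)


def _draw_covariates(rng: np.random.Generator, n: int) -> dict:
    return {
        "sex": rng.integers(0, 2, n),
        "education": (rng.random(n) < 0.2).astype(int),
        "zung": np.clip(rng.normal(41.0, 8.0, n), 20.0, 80.0),
        "euler": np.rint(rng.normal(-40.0, 15.0, n)).astype(int),
        "motion": np.clip(np.abs(rng.normal(0.15, 0.07, n)), 0.01, 0.39),
    }


def _feature_matrix(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    effective_age: np.ndarray,
    shift_sd_units: np.ndarray,
    scale_factor: np.ndarray,
    burden: np.ndarray,
) -> pd.DataFrame:
    base, slope = cfg.baselines(), cfg.slopes()
    curv, noise = cfg.curvatures(), cfg.noise_sds()
    beff = cfg.burden_effects()
    da = effective_age - cfg.age_center
    cols = {}
    for key in FEATURE_COLUMNS:
        cols[key] = (
            base[key]
            + slope[key] * da
            + curv[key] * da**2
            + beff[key] * burden
            + shift_sd_units * noise[key]
            + rng.normal(0.0, 1.0, len(da)) * noise[key] * np.sqrt(scale_factor)
        )
    return pd.DataFrame(cols)


def simulate_training_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the healthy normative (training) cohort.

    Ages are uniform on ``config.age_range``; each participant carries a
    latent brain-age deviation ~ N(0, training_bag_sd) along which their
    feature trajectories are evaluated; sites are assigned uniformly with
    the configured additive/multiplicative scanner effects. Deterministic
    under a fixed config (the seed is part of the config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_training
    age = rng.uniform(*config.age_range, n)
    dev = rng.normal(0.0, config.training_bag_sd, n)
    site_idx = rng.integers(0, config.n_sites, n)
    shift = np.asarray(config.site_shift)[site_idx]
    scale = np.asarray(config.site_scale)[site_idx]
    cov = _draw_covariates(rng, n)
    feats = _feature_matrix(config, rng, age + dev, shift, scale, np.zeros(n))
    table = pd.DataFrame(
        {
            "participant_id": [f"T{i:04d}" for i in range(n)],
            "age": age,
            **cov,
            "site": [f"site{s}" for s in site_idx],
            "cohort": "training",
            "group": 0,
            "hiv": 0,
            "cu": 0,
            "nci": 0,
        }
    ).join(feats)
    noise = config.noise_sds()
    site_offsets = {
        f"site{s}": {k: config.site_shift[s] * noise[k] for k in FEATURE_COLUMNS}
        for s in range(config.n_sites)
    }
    truth = GroundTruth(
        rows=pd.DataFrame(
            {
                "participant_id": table["participant_id"],
                "true_bag": dev,
                "effective_age": age + dev,
                "nci_p": np.nan,
            }
        ),
        site_offsets=site_offsets,
        burden_offsets=config.burden_effects(),
    )
    return table, truth


def simulate_clinical_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the clinical cohort with planted dose and mediation effects.

    Groups are sized by ``n_per_group``; the one-disorder group is split
    evenly between HIV+/CU- and HIV-/CU+. The latent brain-age deviation is
    ``mediation_a[group] + N(0, clinical_bag_sd)`` and shifts the feature
    trajectories (plus the network-specific burden offsets). NCI is drawn
    from ``intercept + mediation_b * deviation + direct_c * group + zung
    term`` through the configured link, so the outcome is partially
    mediated by the planted brain-age gap.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n0, n1, n2 = config.n_per_group
    n = n0 + n1 + n2
    group = np.repeat([0, 1, 2], [n0, n1, n2])
    hiv = np.zeros(n, dtype=int)
    cu = np.zeros(n, dtype=int)
    hiv[group == 2] = 1
    cu[group == 2] = 1
    ones = np.flatnonzero(group == 1)
    hiv[ones[: (n1 + 1) // 2]] = 1
    cu[ones[(n1 + 1) // 2 :]] = 1
    age = rng.uniform(*config.age_range_clinical, n)
    a = np.asarray(config.mediation_a)[group]
    true_bag = a + rng.normal(0.0, config.clinical_bag_sd, n)
    cov = _draw_covariates(rng, n)
    shift = np.full(n, config.clinical_site_shift)
    scale = np.full(n, config.clinical_site_scale)
    feats = _feature_matrix(config, rng, age + true_bag, shift, scale, group.astype(float))
    linpred = (
        config.nci_intercept
        + config.mediation_b * true_bag
        + config.direct_c * group
        + config.nci_zung * (cov["zung"] - 41.0)
    )
    if config.nci_link == "logistic":
        p = expit(linpred)
    else:
        p = np.clip(linpred, 0.0, 1.0)
    nci = (rng.random(n) < p).astype(int)
    table = pd.DataFrame(
        {
            "participant_id": [f"C{i:04d}" for i in range(n)],
            "age": age,
            **cov,
            "site": "clinical",
            "cohort": "clinical",
            "group": group,
            "hiv": hiv,
            "cu": cu,
            "nci": nci,
        }
    ).join(feats)
    noise = config.noise_sds()
    truth = GroundTruth(
        rows=pd.DataFrame(
            {
                "participant_id": table["participant_id"],
                "true_bag": true_bag,
                "effective_age": age + true_bag,
                "nci_p": p,
            }
        ),
        site_offsets={"clinical": {k: config.clinical_site_shift * noise[k] for k in FEATURE_COLUMNS}},
        burden_offsets=config.burden_effects(),
    )
    return table, truth


def simulate_domain_tscores(
    n: int,
    n_domains: int = 7,
    impaired_fraction: float = 0.25,
    seed: int = 0,
    mean: float = 50.0,
    sd: float = 10.0,
    impaired_mean: float = 38.0,
    impaired_sd: float = 3.0,
    threshold_sd: float = 1.0,
    min_domains: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cognitive-domain T-scores with a designated impaired subset.

    Unimpaired scores are N(mean, sd) per domain. Each designated impaired
    participant has a random number (>= ``min_domains``) of domains drawn
    from N(impaired_mean, impaired_sd); the draw is repeated until at least
    ``min_domains`` of them fall at or below mean - threshold_sd * sd, so
    the planted truth flag genuinely satisfies the impairment rule.
    Returns the T-score table and the truth flags.
    """
    if n_domains < 2:
        raise ConfigError("need at least two cognitive domains")
    if not 0.0 <= impaired_fraction <= 1.0:
        raise ConfigError("impaired_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    scores = rng.normal(mean, sd, (n, n_domains))
    n_imp = int(round(impaired_fraction * n))
    impaired_rows = rng.choice(n, size=n_imp, replace=False)
    cutoff = mean - threshold_sd * sd
    for i in impaired_rows:
        m = int(rng.integers(min_domains, n_domains + 1))
        which = rng.choice(n_domains, size=m, replace=False)
        draw = rng.normal(impaired_mean, impaired_sd, m)
        while (draw <= cutoff).sum() < min_domains:
            draw = rng.normal(impaired_mean, impaired_sd, m)
        scores[i, which] = draw
    table = pd.DataFrame(scores, columns=[f"domain_{j + 1}" for j in range(n_domains)])
    table.insert(0, "participant_id", [f"C{i:04d}" for i in range(n)])
    truth = pd.Series(np.isin(np.arange(n), impaired_rows), name="impaired")
    return table, truth


def simulate_recruitment_roster(
    n: int = 196,
    n_recon_failure: int = 4,
    n_high_motion: int = 6,
    motion_max: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Recruitment roster for the quality-control exclusion flow.

    Emulates a cohort in which a few participants fail cortical-surface
    reconstruction and a few others exceed the head-motion cut-off; the
    two exclusion sets are disjoint, so applying the filter retains
    ``n - n_recon_failure - n_high_motion`` participants.
    """
    if n_recon_failure + n_high_motion > n:
        raise ConfigError("more exclusions than participants")
    rng = np.random.default_rng(seed)
    motion = np.clip(np.abs(rng.normal(0.15, 0.07, n)), 0.01, motion_max - 0.01)
    recon_ok = np.ones(n, dtype=bool)
    bad = rng.choice(n, size=n_recon_failure + n_high_motion, replace=False)
    recon_ok[bad[:n_recon_failure]] = False
    motion[bad[n_recon_failure:]] = rng.uniform(motion_max + 0.02, motion_max + 0.3, n_high_motion)
    return pd.DataFrame(
        {
            "participant_id": [f"R{i:04d}" for i in range(n)],
            "recon_ok": recon_ok,
            "motion": motion,
        }
    )
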