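"""Synthetic full-cohort tables with planted age-density associations.

The generator emulates a prospective-cohort incident-CRC series: all
incident cases get age, sex, tumor and molecular covariates drawn from
realistic marginals; a logistic availability model (age group, sex,
stage, diagnosis year) decides which cases contribute tissue data; and,
for available cases, binary high/low vessel-density states are drawn
from per-age-group probabilities chosen so the group odds ratios versus
the oldest group equal the planted association parameters.  Continuous
density values consistent with the binary states are attached for the
dichotomization machinery.  Availability is independent of the density
outcomes given the modeled covariates, so inverse-probability weighting
recovers the planted odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

#: Age groups; the last one is the regression referent.
AGE_GROUPS = ("<55", "55-69", ">=70")
AGE_BANDS = {"<55": (45.0, 55.0), "55-69": (55.0, 70.0), ">=70": (70.0, 85.0)}

#: Outcome columns planted by the generator.
OUTCOME_COLS = ("overall_high", "micro_high", "lamb1_high")


def age_group_of(age: float) -> str:
    if age < 55:
        return "<55"
    if age < 70:
        return "55-69"
    return ">=70"


@dataclass
class CohortSimConfig:
    n_total: int = 4476
    #: expected available-case counts by age group (<55, 55-69, >=70)
    n_by_age: tuple[int, int, int] = (52, 400, 391)
    #: full-cohort age-group proportions
    age_group_props: tuple[float, float, float] = (0.10, 0.47, 0.43)
    #: P(high density) by age group, per outcome; chosen so the group
    #: odds ratios vs >=70 equal the planted associations
    p_high_by_age: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "overall_high": (0.386, 0.459, 0.500),
            "micro_high": (0.537, 0.457, 0.500),
            "lamb1_high": (0.219, 0.359, 0.500),
        }
    )
    #: coefficients of the availability model beyond the age terms
    #: (age-group intercepts are calibrated to hit n_by_age exactly)
    availability_model: dict[str, float] = field(
        default_factory=lambda: {
            "sex_female": 0.15,
            "stage_iv": -0.30,
            "year_per_decade": 0.20,
        }
    )
    covariate_marginals: dict[str, object] = field(
        default_factory=lambda: {
            "sex_female": 0.56,
            "bmi_median": 26.0,
            "bmi_log_sd": 0.135,
            "pack_years": (0.40, 0.40, 0.20),  # 0 / 1-39 / >=40
            "family_history_present": 0.21,
            "tumor_location": (0.50, 0.30, 0.20),  # proximal/distal/rectum
            "stage": (0.23, 0.33, 0.29, 0.15),
            "msi_high": 0.18,
            "cimp_high": 0.19,
            "line1": (0.22, 0.39, 0.39),  # <=55 / 55-65 / >65 %
            "kras_mutated": 0.40,
            "braf_mutated": 0.16,
            "pik3ca_mutated": 0.17,
            "year_range": (1985, 2008),
        }
    )
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "family_history": 0.005,
            "tumor_location": 0.004,
            "msi": 0.031,
            "cimp": 0.076,
            "kras": 0.030,
            "braf": 0.023,
            "pik3ca": 0.088,
            "line1_cat": 0.029,
        }
    )
    #: continuous-density scales: (median, log-scale spread) per outcome
    density_medians: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "overall": (197.0, 0.42),
            "micro": (93.0, 0.55),
            "lamb1": (8.0, 0.70),
        }
    )
    lamb1_zero_fraction: float = 0.55  # of low/negative cases
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if abs(sum(self.age_group_props) - 1.0) > 1e-9:
            raise ValueError("age_group_props must sum to 1")
        for name, probs in self.p_high_by_age.items():
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"p_high_by_age[{name}] outside [0,1]")
        for r in self.missing_rates.values():
            if not 0.0 <= r <= 1.0:
                raise ValueError("missing rates must be in [0,1]")

    @property
    def expected_available(self) -> float:
        return float(sum(self.n_by_age))


def _calibrate_group_intercepts(
    lp_extra: np.ndarray, group_idx: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Per-age-group intercepts c_g with mean(expit(c_g + lp)) = target.

    Newton iterations on each group; makes the expected available count
    match sum(n_by_age) exactly in expectation over the realized
    covariates.
    """
    out = np.zeros(3)
    for g in range(3):
        lp = lp_extra[group_idx == g]
        target = targets[g]
        c = logit(np.clip(target, 1e-6, 1 - 1e-6))
        for _ in range(50):
            p = expit(c + lp)
            f = p.mean() - target
            df = (p * (1 - p)).mean()
            if df <= 0 or abs(f) < 1e-12:
                break
            c -= f / df
        out[g] = c
    return out


def generate_cohort(
    config: CohortSimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the full-cohort table (one row per incident case).

    Unavailable cases carry NaN in the outcome and density columns;
    covariate missingness is injected per ``missing_rates``.
    """
    config = config or CohortSimConfig()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_total
    m = config.covariate_marginals

    group_idx = rng.choice(3, size=n, p=np.asarray(config.age_group_props))
    age = np.empty(n)
    for g, name in enumerate(AGE_GROUPS):
        lo, hi = AGE_BANDS[name]
        sel = group_idx == g
        age[sel] = rng.uniform(lo, hi, size=sel.sum())

    sex = np.where(rng.random(n) < m["sex_female"], "female", "male")
    bmi = m["bmi_median"] * np.exp(rng.normal(0.0, m["bmi_log_sd"], n))
    pack = rng.choice(["0", "1-39", ">=40"], size=n, p=np.asarray(m["pack_years"]))
    famhx = np.where(
        rng.random(n) < m["family_history_present"], "present", "absent"
    )
    location = rng.choice(
        ["proximal", "distal", "rectum"], size=n, p=np.asarray(m["tumor_location"])
    )
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=np.asarray(m["stage"]))
    msi = np.where(rng.random(n) < m["msi_high"], "MSI-high", "non-MSI-high")
    cimp = np.where(rng.random(n) < m["cimp_high"], "high", "negative/low")
    line1 = rng.choice(["<=55", "55-65", ">65"], size=n, p=np.asarray(m["line1"]))
    kras = np.where(rng.random(n) < m["kras_mutated"], "mutated", "wild-type")
    braf = np.where(rng.random(n) < m["braf_mutated"], "mutated", "wild-type")
    pik3ca = np.where(rng.random(n) < m["pik3ca_mutated"], "mutated", "wild-type")
    y0, y1 = m["year_range"]
    year = rng.integers(y0, y1 + 1, size=n)

    # availability: logistic in age group (calibrated), sex, stage, year
    coeffs = config.availability_model
    lp_extra = (
        coeffs["sex_female"] * ((sex == "female") - np.mean(sex == "female"))
        + coeffs["stage_iv"] * ((stage == "IV") - np.mean(stage == "IV"))
        + coeffs["year_per_decade"] * (year - year.mean()) / 10.0
    )
    # calibrate against the realized group sizes so the expected
    # available count equals sum(n_by_age) exactly
    # targets at or above 1 mean "everyone in this group available"
    realized = np.bincount(group_idx, minlength=3)
    targets = np.clip(
        np.asarray(config.n_by_age) / np.maximum(realized, 1), 0.0, 1.0 - 1e-9
    )
    intercepts = _calibrate_group_intercepts(lp_extra, group_idx, targets)
    p_avail = expit(intercepts[group_idx] + lp_extra)
    available = rng.random(n) < p_avail

    df = pd.DataFrame(
        {
            "case_id": [f"case-{i:05d}" for i in range(n)],
            "age": age,
            "age_group": pd.Categorical(
                np.asarray(AGE_GROUPS)[group_idx], categories=AGE_GROUPS
            ),
            "sex": sex,
            "bmi": bmi,
            "bmi_cat": np.where(bmi >= 30, ">=30", "<30"),
            "pack_years_cat": pack,
            "family_history": famhx,
            "tumor_location": location,
            "stage": stage,
            "msi": msi,
            "cimp": cimp,
            "line1_cat": line1,
            "kras": kras,
            "braf": braf,
            "pik3ca": pik3ca,
            "diagnosis_year": year,
            "availability_prob": p_avail,
            "tissue_available": available,
        }
    )

    # planted outcomes + consistent continuous densities (available only)
    for outcome, var in zip(OUTCOME_COLS, ("overall", "micro", "lamb1")):
        probs = np.asarray(config.p_high_by_age[outcome])
        high = np.full(n, np.nan)
        high[available] = (
            rng.random(available.sum()) < probs[group_idx[available]]
        ).astype(float)
        df[outcome] = high
        med, spread = config.density_medians[var]
        dens = np.full(n, np.nan)
        z = np.abs(rng.normal(0.0, spread, n)) + 1e-3
        if var == "lamb1":
            low_val = np.where(
                rng.random(n) < config.lamb1_zero_fraction,
                0.0,
                med * np.exp(-z),
            )
        else:
            low_val = med * np.exp(-z)
        dens[available] = np.where(
            high[available] == 1.0, med * np.exp(z[available]), low_val[available]
        )
        df[f"density_{var}"] = dens

    # covariate missingness
    for col, rate in config.missing_rates.items():
        if rate > 0:
            df.loc[rng.random(n) < rate, col] = np.nan
    return df
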