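"""Age-association statistics with inverse-probability weighting.

Reproduces the analysis stage: per-case pooling of vessel densities,
median dichotomization (with the special zero-inflated rule for
CD34+LAMB1+ density), Spearman age-trend tests, an availability model
whose inverse probabilities reweight the tissue subcohort back to all
incident cases, weighted multivariable logistic regression with a
robust (sandwich) variance, backward elimination with age forced in,
majority-category missing handling with missing-indicator terms, and
Bonferroni-style multiplicity control over the nine vessel variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
import statsmodels.api as sm

from vesselphen.phenotyping import CoreRecord, DENSITY_VARS, vessel_counts
from vesselphen.simulate.cohort import AGE_GROUPS

# ---------------------------------------------------------------------------
# configuration


@dataclass
class StatsConfig:
    alpha: float = 0.005  # ~ 0.05 / 9 vessel variables
    backward_threshold: float = 0.1
    weight_truncate_quantile: float = 0.99
    forced_terms: tuple[str, ...] = ("age",)
    availability_predictors: tuple[str, ...] = (
        "age_group",
        "sex",
        "stage",
        "diagnosis_year",
    )

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 < self.backward_threshold < 1:
            raise ValueError("backward-elimination threshold must be in (0,1)")


# ---------------------------------------------------------------------------
# per-case aggregation and dichotomization


def aggregate_case_metrics(
    cores_by_case: dict[str, list[CoreRecord]]
) -> tuple[pd.DataFrame, list[str]]:
    """Pool per-core vessel counts into per-case densities.

    Pooled density = sum of category counts across QC-passing cores
    divided by the summed core areas (robust to unequal core tissue
    areas).  Cases whose cores all failed QC are dropped and reported.
    """
    rows = []
    dropped: list[str] = []
    for case_id, cores in cores_by_case.items():
        good = [c for c in cores if c.qc_passed and c.core_area_mm2 > 0]
        if not good:
            dropped.append(case_id)
            continue
        total_area = sum(c.core_area_mm2 for c in good)
        counts: dict[str, float] = {}
        for c in good:
            for k, v in vessel_counts(c.vessels).items():
                counts[k] = counts.get(k, 0) + v
        row = {"case_id": case_id, "n_cores": len(good)}
        for k in list(DENSITY_VARS) + ["irregular"]:
            row[f"density_{k}"] = counts.get(k, 0) / total_area
        rows.append(row)
    return pd.DataFrame(rows), dropped


def dichotomize(
    values: pd.Series, scheme: str = "median"
) -> tuple[pd.Series, float]:
    """Binary high/low split of a density variable.

    ``median``: high = strictly above the median of all values.
    ``nonzero-median``: high = strictly above the median of the non-zero
    values; zeros are always low/negative (the CD34+LAMB1+ rule).
    Returns the 0/1 series and the cutpoint used.
    """
    v = pd.Series(values).astype(float)
    if v.notna().sum() < 2:
        raise ValueError("need at least two cases to dichotomize")
    if scheme == "median":
        cut = float(v.median())
    elif scheme == "nonzero-median":
        nz = v[v > 0]
        cut = float(nz.median()) if len(nz) else float("inf")
    else:
        raise ValueError(f"unknown dichotomization scheme {scheme!r}")
    if v.nunique(dropna=True) == 1:
        warnings.warn("all values equal; every case classified low", stacklevel=2)
    high = (v > cut).astype(float)
    high[v.isna()] = np.nan
    return high, cut


# ---------------------------------------------------------------------------
# Spearman trend


def spearman_trend(age, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks and the t-approximation
    two-sided p-value."""
    age = np.asarray(age, float)
    y = np.asarray(y, float)
    ok = np.isfinite(age) & np.isfinite(y)
    age, y = age[ok], y[ok]
    if age.size < 5:
        raise ValueError("need n >= 5 for the trend test")
    if np.all(age == age[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(age, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# missing handling


#: categorical covariates handled by majority imputation + indicator
MAJORITY_IMPUTE_VARS = (
    "family_history",
    "tumor_location",
    "msi",
    "cimp",
    "kras",
    "braf",
    "pik3ca",
)
#: LINE-1 gets its own separate indicator level, never majority-imputed
LINE1_VAR = "line1_cat"


def handle_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Model-ready table: majority-category imputation with per-variable
    missing indicators; LINE-1 missing becomes a separate level."""
    out = table.copy()
    for var in MAJORITY_IMPUTE_VARS:
        if var not in out.columns:
            continue
        miss = out[var].isna()
        if miss.any():
            majority = out[var].mode(dropna=True).iloc[0]
            out[var] = out[var].fillna(majority)
            out[f"{var}_missing"] = miss.astype(int)
    if LINE1_VAR in out.columns and out[LINE1_VAR].isna().any():
        out[LINE1_VAR] = out[LINE1_VAR].astype(object).where(
            out[LINE1_VAR].notna(), "missing"
        )
    return out


# ---------------------------------------------------------------------------
# design blocks


def _dummies(series: pd.Series, levels: list[str], prefix: str) -> pd.DataFrame:
    cols = {}
    for lev in levels:
        cols[f"{prefix}[{lev}]"] = (series == lev).astype(float)
    return pd.DataFrame(cols, index=series.index)


def make_model_terms(
    df: pd.DataFrame, include_msi: bool = True
) -> dict[str, pd.DataFrame]:
    """Named covariate blocks (dummy columns; referents dropped).

    Each multi-level covariate enters and leaves the model as a whole
    block, together with its missing-indicator column if present.
    """
    terms: dict[str, pd.DataFrame] = {}
    terms["age"] = _dummies(df["age_group"], ["<55", "55-69"], "age")
    terms["sex"] = _dummies(df["sex"], ["female"], "sex")
    terms["bmi"] = _dummies(df["bmi_cat"], [">=30"], "bmi")
    terms["pack_years"] = _dummies(df["pack_years_cat"], ["1-39", ">=40"], "pack_years")
    terms["family_history"] = _dummies(df["family_history"], ["present"], "family_history")
    terms["tumor_location"] = _dummies(df["tumor_location"], ["distal", "rectum"], "tumor_location")
    if include_msi:
        terms["msi"] = _dummies(df["msi"], ["MSI-high"], "msi")
    terms["cimp"] = _dummies(df["cimp"], ["high"], "cimp")
    line1_levels = ["55-65", ">65"]
    if (df[LINE1_VAR] == "missing").any():
        line1_levels.append("missing")
    terms["line1"] = _dummies(df[LINE1_VAR], line1_levels, "line1")
    terms["kras"] = _dummies(df["kras"], ["mutated"], "kras")
    terms["braf"] = _dummies(df["braf"], ["mutated"], "braf")
    terms["pik3ca"] = _dummies(df["pik3ca"], ["mutated"], "pik3ca")
    for var in MAJORITY_IMPUTE_VARS:
        col = f"{var}_missing"
        if col in df.columns and var in terms and df[col].loc[terms[var].index].sum() > 0:
            terms[var] = terms[var].assign(**{col: df[col].astype(float)})
    return terms


# ---------------------------------------------------------------------------
# weighted logistic regression


@dataclass
class RegressionResult:
    params: pd.Series
    cov: pd.DataFrame  # robust (sandwich) covariance
    n: int
    converged: bool
    term_columns: dict[str, list[str]] = field(default_factory=dict)
    p_trend: float | None = None

    @property
    def or_table(self) -> pd.DataFrame:
        se = pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)
        z = self.params / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "odds_ratio": np.exp(self.params),
                "ci_low": np.exp(self.params - 1.959963984540054 * se),
                "ci_high": np.exp(self.params + 1.959963984540054 * se),
                "p": p,
            }
        )

    def wald_p(self, columns: list[str]) -> float:
        """Joint Wald test that the given coefficients are all zero."""
        b = self.params[columns].to_numpy()
        V = self.cov.loc[columns, columns].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        return float(stats.chi2.sf(stat, len(columns)))


def fit_weighted_logistic(
    outcome: pd.Series,
    design: pd.DataFrame,
    weights: pd.Series | np.ndarray | None = None,
) -> RegressionResult:
    """Weighted maximum-likelihood logistic fit with sandwich variance.

    Point estimates come from the weighted Bernoulli likelihood; the
    variance is the HC0 sandwich (weights are estimated inverse
    probabilities, so the model-based variance would be misleading).
    Doubling all weights leaves the estimates unchanged.
    """
    y = pd.Series(outcome).astype(float)
    X = design.copy()
    if "const" not in X.columns:
        X.insert(0, "const", 1.0)
    w = (
        np.ones(len(y))
        if weights is None
        else np.asarray(pd.Series(weights).reindex(y.index), float)
    )
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if y.isna().any() or X.isna().any().any():
        raise ValueError("outcome/design contain missing values")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    Xm = X.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y.to_numpy(), Xm, family=sm.families.Binomial(), freq_weights=w)
        try:
            fit = model.fit(maxiter=200)
        except Exception as exc:  # perfect separation, singular design...
            raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not fit.converged:
        raise RuntimeError("logistic fit did not converge (separation?)")
    beta = fit.params
    p_hat = expit(Xm @ beta)
    # complete separation: every fitted probability pinned to its label.
    # (quasi-separation on a sparse dummy is tolerated -- its Wald p is
    # ~1 and backward elimination removes it.)
    y_arr = y.to_numpy()
    extreme = (p_hat > 1 - 1e-6) | (p_hat < 1e-6)
    if extreme.all() and np.abs(y_arr - p_hat).max() < 1e-6:
        raise RuntimeError(
            "complete separation: the outcome is perfectly predicted by "
            "the design; coefficients diverge"
        )
    # HC0 sandwich: A^-1 M A^-1 with A the weighted information
    W_info = w * p_hat * (1 - p_hat)
    A = Xm.T @ (Xm * W_info[:, None])
    score = Xm * (w * (y.to_numpy() - p_hat))[:, None]
    M = score.T @ score
    A_inv = np.linalg.pinv(A)
    cov = A_inv @ M @ A_inv
    params = pd.Series(beta, index=X.columns)
    cov_df = pd.DataFrame(cov, index=X.columns, columns=X.columns)
    return RegressionResult(params=params, cov=cov_df, n=len(y), converged=True)


# ---------------------------------------------------------------------------
# IPW weights


@dataclass
class IPWResult:
    weights: pd.Series  # indexed by available-case rows
    probabilities: pd.Series  # all cases
    balance: pd.DataFrame  # standardized mean differences pre/post
    truncated_at: float


def estimate_ipw_weights(
    cohort: pd.DataFrame, config: StatsConfig | None = None
) -> IPWResult:
    """Inverse-probability-of-availability weights from the full cohort.

    Fits a logistic model of tissue availability on the configured
    predictors over all incident cases; available cases get weight
    1/p-hat, truncated at the configured upper quantile.  A balance
    table of standardized mean differences (full cohort vs weighted
    available cases) is returned as a diagnostic.
    """
    config = config or StatsConfig()
    if cohort["tissue_available"].all():
        w = pd.Series(1.0, index=cohort.index)
        probs = pd.Series(1.0, index=cohort.index)
        design = _availability_design(cohort, config)
        balance = _balance_table(design, cohort["tissue_available"].to_numpy(bool), w)
        return IPWResult(w, probs, balance, truncated_at=1.0)
    design = _availability_design(cohort, config)
    avail = cohort["tissue_available"].astype(float)
    fit = fit_weighted_logistic(avail, design)
    X = design.copy()
    X.insert(0, "const", 1.0)
    probs = pd.Series(expit(X.to_numpy() @ fit.params.to_numpy()), index=cohort.index)
    raw = 1.0 / probs[cohort["tissue_available"].astype(bool)]
    bound = float(np.quantile(raw, config.weight_truncate_quantile))
    weights = raw.clip(upper=bound)
    balance = _balance_table(
        design, cohort["tissue_available"].to_numpy(bool), weights
    )
    return IPWResult(weights, probs, balance, truncated_at=bound)


def _availability_design(cohort: pd.DataFrame, config: StatsConfig) -> pd.DataFrame:
    parts = []
    for pred in config.availability_predictors:
        if pred == "age_group":
            parts.append(_dummies(cohort["age_group"], ["<55", "55-69"], "age"))
        elif pred == "sex":
            parts.append(_dummies(cohort["sex"], ["female"], "sex"))
        elif pred == "stage":
            s = cohort["stage"]
            if s.isna().any():
                s = s.fillna(s.mode(dropna=True).iloc[0])
            parts.append(_dummies(s, ["II", "III", "IV"], "stage"))
        elif pred == "diagnosis_year":
            y = cohort["diagnosis_year"].astype(float)
            parts.append(
                pd.DataFrame({"year_per_decade": (y - y.mean()) / 10.0}, index=cohort.index)
            )
        else:
            parts.append(cohort[[pred]].astype(float))
    return pd.concat(parts, axis=1)


def _balance_table(
    design: pd.DataFrame, available: np.ndarray, weights: pd.Series
) -> pd.DataFrame:
    rows = []
    w = weights.reindex(design.index[available]).to_numpy(float)
    for col in design.columns:
        x = design[col].to_numpy(float)
        full_mean = x.mean()
        sd = x.std()
        if sd == 0:
            continue
        avail_x = x[available]
        raw_smd = (avail_x.mean() - full_mean) / sd
        wt_smd = (np.average(avail_x, weights=w) - full_mean) / sd
        rows.append(
            {"predictor": col, "smd_unweighted": raw_smd, "smd_weighted": wt_smd}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# backward elimination


def backward_eliminate(
    outcome: pd.Series,
    terms: dict[str, pd.DataFrame],
    weights=None,
    threshold: float = 0.1,
    forced: tuple[str, ...] = ("age",),
) -> tuple[RegressionResult, list[str], list[tuple[str, float]]]:
    """Iteratively drop the weakest removable covariate block.

    At each step the non-forced block with the largest joint Wald
    p-value >= ``threshold`` is removed and the model refit; forced
    blocks (age) always stay.  Returns the final fit, the retained
    block names, and the elimination path as (block, p) pairs.
    """
    current = dict(terms)
    path: list[tuple[str, float]] = []
    while True:
        design = pd.concat(current.values(), axis=1)
        fit = fit_weighted_logistic(outcome, design, weights)
        fit.term_columns = {k: list(v.columns) for k, v in current.items()}
        candidates = {
            name: fit.wald_p(list(block.columns))
            for name, block in current.items()
            if name not in forced
        }
        if not candidates:
            return fit, list(current), path
        worst, worst_p = max(candidates.items(), key=lambda kv: kv[1])
        if worst_p < threshold:
            return fit, list(current), path
        path.append((worst, worst_p))
        del current[worst]


# ---------------------------------------------------------------------------
# multiplicity


def multiplicity_flag(p_values, alpha: float = 0.005) -> np.ndarray:
    """Significance flags at the vessel-variable-adjusted alpha (0.005,
    approximately 0.05 Bonferroni-corrected for the 9 variables)."""
    p = np.asarray(p_values, float)
    return p < alpha


# ---------------------------------------------------------------------------
# full analysis


@dataclass
class OutcomeResult:
    outcome: str
    stratum: str
    univariable: RegressionResult
    multivariable: RegressionResult
    unweighted: RegressionResult
    retained_terms: list[str]
    elimination_path: list[tuple[str, float]]
    crosstab: pd.DataFrame


@dataclass
class AnalysisReport:
    results: dict[tuple[str, str], OutcomeResult]
    spearman: pd.DataFrame
    ipw: IPWResult

    def or_summary(self) -> pd.DataFrame:
        rows = []
        for (outcome, stratum), res in self.results.items():
            for model_name, fit in (
                ("univariable", res.univariable),
                ("multivariable", res.multivariable),
                ("unweighted", res.unweighted),
            ):
                tab = fit.or_table
                for level in ("<55", "55-69"):
                    col = f"age[{level}]"
                    if col in tab.index:
                        rows.append(
                            {
                                "outcome": outcome,
                                "stratum": stratum,
                                "model": model_name,
                                "age_level": level,
                                "odds_ratio": tab.loc[col, "odds_ratio"],
                                "ci_low": tab.loc[col, "ci_low"],
                                "ci_high": tab.loc[col, "ci_high"],
                                "p": tab.loc[col, "p"],
                                "p_trend": fit.p_trend,
                            }
                        )
        return pd.DataFrame(rows)


def _p_trend(
    outcome: pd.Series,
    df: pd.DataFrame,
    terms: dict[str, pd.DataFrame],
    retained: list[str],
    weights,
) -> float:
    """P for continuous age in a companion model where the age-group
    dummies are replaced by raw age (years)."""
    blocks = {k: v for k, v in terms.items() if k in retained and k != "age"}
    design = pd.DataFrame({"age_years": df["age"].astype(float)})
    if blocks:
        design = pd.concat([design] + list(blocks.values()), axis=1)
    fit = fit_weighted_logistic(outcome, design, weights)
    return float(fit.or_table.loc["age_years", "p"])


def run_full_analysis(
    cohort: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    config: StatsConfig | None = None,
) -> AnalysisReport:
    """The full statistical stage on one cohort table.

    For each outcome (overall, micro, LAMB1 high) and stratum (all
    cases, non-MSI-high): univariable and multivariable IPW fits with
    backward elimination, plus unweighted sensitivity fits; Spearman
    age-trend tests for the continuous densities; age-by-outcome
    cross-tabulations.  When ``metrics`` (per-case densities) is given,
    the binary outcomes are derived by dichotomization; otherwise the
    cohort table must already carry the outcome columns.
    """
    config = config or StatsConfig()
    cohort = handle_missing(cohort)
    ipw = estimate_ipw_weights(cohort, config)

    data = cohort[cohort["tissue_available"].astype(bool)].copy()
    if metrics is not None:
        metrics = metrics.set_index("case_id") if "case_id" in metrics.columns else metrics
        data = data.join(metrics, on="case_id", rsuffix="_m")
        for outcome, var, scheme in (
            ("overall_high", "density_overall", "median"),
            ("micro_high", "density_micro", "median"),
            ("lamb1_high", "density_lamb1", "nonzero-median"),
        ):
            data[outcome], _ = dichotomize(data[var], scheme)

    # Spearman age trends on the continuous densities
    sp_rows = []
    for col in data.columns:
        if col.startswith("density_"):
            try:
                rho, p = spearman_trend(data["age"], data[col])
            except ValueError:
                continue
            sp_rows.append({"variable": col, "rho": rho, "p": p})
    spearman = pd.DataFrame(sp_rows)
    if len(spearman):
        spearman["significant"] = multiplicity_flag(spearman["p"], config.alpha)

    results: dict[tuple[str, str], OutcomeResult] = {}
    strata = {
        "all": data,
        "non-MSI-high": data[data["msi"] == "non-MSI-high"],
    }
    for stratum, sdf in strata.items():
        include_msi = stratum == "all"
        for outcome in ("overall_high", "micro_high", "lamb1_high"):
            sub = sdf[sdf[outcome].notna()]
            y = sub[outcome].astype(float)
            w = ipw.weights.reindex(sub.index)
            terms = make_model_terms(sub, include_msi=include_msi)

            uni = fit_weighted_logistic(y, terms["age"], w)
            uni.term_columns = {"age": list(terms["age"].columns)}
            uni.p_trend = _p_trend(y, sub, terms, ["age"], w)

            multi, retained, path = backward_eliminate(
                y, terms, w, config.backward_threshold, config.forced_terms
            )
            multi.p_trend = _p_trend(y, sub, terms, retained, w)

            unw, retained_u, _ = backward_eliminate(
                y, terms, None, config.backward_threshold, config.forced_terms
            )
            unw.p_trend = _p_trend(y, sub, terms, retained_u, None)

            crosstab = pd.crosstab(sub["age_group"], y)
            results[(outcome, stratum)] = OutcomeResult(
                outcome=outcome,
                stratum=stratum,
                univariable=uni,
                multivariable=multi,
                unweighted=unw,
                retained_terms=retained,
                elimination_path=path,
                crosstab=crosstab,
            )
    return AnalysisReport(results=results, spearman=spearman, ipw=ipw)
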