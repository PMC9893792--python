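"""Moderation regressions, stratified slopes, Wald tests, and validation.

The central model is an ordinary least squares regression of a cognitive
change score on a connectivity change score, MeDi adherence group (two
treatment contrasts against the low group, or the continuous 0–55 total),
their multiplicative interaction, and a fixed covariate set (age, sex,
race/ethnicity indicators, education, NART IQ, caloric intake, scrub
percentage, mean cortical thickness, total brain volume, log-transformed
WMH volume, mean FA). Inference is Wald-style by default — normal critical
values for coefficient CIs and chi-square joint tests of the interaction
coefficients — with classical t/F available via ``use_t=True``. The
conventional significance levels are 0.05 for main terms and 0.10 for
interaction terms. No multiple-comparison correction is applied; reports
carry the count of tests performed instead.

Complete-case analysis throughout: rows with missing model variables are
dropped before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .config import SimulationConfig
from .ffq import GROUPS, assign_tertiles
from .synthetic import simulate_analysis_table

logger = logging.getLogger(__name__)

ALPHA_MAIN = 0.05
ALPHA_INTERACTION = 0.10

DEFAULT_COVARIATES: tuple[str, ...] = (
    "age",
    "female",
    "race_black",
    "race_other",
    "education",
    "nart_iq",
    "caloric_intake",
    "scrub_pct",
    "cortical_thickness",
    "total_brain_volume",
    "log_wmh",
    "mean_fa",
)

AGE_GROUPS = ("younger", "middle", "older")


@dataclass
class ModerationSpec:
    """What to regress on what: outcome, exposure, moderator, covariates."""

    outcome: str = "delta_MEMORY"
    exposure: str = "delta_overall_between"
    moderator: str = "group"  # "group" (tertile contrasts) or "continuous"
    group_col: str = "medi_group"
    continuous_col: str = "medi_total"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    groups: tuple[str, ...] = GROUPS

    def model_columns(self) -> list[str]:
        mod = self.group_col if self.moderator == "group" else self.continuous_col
        return [self.outcome, self.exposure, mod, *self.covariates]


@dataclass
class ModerationFit:
    """Coefficient table with Wald CIs, joint interaction test, fit stats."""

    params: pd.DataFrame  # index term; columns B, LL, UL, p
    cov_params: pd.DataFrame = field(repr=False)
    interaction_terms: list[str] = field(default_factory=list)
    wald_chi2: float = float("nan")
    wald_df: int = 0
    wald_p: float = float("nan")
    n: int = 0
    r_squared: float = float("nan")
    use_t: bool = False

    def coef(self, term: str) -> pd.Series:
        return self.params.loc[term]


def prepare_analysis_table(df: pd.DataFrame) -> pd.DataFrame:
    """Derive modelling columns (log-WMH) from raw inputs where absent."""
    out = df.copy()
    if "log_wmh" not in out.columns and "wmh_volume" in out.columns:
        out["log_wmh"] = np.log(out["wmh_volume"])
    return out


def _complete_cases(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"analysis table missing columns: {missing}")
    sub = data[cols].dropna()
    dropped = len(data) - len(sub)
    if dropped:
        logger.info("dropped %d incomplete cases", dropped)
    return sub


def _check_rank(X: pd.DataFrame) -> None:
    """Raise listing (near-)collinear columns if the design is rank-deficient."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        scale = diag.max() if diag.max() > 0 else 1.0
        bad = [X.columns[i] for i in np.flatnonzero(diag / scale < 1e-10)]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def build_design(
    spec: ModerationSpec, data: pd.DataFrame, with_interaction: bool = True
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """(y, X, interaction term names) for a moderation model.

    Group moderation uses treatment coding against the first group (low
    adherence); the interaction columns are exposure x each non-reference
    contrast. Continuous moderation has a single interaction column.
    """
    sub = _complete_cases(data, spec.model_columns())
    y = sub[spec.outcome]
    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    X[spec.exposure] = sub[spec.exposure]
    interactions: list[str] = []
    if spec.moderator == "group":
        ref, *others = spec.groups
        unknown = set(sub[spec.group_col].unique()) - set(spec.groups)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
        for g in others:
            ind = (sub[spec.group_col] == g).astype(float)
            X[f"medi_{g}"] = ind
            if with_interaction:
                name = f"{spec.exposure}:medi_{g}"
                X[name] = sub[spec.exposure] * ind
                interactions.append(name)
    elif spec.moderator == "continuous":
        X["medi_total"] = sub[spec.continuous_col].astype(float)
        if with_interaction:
            name = f"{spec.exposure}:medi_total"
            X[name] = sub[spec.exposure] * X["medi_total"]
            interactions.append(name)
    else:
        raise ValueError(f"unknown moderator kind {spec.moderator!r}")
    for cov in spec.covariates:
        X[cov] = sub[cov].astype(float)
    return y, X, interactions


def _wald_fit(y: pd.Series, X: pd.DataFrame, use_t: bool):
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"n = {len(y)} too small for {X.shape[1]} parameters"
        )
    _check_rank(X)
    res = sm.OLS(y.to_numpy(dtype=float), X).fit(use_t=use_t)
    crit = (
        sps.t.ppf(0.975, res.df_resid) if use_t else sps.norm.ppf(0.975)
    )
    se = res.bse
    table = pd.DataFrame(
        {
            "B": res.params,
            "LL": res.params - crit * se,
            "UL": res.params + crit * se,
            "p": res.pvalues,
        }
    )
    return res, table


def fit_moderation(
    spec: ModerationSpec, data: pd.DataFrame, use_t: bool = False
) -> ModerationFit:
    """Covariate-adjusted OLS moderation fit with Wald inference."""
    y, X, interactions = build_design(spec, data, with_interaction=True)
    res, table = _wald_fit(y, X, use_t)
    fit = ModerationFit(
        params=table,
        cov_params=pd.DataFrame(
            res.cov_params(), index=X.columns, columns=X.columns
        ),
        interaction_terms=interactions,
        n=int(res.nobs),
        r_squared=float(res.rsquared),
        use_t=use_t,
    )
    fit.wald_chi2, fit.wald_df, fit.wald_p = interaction_wald(fit)
    return fit


def interaction_wald(fit: ModerationFit) -> tuple[float, int, float]:
    """Joint Wald chi-square of the interaction coefficients.

    Computes b' V^{-1} b over the interaction terms, referred to a
    chi-square with df = number of interaction terms. For a single term
    this is exactly (B/SE)^2.
    """
    terms = fit.interaction_terms
    if not terms:
        raise ValueError("fit contains no interaction terms")
    b = fit.params.loc[terms, "B"].to_numpy()
    V = fit.cov_params.loc[terms, terms].to_numpy()
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        raise ValueError("singular coefficient covariance for interaction terms")
    df = len(terms)
    return stat, df, float(sps.chi2.sf(stat, df))


def stratified_slopes(
    spec: ModerationSpec, data: pd.DataFrame, use_t: bool = False
) -> pd.DataFrame:
    """Covariate-adjusted exposure slope refit within each MeDi group."""
    rows = []
    for g in spec.groups:
        sub = data[data[spec.group_col] == g]
        row: dict = {"group": g, "n": len(sub)}
        try:
            strat_spec = ModerationSpec(
                outcome=spec.outcome,
                exposure=spec.exposure,
                moderator="group",
                group_col=spec.group_col,
                covariates=spec.covariates,
                groups=(g,),  # single stratum: no contrasts, no interaction
            )
            y, X, _ = build_design(strat_spec, sub, with_interaction=False)
            _, table = _wald_fit(y, X, use_t)
            row.update(table.loc[spec.exposure].to_dict())
        except ValueError as err:
            logger.warning("stratum %s skipped: %s", g, err)
            row.update({"B": np.nan, "LL": np.nan, "UL": np.nan, "p": np.nan})
            row["skipped"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)


def age_stratified(
    spec: ModerationSpec,
    data: pd.DataFrame,
    age_col: str = "age",
    use_t: bool = False,
) -> pd.DataFrame:
    """Joint interaction Wald test refit within each age tertile."""
    data = data.copy()
    data["age_group"] = assign_tertiles(data[age_col].to_numpy(), AGE_GROUPS)
    rows = []
    for g in AGE_GROUPS:
        sub = data[data["age_group"] == g]
        row: dict = {"age_group": g, "n": len(sub)}
        try:
            fit = fit_moderation(spec, sub, use_t=use_t)
            row.update(
                {"wald_chi2": fit.wald_chi2, "df": fit.wald_df, "p": fit.wald_p}
            )
        except ValueError as err:
            logger.warning("age stratum %s skipped: %s", g, err)
            row.update({"wald_chi2": np.nan, "df": np.nan, "p": np.nan})
            row["skipped"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)


def continuous_sensitivity(
    spec: ModerationSpec, data: pd.DataFrame, use_t: bool = False
) -> ModerationFit:
    """Moderation refit with the continuous 0–55 total (1 interaction df)."""
    cont = ModerationSpec(
        outcome=spec.outcome,
        exposure=spec.exposure,
        moderator="continuous",
        group_col=spec.group_col,
        continuous_col=spec.continuous_col,
        covariates=spec.covariates,
        groups=spec.groups,
    )
    return fit_moderation(cont, data, use_t=use_t)


def describe_cohort(
    data: pd.DataFrame,
    group_col: str = "medi_group",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group descriptives with one-way ANOVA / Pearson chi-square tests.

    Continuous variables report mean (SD) by group with an F test;
    categorical variables report percentages with an uncorrected Pearson
    chi-square on the full contingency table. A variable constant overall
    is reported with p = 1 and a warning.
    """
    groups = [g for g in GROUPS if g in set(data[group_col])]
    if len(groups) < 2:
        raise ValueError("describe_cohort requires at least 2 groups")
    if continuous is None:
        continuous = [
            c
            for c in (
                "age", "education", "nart_iq", "caloric_intake",
                "cortical_thickness", "total_brain_volume", "wmh_volume",
                "mean_fa", "scrub_pct",
            )
            if c in data.columns
        ]
    if categorical is None:
        categorical = [c for c in ("female", "race") if c in data.columns]

    rows = []
    for var in continuous:
        cells = {
            g: f"{data.loc[data[group_col] == g, var].mean():.2f} "
            f"({data.loc[data[group_col] == g, var].std(ddof=1):.2f})"
            for g in groups
        }
        if data[var].nunique() <= 1:
            warnings.warn(f"variable {var!r} is constant; p set to 1")
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.f_oneway(
                *(data.loc[data[group_col] == g, var].dropna() for g in groups)
            )
        rows.append(
            {"variable": var, "kind": "continuous", **cells,
             "statistic": float(stat), "p": float(p)}
        )
    for var in categorical:
        obs = pd.crosstab(data[var], data[group_col])[groups]
        cells = {g: " / ".join(f"{v:.1f}%" for v in 100 * obs[g] / obs[g].sum())
                 for g in groups}
        if data[var].nunique() <= 1:
            warnings.warn(f"variable {var!r} is constant; p set to 1")
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = sps.chi2_contingency(obs.to_numpy(), correction=False)
        rows.append(
            {"variable": var, "kind": "categorical", **cells,
             "statistic": float(stat), "p": float(p)}
        )
    return pd.DataFrame(rows)


def exclusion_cascade(roster: pd.DataFrame) -> dict[str, int]:
    """Stepwise sample sizes from the enrolled cohort to the analytic N.

    Order: returned for follow-up → has diet data → has both-visit rsFC →
    has DTI FA → has WMH. Each step is logged.
    """
    steps: dict[str, int] = {"enrolled": len(roster)}
    kept = roster[roster["returned_followup"]]
    steps["returned"] = len(kept)
    kept = kept[kept["has_diet"]]
    steps["after_diet"] = len(kept)
    kept = kept[kept["has_rsfc_both_visits"]]
    steps["after_diet_rsfc"] = len(kept)
    kept = kept[kept["has_dti_fa"]]
    steps["after_dti_fa"] = len(kept)
    kept = kept[kept["has_wmh"]]
    steps["final"] = len(kept)
    for name, n in steps.items():
        logger.info("exclusion cascade: %s = %d", name, n)
    return steps


@dataclass
class RecoveryReport:
    """Per-group slope recovery plus joint-interaction operating traits."""

    per_group: pd.DataFrame  # planted, mean_est, bias, rmse, coverage, sign rate
    sign_flip_rate: float
    interaction_rejection_rate: float
    n_replicates: int
    n_subjects: int
    alpha_interaction: float = ALPHA_INTERACTION


def recovery_experiment(
    config: SimulationConfig,
    n_replicates: int = 200,
    spec: ModerationSpec | None = None,
    alpha_interaction: float = ALPHA_INTERACTION,
    include_stratified: bool = True,
    base_replicate: int = 0,
) -> RecoveryReport:
    """Simulate → fit across replicates; report bias, RMSE, coverage, power.

    Each replicate draws a fresh summary-level cohort, refits the
    group-stratified slopes and the joint interaction test, and records
    whether each group's 95% CI covers its planted slope, whether the
    planted sign pattern (negative low-group slope, positive high-group
    slope) is recovered, and whether the joint interaction test rejects at
    ``alpha_interaction``.
    """
    spec = spec or ModerationSpec()
    planted = config.planted_betas
    est: dict[str, list[float]] = {g: [] for g in spec.groups}
    cover: dict[str, list[bool]] = {g: [] for g in spec.groups}
    flips: list[bool] = []
    rejections: list[bool] = []

    for rep in range(n_replicates):
        table = simulate_analysis_table(config, replicate=base_replicate + rep)
        fit = fit_moderation(spec, table)
        rejections.append(fit.wald_p < alpha_interaction)
        if include_stratified:
            strat = stratified_slopes(spec, table).set_index("group")
            for g in spec.groups:
                est[g].append(strat.loc[g, "B"])
                cover[g].append(
                    strat.loc[g, "LL"] <= planted[g] <= strat.loc[g, "UL"]
                )
            flips.append(
                (np.sign(strat.loc["low", "B"]) == np.sign(planted["low"]))
                and (np.sign(strat.loc["high", "B"]) == np.sign(planted["high"]))
            )

    rows = []
    for g in spec.groups:
        e = np.asarray(est[g], dtype=float)
        rows.append(
            {
                "group": g,
                "planted": planted[g],
                "mean_est": e.mean() if e.size else np.nan,
                "bias": e.mean() - planted[g] if e.size else np.nan,
                "rmse": float(np.sqrt(np.mean((e - planted[g]) ** 2)))
                if e.size
                else np.nan,
                "coverage": float(np.mean(cover[g])) if cover[g] else np.nan,
                "sign_rate": float(np.mean(np.sign(e) == np.sign(planted[g])))
                if e.size and planted[g] != 0
                else np.nan,
            }
        )
    return RecoveryReport(
        per_group=pd.DataFrame(rows),
        sign_flip_rate=float(np.mean(flips)) if flips else float("nan"),
        interaction_rejection_rate=float(np.mean(rejections)),
        n_replicates=n_replicates,
        n_subjects=config.n_subjects,
        alpha_interaction=alpha_interaction,
    )
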