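"""Statistical validation layer: prognosis, associations, contrasts.

Four analyses mirror the standard clinical validation of a staging
model on an at-risk cohort:

* :func:`cox_compare` — Cox proportional-hazards comparison of a
  baseline model (demographics + APOE4) against a full model that adds
  disease stage and one-hot subtype, reporting concordance index, AIC,
  hazard ratios and a log-rank test of stage-dichotomized groups.
* :func:`nested_linear` — three nested OLS models (covariates /
  + stage / + stage + subtype) with the adjusted-R-squared ladder and
  the stage coefficient from the full model.
* :func:`logistic_association` — the logistic analogue for binary
  outcomes with a likelihood-ratio test against the covariate-only
  model.
* :func:`subtype_contrasts` — pairwise Mann-Whitney tests between
  subtypes on covariate- and stage-residualized values, with
  Benjamini-Hochberg correction over the pair family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import ConfigurationError, FitError

BASE_COVARIATES = ["age", "gender", "education", "apoe4"]


def _subtype_dummies(subtype: pd.Series) -> pd.DataFrame:
    """One-hot encode subtype with the most prevalent level as reference."""
    counts = subtype.value_counts()
    reference = counts.index[np.argmax(counts.to_numpy())]
    levels = [l for l in sorted(counts.index) if l != reference]
    return pd.DataFrame(
        {f"subtype_{l}": (subtype == l).astype(float) for l in levels},
        index=subtype.index,
    )


# ---------------------------------------------------------------------------
# Cox comparison
# ---------------------------------------------------------------------------


@dataclass
class CoxModelResult:
    concordance_index: float
    aic: float
    log_likelihood: float
    n_params: int
    hazard_ratios: pd.DataFrame      # term, hr, ci_low, ci_high, p


@dataclass
class ModelComparison:
    base: CoxModelResult
    full: CoxModelResult
    logrank_stage_p: float

    def forest_table(self) -> pd.DataFrame:
        """Forest-plot-ready table of the full model."""
        return self.full.hazard_ratios.rename(columns={"term": "term"})


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxModelResult:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[["time", "event"] + covariates], duration_col="time",
                    event_col="event")
    except ConvergenceError as err:
        raise FitError(
            f"Cox model failed to converge with covariates {covariates}: {err}"
        ) from err
    summ = cph.summary
    hr = pd.DataFrame({
        "term": summ.index,
        "hr": np.exp(summ["coef"]).to_numpy(),
        "ci_low": np.exp(summ["coef lower 95%"]).to_numpy(),
        "ci_high": np.exp(summ["coef upper 95%"]).to_numpy(),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    k = len(covariates)
    ll = cph.log_likelihood_
    return CoxModelResult(
        concordance_index=float(cph.concordance_index_),
        aic=float(2 * k - 2 * ll),
        log_likelihood=float(ll),
        n_params=k,
        hazard_ratios=hr,
    )


def cox_compare(records: pd.DataFrame) -> ModelComparison:
    """Baseline-vs-full Cox comparison on a survival table.

    ``records`` needs columns ``time`` (> 0, months), ``event`` (0/1),
    the four base covariates, ``stage`` and ``subtype``. The full model
    adds stage plus one-hot subtype (most prevalent subtype as the
    reference). Ties are handled with the Efron approximation. The
    headline log-rank p compares subjects with stage <= cohort median
    against the rest.
    """
    required = ["time", "event", *BASE_COVARIATES, "stage", "subtype"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ConfigurationError(f"survival table lacks columns: {missing}")
    if (records["time"] <= 0).any():
        raise ConfigurationError("all survival times must be > 0")
    if records["event"].sum() < 2:
        raise ConfigurationError("need at least 2 events for a Cox fit")
    df = records.copy()
    dummies = _subtype_dummies(df["subtype"])
    df = pd.concat([df.drop(columns=["subtype"]), dummies], axis=1)
    base = _fit_cox(df, BASE_COVARIATES)
    full = _fit_cox(df, BASE_COVARIATES + ["stage"] + list(dummies.columns))
    median_stage = records["stage"].median()
    low = records["stage"] <= median_stage
    lr = logrank_test(
        records.loc[low, "time"], records.loc[~low, "time"],
        records.loc[low, "event"], records.loc[~low, "event"],
    )
    return ModelComparison(base, full, float(lr.p_value))


# ---------------------------------------------------------------------------
# Association regressions
# ---------------------------------------------------------------------------


@dataclass
class AssociationReport:
    outcome: str
    kind: str                                # "linear" | "logistic"
    r2_ladder: dict                          # base / base+stage / full
    beta_stage: float
    beta_stage_se: float
    beta_stage_p: float
    overall_p: float                         # F-test or LR-test of the full model
    contrasts: pd.DataFrame | None = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "outcome": self.outcome,
            "kind": self.kind,
            "r2_ladder": self.r2_ladder,
            "beta_stage": self.beta_stage,
            "beta_stage_se": self.beta_stage_se,
            "beta_stage_p": self.beta_stage_p,
            "overall_p": self.overall_p,
            "notes": self.notes,
        }
        if self.contrasts is not None:
            out["contrasts"] = self.contrasts.to_dict(orient="records")
        return out


def _design(covariates: pd.DataFrame, stage=None, subtype=None):
    X = covariates[BASE_COVARIATES].astype(float).copy()
    if stage is not None:
        X["stage"] = np.asarray(stage, dtype=float)
    if subtype is not None:
        X = pd.concat([X, _subtype_dummies(pd.Series(subtype, index=X.index))], axis=1)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame):
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns involved in the deficiency
        bad = []
        keep: list[str] = []
        for col in X.columns:
            trial = keep + [col]
            if np.linalg.matrix_rank(X[trial].to_numpy()) < len(trial):
                bad.append(col)
            else:
                keep.append(col)
        raise ConfigurationError(f"design matrix is rank deficient; collinear columns: {bad}")


def nested_linear(outcome: pd.Series, covariates: pd.DataFrame,
                  stage: pd.Series, subtype: pd.Series) -> AssociationReport:
    """Three nested OLS fits for a continuous outcome.

    Reports the adjusted-R-squared ladder (covariates only, + stage,
    + stage + subtype), the stage coefficient (SE, p) from the full
    model, and the full model's F-test p-value.
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    X_full = _design(covariates, stage, subtype)
    if n <= X_full.shape[1] + 2:
        raise ConfigurationError("too few observations for the full model")
    _check_rank(X_full)
    ladder = {}
    fits = {}
    for name, X in (
        ("base", _design(covariates)),
        ("base+stage", _design(covariates, stage)),
        ("base+stage+subtype", X_full),
    ):
        res = sm.OLS(y, X).fit()
        ladder[name] = float(res.rsquared_adj)
        fits[name] = res
    full = fits["base+stage+subtype"]
    return AssociationReport(
        outcome=getattr(outcome, "name", None) or "outcome",
        kind="linear",
        r2_ladder=ladder,
        beta_stage=float(full.params["stage"]),
        beta_stage_se=float(full.bse["stage"]),
        beta_stage_p=float(full.pvalues["stage"]),
        overall_p=float(full.f_pvalue),
    )


def logistic_association(outcome: pd.Series, covariates: pd.DataFrame,
                         stage: pd.Series, subtype: pd.Series) -> AssociationReport:
    """Logistic regression of a binary outcome on covariates + stage +
    subtype, with a likelihood-ratio test against the covariate-only
    model. Perfect separation is flagged and the stage coefficient
    reported as non-estimable (NaN) rather than raised."""
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ConfigurationError("binary outcome must contain both classes")
    X_base = _design(covariates)
    X_full = _design(covariates, stage, subtype)
    _check_rank(X_full)
    notes = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
            base = sm.Logit(y, X_base).fit(disp=0, maxiter=200)
        if not (full.mle_retvals.get("converged", True)
                and base.mle_retvals.get("converged", True)):
            raise PerfectSeparationError("logistic fit did not converge")
        lr = 2 * (full.llf - base.llf)
        overall_p = float(stats.chi2.sf(max(lr, 0.0), df=X_full.shape[1] - X_base.shape[1]))
        ladder = {
            "base": float(base.prsquared),
            "base+stage+subtype": float(full.prsquared),
        }
        beta, se, p = (float(full.params["stage"]), float(full.bse["stage"]),
                       float(full.pvalues["stage"]))
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        notes.append(f"non-estimable: {err}")
        ladder, beta, se, p, overall_p = {}, np.nan, np.nan, np.nan, np.nan
    return AssociationReport(
        outcome=getattr(outcome, "name", None) or "outcome",
        kind="logistic",
        r2_ladder=ladder,
        beta_stage=beta,
        beta_stage_se=se,
        beta_stage_p=p,
        overall_p=overall_p,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Subtype contrasts
# ---------------------------------------------------------------------------


def subtype_contrasts(values: pd.Series, subtype: pd.Series,
                      covariates: pd.DataFrame, stage: pd.Series,
                      min_group: int = 2) -> pd.DataFrame:
    """Pairwise subtype comparisons adjusted for covariates and stage.

    Values are residualized on covariates + stage by least squares, then
    every subtype pair is compared with a two-sided Mann-Whitney test on
    the residuals; p-values are Benjamini-Hochberg adjusted over the
    pair family. Pairs with an undersized group are skipped and noted in
    the ``skipped`` column of the attrs.
    """
    levels = sorted(pd.unique(subtype))
    big = [l for l in levels if (subtype == l).sum() >= min_group]
    if len(big) < 2:
        raise ConfigurationError("need >= 2 subtypes with >= 2 subjects each")
    X = _design(covariates, stage)
    resid = pd.Series(
        sm.OLS(np.asarray(values, dtype=float), X).fit().resid,
        index=values.index,
    )
    rows, skipped = [], []
    for a, b in itertools.combinations(levels, 2):
        if a not in big or b not in big:
            skipped.append((a, b))
            continue
        ra = resid[subtype == a]
        rb = resid[subtype == b]
        stat, p = stats.mannwhitneyu(ra, rb, alternative="two-sided")
        rows.append({"pair": f"{a}-{b}", "statistic": float(stat), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    table.attrs["skipped"] = skipped
    return table
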