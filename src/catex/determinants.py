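"""Determinants of catastrophic expenditure: regression stage.

Given the per-household CHE decomposition, this module fits

* a logistic regression of the CHE indicator on household covariates, with
  average marginal effects (AMEs) so its coefficients can be read on the
  probability scale, and
* an ordinary-least-squares linear probability model (LPM) with
  heteroskedasticity-robust (HC1) standard errors — the LPM is defensible
  here because CHE prevalence is mid-range (roughly 20–80%), where the
  logistic curve is near-linear,

plus classic bidirectional (entry–removal) stepwise covariate selection on
Wald p-values, a side-by-side AME-vs-LPM comparison, and the Pearson
chi-square association test used for subgroup contrasts.

Money covariates are expressed in thousands of pesos so that a coefficient
reads "change in P(CHE) per additional 1000 MXN".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io_model import SurveyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "FitResult",
    "SeparationError",
    "StepwiseOscillationError",
    "DEFAULT_COVARIATES",
    "design_covariates",
    "build_design_matrix",
    "fit_logit",
    "fit_lpm",
    "marginal_effects",
    "stepwise_select",
    "compare_models",
    "contingency_chi2",
    "regression_table",
]

#: Default covariate set: the variables the determinants stage examines.
#: Money covariates are annual amounts in 1000-MXN units.
DEFAULT_COVARIATES = [
    "income_k",
    "hospitalization_k",
    "medicines_k",
    "household_size",
    "patient_male",
    "patient_employed",
    "missed_work_days",
]


class SeparationError(RuntimeError):
    """The logit likelihood is unbounded: a covariate separates the classes."""


class StepwiseOscillationError(RuntimeError):
    """Stepwise selection revisited a model: entry/removal thresholds cycle."""


@dataclass
class DesignMatrix:
    """Binary response (CHE flag at one threshold) plus named covariates."""

    response: pd.Series
    covariates: pd.DataFrame
    threshold: float | None = None

    def __post_init__(self) -> None:
        if len(self.response) != len(self.covariates):
            raise ValueError("response and covariates differ in length")
        if self.covariates.isna().any().any() or self.response.isna().any():
            raise ValueError("design matrix contains missing cells")

    @property
    def n(self) -> int:
        return len(self.response)

    def subset(self, cols: Sequence[str]) -> "DesignMatrix":
        return DesignMatrix(self.response, self.covariates[list(cols)],
                            self.threshold)


@dataclass
class FitResult:
    """Fitted model summary for either the logit or the LPM."""

    model: str  # "logit" | "ols"
    params: pd.Series
    bse: pd.Series
    ci95: pd.DataFrame  # columns lo, hi
    pvalues: pd.Series
    n_used: int
    converged: bool
    threshold: float | None = None
    marginal_effects: pd.Series | None = None
    marginal_effects_se: pd.Series | None = None
    pseudo_r2: float | None = None  # McFadden (logit)
    r2: float | None = None  # OLS
    lr_chi2: float | None = None
    lr_df: int | None = None
    llf: float | None = None
    sm_result: object = field(default=None, repr=False)


def design_covariates(
    ds: SurveyDataset,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Covariate columns of the determinants design matrix.

    Derived columns: ``income_k``, ``hospitalization_k``, ``medicines_k``
    (annual 1000-MXN units, so coefficients read per additional 1000 pesos),
    ``patient_male`` (male = 1).
    """
    frame = ds.frame
    X = pd.DataFrame(index=frame.index)
    X["income_k"] = frame["income"] / 1000.0
    X["hospitalization_k"] = frame["oop_hospitalization"] / 1000.0
    X["medicines_k"] = frame["oop_medicines"] / 1000.0
    X["household_size"] = frame["household_size"].astype(float)
    X["patient_male"] = (frame["patient_sex"] == "male").astype(float)
    X["patient_employed"] = frame["patient_employed"].astype(float)
    X["missed_work_days"] = frame["missed_work_days"].astype(float)
    for extra in covariates:
        if extra not in X.columns:
            if extra not in frame.columns:
                raise ValueError(f"unknown covariate {extra!r}")
            X[extra] = pd.to_numeric(frame[extra])
    return X[list(covariates)]


def build_design_matrix(
    ds: SurveyDataset,
    decomposition: pd.DataFrame,
    threshold: float = 0.30,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> DesignMatrix:
    """Assemble the regression table from records and their decomposition.

    ``ds`` must be the same annualized MXN dataset the decomposition was
    computed from; the response is the CHE flag at ``threshold``.
    """
    flag_col = f"flag_{int(round(threshold * 100))}"
    if flag_col not in decomposition.columns:
        raise ValueError(f"decomposition lacks column {flag_col}")
    X = design_covariates(ds, covariates)
    y = pd.Series(decomposition[flag_col].to_numpy(), index=ds.frame.index,
                  name="che")
    return DesignMatrix(response=y, covariates=X, threshold=threshold)


def _check_separation(dm: DesignMatrix) -> str | None:
    """Name a covariate that perfectly separates the response, if any."""
    y = dm.response.to_numpy()
    for col in dm.covariates.columns:
        x = dm.covariates[col].to_numpy(dtype=float)
        x0, x1 = x[y == 0], x[y == 1]
        if len(x0) == 0 or len(x1) == 0:
            continue
        if x0.max() < x1.min() or x1.max() < x0.min():
            return col
    return None


def fit_logit(dm: DesignMatrix, maxiter: int = 200) -> FitResult:
    """Maximum-likelihood logistic regression of the CHE flag.

    Reports coefficients, Wald standard errors and 95% CIs, McFadden
    pseudo-R², and the likelihood-ratio chi-square against the
    intercept-only model.  The ``converged`` flag is honest: failure to
    converge, or non-finite estimates, are reported, never masked.  Perfect
    separation raises :class:`SeparationError` naming the covariate.
    """
    y = dm.response.to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("response is constant; logit model is undefined")
    X = sm.add_constant(dm.covariates.astype(float), has_constant="add")
    if dm.n <= X.shape[1]:
        raise ValueError("more parameters than observations")
    sep = _check_separation(dm)
    if sep is not None:
        raise SeparationError(
            f"covariate {sep!r} perfectly separates the response; "
            "the likelihood has no maximum"
        )
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=maxiter, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"logit estimation failed ({exc}); the fit is unstable "
            "(quasi-separation or singular design)"
        ) from exc
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    finite = bool(np.isfinite(params).all() and np.isfinite(bse).all())
    grad_ok = False
    if finite:
        score = model.score(res.params)
        grad_ok = bool(np.max(np.abs(score)) < 1e-4 * max(1.0, dm.n / 100))
    converged = bool(res.mle_retvals.get("converged", False)) and finite and grad_ok
    if not converged:
        logger.warning(
            "logit at threshold %s did not converge (finite=%s, grad_ok=%s)",
            dm.threshold, finite, grad_ok,
        )
    ci = pd.DataFrame(np.asarray(res.conf_int()), index=X.columns,
                      columns=["lo", "hi"])
    return FitResult(
        model="logit", params=params, bse=bse, ci95=ci,
        pvalues=pd.Series(res.pvalues, index=X.columns),
        n_used=dm.n, converged=converged, threshold=dm.threshold,
        pseudo_r2=float(res.prsquared), lr_chi2=float(res.llr),
        lr_df=int(res.df_model), llf=float(res.llf), sm_result=res,
    )


def fit_lpm(dm: DesignMatrix) -> FitResult:
    """Linear probability model: OLS of the CHE flag with HC1 robust SEs.

    Coefficients are direct probability changes per covariate unit.  A
    rank-deficient design raises, naming the collinear columns.
    """
    X = sm.add_constant(dm.covariates.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.iloc[:, 1:].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"most collinear pair: {worst}"
        )
    res = sm.OLS(dm.response.to_numpy(dtype=float), X).fit(cov_type="HC1")
    params = pd.Series(res.params, index=X.columns)
    slopes = params.drop("const")
    return FitResult(
        model="ols", params=params,
        bse=pd.Series(res.bse, index=X.columns),
        ci95=pd.DataFrame(np.asarray(res.conf_int()), index=X.columns,
                          columns=["lo", "hi"]),
        pvalues=pd.Series(res.pvalues, index=X.columns),
        n_used=dm.n, converged=True, threshold=dm.threshold,
        marginal_effects=slopes,  # LPM slopes are the marginal effects
        marginal_effects_se=pd.Series(res.bse, index=X.columns).drop("const"),
        r2=float(res.rsquared), sm_result=res,
    )


def marginal_effects(fit: FitResult, dm: DesignMatrix,
                     at: str = "overall") -> FitResult:
    """Attach marginal effects of the logit to its FitResult.

    ``at="overall"`` gives average marginal effects (AMEs): for a continuous
    covariate the sample mean of ``b_j p_i(1−p_i)``; for a binary covariate
    the difference in mean predicted probability between the two
    counterfactuals.  ``at="mean"`` evaluates at covariate means instead.
    Delta-method standard errors accompany the point estimates.
    """
    if fit.model != "logit":
        raise ValueError("marginal_effects applies to logit fits")
    if not fit.converged:
        raise RuntimeError("refusing marginal effects of a non-converged fit")
    if at not in ("overall", "mean"):
        raise ValueError("at must be 'overall' or 'mean'")
    meff = fit.sm_result.get_margeff(at=at, method="dydx", dummy=True)
    names = list(dm.covariates.columns)
    fit.marginal_effects = pd.Series(meff.margeff, index=names)
    fit.marginal_effects_se = pd.Series(meff.margeff_se, index=names)
    return fit


def _fit_for_step(dm: DesignMatrix, cols: list[str], model: str) -> FitResult:
    sub = dm.subset(cols) if cols else DesignMatrix(
        dm.response, dm.covariates[[]], dm.threshold)
    if model == "logit":
        y = sub.response.to_numpy(dtype=float)
        X = sm.add_constant(sub.covariates.astype(float), has_constant="add")
        res = sm.Logit(y, X).fit(disp=0, warn_convergence=False)
        return FitResult(
            model="logit", params=pd.Series(res.params, index=X.columns),
            bse=pd.Series(res.bse, index=X.columns),
            ci95=pd.DataFrame(np.asarray(res.conf_int()), index=X.columns,
                              columns=["lo", "hi"]),
            pvalues=pd.Series(res.pvalues, index=X.columns),
            n_used=sub.n, converged=bool(res.mle_retvals.get("converged", True)),
            threshold=dm.threshold, pseudo_r2=float(res.prsquared),
            llf=float(res.llf), sm_result=res,
        )
    return fit_lpm(sub)


def stepwise_select(
    dm: DesignMatrix,
    model: str = "logit",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 200,
) -> tuple[list[str], FitResult, pd.DataFrame]:
    """Bidirectional (entry–removal) stepwise selection on Wald p-values.

    Starting from the intercept-only model, each cycle adds the candidate
    with the smallest Wald p-value below ``p_enter`` and then removes the
    included covariate with the largest p-value above ``p_remove``.
    Deterministic given column order (ties broken by order); an audit log of
    every step is returned.  Revisiting a previously seen model aborts with
    :class:`StepwiseOscillationError` (only possible when the thresholds are
    mis-ordered, hence the admissibility check ``p_enter ≤ p_remove``).
    """
    if p_enter > p_remove:
        raise ValueError("p_enter must be <= p_remove")
    if model not in ("logit", "ols"):
        raise ValueError("model must be 'logit' or 'ols'")
    candidates = list(dm.covariates.columns)
    selected: list[str] = []
    visited = {frozenset()}
    log: list[dict] = []
    for step in range(max_steps):
        changed = False
        # entry: best candidate below p_enter
        best_col, best_p = None, None
        for col in candidates:
            if col in selected:
                continue
            trial = _fit_for_step(dm, selected + [col], model)
            p = float(trial.pvalues[col])
            if p < p_enter and (best_p is None or p < best_p):
                best_col, best_p = col, p
        if best_col is not None:
            selected.append(best_col)
            log.append({"step": step, "action": "enter", "covariate": best_col,
                        "p": best_p})
            changed = True
        # removal: worst included above p_remove
        if selected:
            fit = _fit_for_step(dm, selected, model)
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if float(pvals[worst]) > p_remove:
                selected.remove(worst)
                log.append({"step": step, "action": "remove",
                            "covariate": worst, "p": float(pvals[worst])})
                changed = True
        if not changed:
            break
        key = frozenset(selected)
        if key in visited:
            raise StepwiseOscillationError(
                f"stepwise revisited model {sorted(key)}; "
                f"audit log: {log}"
            )
        visited.add(key)
    final = _fit_for_step(dm, selected, model)
    return selected, final, pd.DataFrame(
        log, columns=["step", "action", "covariate", "p"])


def compare_models(logit_fit: FitResult, lpm_fit: FitResult) -> pd.DataFrame:
    """Side-by-side logit AMEs vs LPM slopes with sign-agreement flags."""
    if logit_fit.marginal_effects is None:
        raise ValueError("logit fit lacks marginal effects; call "
                         "marginal_effects() first")
    ame = logit_fit.marginal_effects
    ols = lpm_fit.marginal_effects
    if set(ame.index) != set(ols.index):
        raise ValueError(
            f"covariate mismatch: {sorted(set(ame.index) ^ set(ols.index))}")
    ols = ols.reindex(ame.index)
    out = pd.DataFrame({"logit_ame": ame, "ols_coef": ols})
    out["abs_difference"] = (out["logit_ame"] - out["ols_coef"]).abs()
    out["sign_agree"] = np.sign(out["logit_ame"]) == np.sign(out["ols_coef"])
    return out


def contingency_chi2(flags, group) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) of CHE flag × group.

    Groups with zero members are dropped with a warning.  Returns
    ``(chi2, df, p)`` with ``df = (r−1)(c−1)``.
    """
    flags = pd.Series(np.asarray(flags))
    group = pd.Series(np.asarray(group))
    if len(flags) != len(group):
        raise ValueError("flags and group differ in length")
    table = pd.crosstab(flags, group)
    empty = table.columns[(table.sum(axis=0) == 0)]
    if len(empty):
        logger.warning("dropping empty group(s): %s", list(empty))
        table = table.drop(columns=empty)
    if table.shape[1] < 2:
        raise ValueError("need at least two non-empty groups")
    chi2, p, dof, _ = scipy.stats.chi2_contingency(table.to_numpy(),
                                                   correction=False)
    return float(chi2), int(dof), float(p)


def _stars(p: float, cuts: tuple[float, float, float]) -> str:
    a, b, c = cuts
    return "***" if p < a else "**" if p < b else "*" if p < c else ""


def regression_table(fit: FitResult,
                     star_cuts: tuple[float, float, float] = (0.01, 0.05, 0.10),
                     ) -> pd.DataFrame:
    """Publication-style table: coefficient, SE, CI95, significance stars."""
    out = pd.DataFrame({
        "coef": fit.params, "se": fit.bse,
        "ci95_lo": fit.ci95["lo"], "ci95_hi": fit.ci95["hi"],
        "p": fit.pvalues,
    })
    out["stars"] = [_stars(p, star_cuts) for p in out["p"]]
    if fit.marginal_effects is not None:
        out["marginal_effect"] = fit.marginal_effects.reindex(out.index)
    return out
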