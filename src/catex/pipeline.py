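"""End-to-end orchestration: one reproducible run from input to report.

A :class:`RunConfig` names either an input CSV or a synthetic scenario plus
the CHE and determinants parameters; :func:`run_pipeline` executes
load/simulate → annualize → decomposition → threshold sensitivity →
regression models → comparison, writes every intermediate as CSV (auditable
text, no binaries), and records a JSON manifest (config hash, seed, library
versions, row counts) so identical configs yield identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import scipy.stats

from . import che_core, determinants, io_model, synthetic_data
from .che_core import DEFAULT_BETA, DEFAULT_THRESHOLDS, DEFAULT_WINDOW
from .determinants import DEFAULT_COVARIATES

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "summarize_descriptives"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; exactly one input source."""

    input_csv: str | None = None
    scenario: synthetic_data.ScenarioConfig | None = None
    convention: io_model.MoneyConvention = field(
        default_factory=io_model.MoneyConvention)
    beta: float = DEFAULT_BETA
    window: tuple[float, float] = DEFAULT_WINDOW
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    model_threshold: float = 0.30
    covariates: tuple[str, ...] = tuple(DEFAULT_COVARIATES)
    stepwise: bool = False
    p_enter: float = 0.05
    p_remove: float = 0.10
    outdir: str = "catex_run"
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.scenario is None):
            raise ValueError(
                "specify exactly one of input_csv or scenario")
        if any(not (0 < z < 1) for z in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    dataset: io_model.SurveyDataset
    poverty_line: che_core.PovertyLine
    decomposition: pd.DataFrame
    sensitivity: pd.DataFrame
    logit_fit: determinants.FitResult | None
    lpm_fit: determinants.FitResult
    comparison: pd.DataFrame | None
    descriptives: pd.DataFrame
    manifest: dict


def _stars(p: float, cuts=(0.001, 0.01, 0.05)) -> str:
    a, b, c = cuts
    return "***" if p < a else "**" if p < b else "*" if p < c else ""


def summarize_descriptives(ds: io_model.SurveyDataset,
                           flags: np.ndarray) -> pd.DataFrame:
    """Sample characteristics by CHE status, with per-variable tests.

    Continuous variables get group means and a two-sample (Welch) t test;
    categorical variables get frequencies and a Pearson chi-square.  A
    constant variable's statistic is omitted with a note.  Stars at
    0.001/0.01/0.05, the descriptive-table convention.
    """
    frame = ds.frame
    flags = np.asarray(flags)
    rows = []
    continuous = ["income", "expenditure_total", "expenditure_food",
                  "patient_age", "patient_education_years",
                  "caregiver_age", "caregiver_education_years",
                  "household_size", "missed_work_days"] + io_model.OOP_COLUMNS
    categorical = ["patient_sex", "caregiver_sex", "patient_diagnosis",
                   "patient_employed", "marital_status",
                   "caregiver_relationship"]
    che, no = frame[flags == 1], frame[flags == 0]
    for col in continuous:
        x1, x0 = che[col].to_numpy(float), no[col].to_numpy(float)
        row = {"variable": col, "kind": "continuous",
               "overall": frame[col].mean(),
               "che_mean": x1.mean() if len(x1) else np.nan,
               "no_che_mean": x0.mean() if len(x0) else np.nan}
        if frame[col].nunique() <= 1 or not len(x1) or not len(x0):
            row.update(stat=np.nan, p=np.nan, stars="",
                       note="constant or empty group; test omitted")
        else:
            t, p = scipy.stats.ttest_ind(x1, x0, equal_var=False)
            row.update(stat=float(t), p=float(p), stars=_stars(p), note="")
        rows.append(row)
    for col in categorical:
        ser = frame[col].astype(str)
        top = ser.value_counts(normalize=True)
        row = {"variable": col, "kind": "categorical",
               "overall": float(top.iloc[0]),
               "che_mean": np.nan, "no_che_mean": np.nan}
        if ser.nunique() <= 1 or not len(che) or not len(no):
            row.update(stat=np.nan, p=np.nan, stars="",
                       note="constant or empty group; test omitted")
        else:
            chi2, df, p = determinants.contingency_chi2(flags, ser.to_numpy())
            row.update(stat=chi2, p=p, stars=_stars(p), note=f"df={df}")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full analysis and persist every artifact under ``outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.scenario is not None:
        scenario = cfg.scenario
        if cfg.seed is not None:
            scenario = dataclasses.replace(scenario, seed=cfg.seed)
        ds = synthetic_data.simulate_households(scenario)
        io_model.write_survey(ds, outdir / "survey.csv")
    else:
        ds = io_model.load_survey(cfg.input_csv, cfg.convention)
        io_model.write_survey(ds, outdir / "survey_accepted.csv")
        if ds.rejects is not None and len(ds.rejects):
            ds.rejects.to_csv(outdir / "rejects.csv", index=False)

    annual = io_model.annualize(ds)
    pl, dec = che_core.decompose(annual, beta=cfg.beta, window=cfg.window,
                                 thresholds=cfg.thresholds)
    dec.to_csv(outdir / "decomposition.csv", index=False)
    sens = che_core.sensitivity_analysis(
        annual, beta=cfg.beta, window=cfg.window, thresholds=cfg.thresholds)
    sens.to_csv(outdir / "incidence_by_threshold.csv", index=False)

    dm = determinants.build_design_matrix(
        annual, dec, threshold=cfg.model_threshold,
        covariates=list(cfg.covariates))
    logit_fit, comparison, logit_note = None, None, ""
    try:
        if cfg.stepwise:
            selected, logit_fit, audit = determinants.stepwise_select(
                dm, model="logit", p_enter=cfg.p_enter, p_remove=cfg.p_remove)
            audit.to_csv(outdir / "stepwise_log.csv", index=False)
            dm_sel = dm.subset(selected) if selected else dm
            logit_fit = determinants.fit_logit(dm_sel)
            logit_fit = determinants.marginal_effects(logit_fit, dm_sel)
        else:
            logit_fit = determinants.fit_logit(dm)
            if logit_fit.converged:
                logit_fit = determinants.marginal_effects(logit_fit, dm)
            else:
                logit_note = ("logit did not converge at threshold "
                              f"{cfg.model_threshold}")
    except (determinants.SeparationError, ValueError) as exc:
        logit_note = f"logit unavailable: {exc}"
        logger.warning(logit_note)

    lpm_fit = determinants.fit_lpm(dm)
    ols_table = determinants.regression_table(lpm_fit)
    ols_table.to_csv(outdir / "ols_table.csv")
    (outdir / "ols_table.txt").write_text(ols_table.round(4).to_string() + "\n")
    if logit_fit is not None:
        logit_table = determinants.regression_table(logit_fit)
        logit_table.to_csv(outdir / "logit_table.csv")
        (outdir / "logit_table.txt").write_text(
            logit_table.round(4).to_string() + "\n")
        if logit_fit.marginal_effects is not None:
            comparison = determinants.compare_models(logit_fit, lpm_fit)
            comparison.to_csv(outdir / "model_comparison.csv")

    flag_col = f"flag_{int(round(cfg.model_threshold * 100))}"
    desc = summarize_descriptives(annual, dec[flag_col].to_numpy())
    desc.to_csv(outdir / "descriptives.csv", index=False)

    manifest = {
        "config_digest": cfg.digest(),
        "seed": (cfg.seed if cfg.seed is not None
                 else getattr(cfg.scenario, "seed", None)),
        "n_households": int(ds.n),
        "n_rejected": int(len(ds.rejects)) if ds.rejects is not None else 0,
        "poverty_line_per_eq_adult": pl.value_per_eq_adult,
        "n_reference": pl.n_reference,
        "sensitivity_rows": int(len(sens)),
        "logit_note": logit_note,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    lines = [
        f"Households analysed: {ds.n}",
        f"Poverty line (annual, per equivalent adult): "
        f"{pl.value_per_eq_adult:.2f} ({pl.n_reference} reference households)",
        "Incidence by threshold:",
    ]
    for _, r in sens.iterrows():
        lines.append(
            f"  z={r['threshold']:.0%}: {r['incidence_pct']:.1f}% "
            f"[{r['ci95_lo']:.1f}, {r['ci95_hi']:.1f}] "
            f"({int(r['n_che'])}/{int(r['n_households'])})")
    if logit_fit is not None and logit_fit.pseudo_r2 is not None:
        lines.append(f"Logit at z={cfg.model_threshold:.0%}: pseudo-R2 = "
                     f"{logit_fit.pseudo_r2:.3f}, LR chi2 = "
                     f"{logit_fit.lr_chi2:.1f} (df {logit_fit.lr_df})")
    if logit_note:
        lines.append(f"NOTE: {logit_note}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")

    return RunResult(dataset=ds, poverty_line=pl, decomposition=dec,
                     sensitivity=sens, logit_fit=logit_fit, lpm_fit=lpm_fit,
                     comparison=comparison, descriptives=desc,
                     manifest=manifest)
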