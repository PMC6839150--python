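"""Stage 3: prognostic evaluation of a scored cohort.

Everything reported on a scored cohort: Kaplan-Meier curves and log-rank
test by score group, univariate and multivariable Cox regression (score as
category or as integer points), the score-vs-median-OS Pearson
correlation, subgroup analyses, and the survival-threshold ROC comparison
of the clinical-covariate model ("AGSR": age, grade, stage, residual),
the score alone, and both combined.

ROC construction: patients are binarized at the cohort's Kaplan-Meier
median OS — "long" means os_time >= median (event or censored; their
follow-up already exceeds the threshold), "short" means os_time < median
with the death observed. Patients censored before the median are excluded
(their class is unknowable). Risk scores are in-sample Cox linear
predictors for each covariate set, with short survival as the positive
class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from roscore.cohort_io import ClinicalTable
from roscore.scoring import GROUP_HIGH, GROUP_LOW, ScoreTable
from roscore.survival import (
    ConstantCovariateError,
    CoxFit,
    LogRankResult,
    RocCurve,
    SurvivalCurve,
    auc_mann_whitney,
    cox_fit,
    km_estimate,
    logrank_test,
    pearson_r,
)

logger = logging.getLogger("roscore")

__all__ = [
    "GroupComparison",
    "CorrelationBlock",
    "RocBlock",
    "EvaluationReport",
    "compare_groups",
    "multivariable_cox",
    "score_survival_correlation",
    "roc_comparison",
    "subgroup_analysis",
    "evaluate",
    "AGSR_COVARIATES",
]

AGSR_COVARIATES = ("age", "grade", "stage", "residual")


def _merge(scores: ScoreTable, clinical: ClinicalTable) -> pd.DataFrame:
    shared = [s for s in scores.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise ValueError("score table and clinical table share no samples")
    df = scores.frame.loc[shared].join(clinical.frame.loc[shared], how="inner")
    return df


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """KM + log-rank + univariate Cox for the high-vs-low split."""

    curves: dict[str, SurvivalCurve]
    medians: dict[str, float | None]
    logrank: LogRankResult
    cox: CoxFit
    n: dict[str, int]

    @property
    def hr_high_vs_low(self) -> float:
        return float(self.cox.hr[0])

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "medians": self.medians,
            "logrank": self.logrank.to_dict(),
            "cox": self.cox.to_dict(),
            "hr_high_vs_low": self.hr_high_vs_low,
            "curves": {g: c.to_dict() for g, c in self.curves.items()},
        }


def compare_groups(scores: ScoreTable, clinical: ClinicalTable) -> GroupComparison:
    """KM curves/medians per score group, log-rank test, and HR(high vs low)."""
    df = _merge(scores, clinical)
    if "group" not in df.columns:
        raise ValueError("scores carry no group labels; run assign_groups first")
    for label in (GROUP_LOW, GROUP_HIGH):
        if (df["group"] == label).sum() == 0:
            raise ValueError(
                f"the {label!r} score group is empty; review the score threshold or panel size K"
            )
    t = df["os_years"].to_numpy(float)
    e = df["os_event"].to_numpy(int)
    high = (df["group"] == GROUP_HIGH).to_numpy()
    curves = {
        GROUP_LOW: km_estimate(t[~high], e[~high]),
        GROUP_HIGH: km_estimate(t[high], e[high]),
    }
    lr = logrank_test(t, e, df["group"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cox = cox_fit(t, e, high.astype(float), names=["score_high_vs_low"])
    return GroupComparison(
        curves=curves,
        medians={g: c.median for g, c in curves.items()},
        logrank=lr,
        cox=cox,
        n={GROUP_LOW: int((~high).sum()), GROUP_HIGH: int(high.sum())},
    )


# ---------------------------------------------------------------------------
# Multivariable Cox
# ---------------------------------------------------------------------------


def _design_matrix(
    df: pd.DataFrame,
    score_form: str,
    covariates,
    age_coding: str,
    stage_coding: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Expanded design matrix; returns (columns frame, dropped-term notes)."""
    cols = {}
    notes = []
    if score_form == "continuous":
        cols["score"] = df["score"].astype(float)
    elif score_form == "categorical":
        cols["score_high_vs_low"] = (df["group"] == GROUP_HIGH).astype(float)
    elif score_form is not None:
        raise ValueError(f"score_form must be 'continuous', 'categorical' or None")

    for cov in covariates:
        if cov == "age":
            if "age" not in df.columns:
                notes.append("age: column absent, dropped")
                continue
            if age_coding == "continuous":
                cols["age"] = df["age"].astype(float)
            elif age_coding == "binary60":
                cols["age_ge_60"] = (df["age"] >= 60).astype(float).where(df["age"].notna())
            else:
                raise ValueError(f"unknown age_coding {age_coding!r}")
        elif cov == "grade":
            if "grade" not in df.columns:
                notes.append("grade: column absent, dropped")
                continue
            for level in ("2", "3", "other"):
                cols[f"grade_{level}_vs_1"] = (df["grade"] == level).astype(float).where(
                    df["grade"].notna()
                )
        elif cov == "stage":
            if "stage" not in df.columns:
                notes.append("stage: column absent, dropped")
                continue
            if stage_coding == "dummy_ref_early":
                # reference = stage I-II pooled
                for level in ("III", "IV"):
                    cols[f"stage_{level}_vs_I-II"] = (df["stage"] == level).astype(float).where(
                        df["stage"].notna()
                    )
            elif stage_coding == "binary_iv_vs_iii":
                mask = df["stage"].isin(("III", "IV"))
                cols["stage_IV_vs_III"] = (df["stage"] == "IV").astype(float).where(mask)
            else:
                raise ValueError(f"unknown stage_coding {stage_coding!r}")
        elif cov == "residual":
            if "residual" not in df.columns:
                notes.append("residual: column absent, dropped")
                continue
            cols["residual_suboptimal"] = (df["residual"] == "suboptimal").astype(float).where(
                df["residual"].notna()
            )
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=df.index), notes


def multivariable_cox(
    scores: ScoreTable,
    clinical: ClinicalTable,
    score_form: str = "continuous",
    covariates=AGSR_COVARIATES,
    age_coding: str = "continuous",
    stage_coding: str = "dummy_ref_early",
    ties: str = "efron",
) -> CoxFit:
    """Cox model over the score plus clinical covariates, complete cases.

    The score enters either as integer points (``continuous``) or as the
    high-vs-low indicator (``categorical``). Categorical covariates are
    expanded against a reference level (stage I-II pooled, grade 1);
    ``stage_coding="binary_iv_vs_iii"`` restricts to stage III/IV and
    fits a single IV-vs-III contrast. Covariates with a single observed
    level on the complete cases are dropped with a warning.
    """
    df = _merge(scores, clinical)
    X, notes = _design_matrix(df, score_form, covariates, age_coding, stage_coding)
    if X.shape[1] == 0:
        raise ValueError("no usable model terms")
    keep = X.notna().all(axis=1)
    dfc, Xc = df.loc[keep], X.loc[keep]
    n, p = Xc.shape
    if n < 10 * p:
        logger.warning(
            "multivariable Cox: only %d complete cases for %d parameters (< 10 per parameter)",
            n,
            p,
        )
    dropped = [c for c in Xc.columns if Xc[c].nunique() < 2]
    for c in dropped:
        msg = f"covariate {c!r} has a single observed level on complete cases; dropped"
        notes.append(msg)
        logger.warning("multivariable Cox: %s", msg)
    Xc = Xc.drop(columns=dropped)
    if Xc.shape[1] == 0:
        raise ValueError("all model terms degenerate on the complete cases")
    fit = cox_fit(
        dfc["os_years"].to_numpy(float),
        dfc["os_event"].to_numpy(int),
        Xc.to_numpy(float),
        names=list(Xc.columns),
        ties=ties,
    )
    fit.warnings.extend(notes)
    return fit


# ---------------------------------------------------------------------------
# Score vs median-OS correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationBlock:
    """Pearson correlation of score value vs per-score-bin KM median OS."""

    pairs: list[tuple[int, float]]
    r: float
    p: float
    excluded: list[dict] = field(default_factory=list)
    min_bin_size: int = 3

    def to_dict(self) -> dict:
        return {
            "pairs": [{"score": s, "median_os": m} for s, m in self.pairs],
            "r": self.r,
            "p": self.p,
            "excluded": self.excluded,
            "min_bin_size": self.min_bin_size,
        }


def score_survival_correlation(
    scores: ScoreTable,
    clinical: ClinicalTable,
    min_bin_size: int = 3,
) -> CorrelationBlock:
    """Correlate each observed score value with its bin's KM median OS.

    Bins with fewer than ``min_bin_size`` patients, or whose KM curve
    never reaches 0.5 (median undefined), are excluded and listed.
    """
    df = _merge(scores, clinical)
    pairs: list[tuple[int, float]] = []
    excluded: list[dict] = []
    for value, bin_df in df.groupby("score"):
        value = int(value)
        if len(bin_df) < min_bin_size:
            excluded.append(
                {"score": value, "n": len(bin_df), "reason": f"fewer than {min_bin_size} patients"}
            )
            continue
        curve = km_estimate(bin_df["os_years"].to_numpy(float), bin_df["os_event"].to_numpy(int))
        if curve.median is None:
            excluded.append(
                {"score": value, "n": len(bin_df), "reason": "KM median undefined (curve stays above 0.5)"}
            )
            continue
        pairs.append((value, curve.median))
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} score bin(s) with an estimable median OS; need >= 3"
        )
    r, p = pearson_r([s for s, _ in pairs], [m for _, m in pairs])
    return CorrelationBlock(pairs=pairs, r=r, p=p, excluded=excluded, min_bin_size=min_bin_size)


# ---------------------------------------------------------------------------
# Survival-threshold ROC comparison
# ---------------------------------------------------------------------------


@dataclass
class RocBlock:
    """AUCs of covariates-only, score-only, and covariates+score models."""

    median_os: float
    roc_covariates: RocCurve | None
    roc_score: RocCurve
    roc_combined: RocCurve | None
    n_included: int
    n_excluded: int
    excluded_samples: list[str]
    covariates: tuple

    def to_dict(self) -> dict:
        return {
            "median_os": self.median_os,
            "auc_covariates": self.roc_covariates.auc if self.roc_covariates else None,
            "auc_score": self.roc_score.auc,
            "auc_combined": self.roc_combined.auc if self.roc_combined else None,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "covariates": list(self.covariates),
        }


def _lp_auc(df: pd.DataFrame, X: pd.DataFrame, label: np.ndarray) -> RocCurve | None:
    keep = X.notna().all(axis=1)
    Xc = X.loc[keep]
    Xc = Xc.loc[:, [c for c in Xc.columns if Xc[c].nunique() > 1]]
    if Xc.shape[1] == 0:
        return None
    dfc = df.loc[keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = cox_fit(
                dfc["os_years"].to_numpy(float),
                dfc["os_event"].to_numpy(int),
                Xc.to_numpy(float),
                names=list(Xc.columns),
            )
        except (ConstantCovariateError, ValueError) as err:
            logger.warning("ROC model %s failed: %s", list(Xc.columns), err)
            return None
    lp = Xc.to_numpy(float) @ fit.coef  # higher = higher hazard = short survival
    return auc_mann_whitney(lp, label[keep.to_numpy()], positive_class="short_survival")


def roc_comparison(
    scores: ScoreTable,
    clinical: ClinicalTable,
    covariates=AGSR_COVARIATES,
    age_coding: str = "continuous",
    stage_coding: str = "dummy_ref_early",
) -> RocBlock:
    """Three-model ROC comparison against the cohort's median-OS threshold.

    Outcome: long survival = os_time >= cohort KM median OS (event flag
    irrelevant — follow-up already exceeds the threshold); short survival
    = death observed before the median. Censored before the median ->
    excluded. Models are fitted on the included subset; risk score is the
    Cox linear predictor; positive class = short survival.
    """
    df = _merge(scores, clinical)
    cohort_curve = km_estimate(df["os_years"].to_numpy(float), df["os_event"].to_numpy(int))
    med = cohort_curve.median
    if med is None:
        raise ValueError("cohort KM median OS undefined; ROC outcome cannot be binarized")
    t = df["os_years"].to_numpy(float)
    e = df["os_event"].to_numpy(int)
    long_ = t >= med
    short = (t < med) & (e == 1)
    excluded_mask = (t < med) & (e == 0)
    included = df.loc[~excluded_mask]
    label = short[~excluded_mask].astype(int)  # 1 = short survival
    if label.sum() == 0 or label.sum() == label.size:
        raise ValueError("a survival class was emptied by the median-OS exclusions")
    assert int(excluded_mask.sum()) + len(included) == len(df)

    Xc, _ = _design_matrix(included, None, covariates, age_coding, stage_coding)
    Xs = pd.DataFrame({"score": included["score"].astype(float)}, index=included.index)
    Xb = pd.concat([Xs, Xc], axis=1)

    label_arr = np.asarray(label)
    block = RocBlock(
        median_os=med,
        roc_covariates=_lp_auc(included, Xc, label_arr),
        roc_score=_lp_auc(included, Xs, label_arr),
        roc_combined=_lp_auc(included, Xb, label_arr),
        n_included=len(included),
        n_excluded=int(excluded_mask.sum()),
        excluded_samples=list(df.index[excluded_mask]),
        covariates=tuple(covariates),
    )
    if block.roc_score is None:
        raise ValueError("score-only ROC model failed (constant score?)")
    return block


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------


def subgroup_analysis(
    scores: ScoreTable,
    clinical: ClinicalTable,
    stratum_column: str,
) -> dict[str, GroupComparison | dict]:
    """Run :func:`compare_groups` within each level of a stratum column.

    Strata failing preconditions (an empty score group, no events, ...)
    are reported as ``{"skipped": reason}`` instead of aborting the run.
    """
    if stratum_column not in clinical.frame.columns:
        raise ValueError(f"stratum column {stratum_column!r} not in clinical table")
    results: dict[str, GroupComparison | dict] = {}
    for level, sub in clinical.frame.groupby(stratum_column, dropna=True):
        sub_clin = ClinicalTable(sub.copy())
        shared = [s for s in scores.sample_ids if s in set(sub_clin.sample_ids)]
        sub_scores = ScoreTable(
            frame=scores.frame.loc[shared].copy(),
            K=scores.K,
            reference_medians=scores.reference_medians,
            missing_genes=scores.missing_genes,
        )
        try:
            results[str(level)] = compare_groups(sub_scores, sub_clin)
        except ValueError as err:
            logger.info("subgroup %r skipped: %s", level, err)
            results[str(level)] = {"skipped": str(err)}
    return results


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    groups: GroupComparison
    cox_categorical: CoxFit | None
    cox_continuous: CoxFit | None
    correlation: CorrelationBlock | None
    roc: RocBlock | None
    subgroups: dict[str, dict]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "groups": self.groups.to_dict(),
            "cox_categorical": self.cox_categorical.to_dict() if self.cox_categorical else None,
            "cox_continuous": self.cox_continuous.to_dict() if self.cox_continuous else None,
            "correlation": self.correlation.to_dict() if self.correlation else None,
            "roc": self.roc.to_dict() if self.roc else None,
            "subgroups": self.subgroups,
            "notes": self.notes,
        }


def evaluate(
    scores: ScoreTable,
    clinical: ClinicalTable,
    covariates=AGSR_COVARIATES,
    stratum_columns=(),
    min_bin_size: int = 3,
    age_coding: str = "continuous",
    stage_coding: str = "dummy_ref_early",
) -> EvaluationReport:
    """Run the full evaluation battery, degrading gracefully per block.

    The group comparison is mandatory; the multivariable, correlation and
    ROC blocks are attempted and recorded as None (with a note) when their
    preconditions fail on this cohort.
    """
    notes: list[str] = []
    groups = compare_groups(scores, clinical)

    def attempt(name, fn):
        try:
            return fn()
        except (ValueError, ConstantCovariateError) as err:
            notes.append(f"{name} skipped: {err}")
            logger.warning("evaluation: %s skipped: %s", name, err)
            return None

    cox_cat = attempt(
        "multivariable (categorical score)",
        lambda: multivariable_cox(
            scores, clinical, "categorical", covariates, age_coding, stage_coding
        ),
    )
    cox_cont = attempt(
        "multivariable (continuous score)",
        lambda: multivariable_cox(
            scores, clinical, "continuous", covariates, age_coding, stage_coding
        ),
    )
    corr = attempt(
        "score-median-OS correlation",
        lambda: score_survival_correlation(scores, clinical, min_bin_size),
    )
    roc = attempt(
        "ROC comparison",
        lambda: roc_comparison(scores, clinical, covariates, age_coding, stage_coding),
    )
    subgroups: dict[str, dict] = {}
    for col in stratum_columns:
        res = attempt(f"subgroup analysis on {col!r}", lambda c=col: subgroup_analysis(scores, clinical, c))
        if res is not None:
            subgroups[col] = {
                level: (block.to_dict() if isinstance(block, GroupComparison) else block)
                for level, block in res.items()
            }
    return EvaluationReport(
        groups=groups,
        cox_categorical=cox_cat,
        cox_continuous=cox_cont,
        correlation=corr,
        roc=roc,
        subgroups=subgroups,
        notes=notes,
    )
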