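"""Orchestration of the two study shapes the package targets.

``run_experiment1`` reproduces the shape of a two-group test-environment
comparison on a single timepoint: subject-level nonparametric outcomes
(mean absolute localisation error), semi-parametric retrieval/precision
relative to a pooled-fit guessing threshold, group-level mixture fits with
bootstrap confidence intervals, a subject-label permutation test on the
group-level parameters, and Bayes-factor-accompanied subject-level group
tests.

``run_change_analysis`` reproduces the core of a two-timepoint change
study: per-subject memory outcomes at T1 and T2, z-scored against the T1
reference sample, difference scores (T1 - T2, positive = decline),
typical-vs-pandemic lifestyle comparisons, and lifestyle-change x
memory-change correlations with Bayes factors, overall and within
dementia-risk subgroups (family history; median split on the depression
score) under a Bonferroni-adjusted alpha.

Data-hygiene rules shared by both: subject-level outcomes more than a
configurable number of SDs (default 3) from the group mean are excluded,
non-iteratively and per outcome independently; every input subject is
accounted for in either the results or the exclusion log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import jzs_ttest_bf, pearson_bf, rank_tests
from .io import trials_to_samples
from .mixture import ErrorSample, FAST_FIT, FitConfig, fit_mixture_mle
from .permutation import PermutationResult, permutation_group_test
from .semiparametric import guessing_threshold, semiparametric_estimates

__all__ = [
    "AnalysisConfig",
    "Experiment1Report",
    "ChangeReport",
    "exclude_outliers",
    "zscore_by_reference",
    "run_experiment1",
    "run_change_analysis",
]


@dataclass(frozen=True)
class AnalysisConfig:
    method: str = "mle"  # "mle" or "semiparametric" for subject-level outcomes
    outlier_sd: float = 3.0
    permutation_B: int = 1000
    bootstrap_n: int = 1000
    min_trials: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")
        if self.permutation_B < 100:
            raise ValueError("permutation_B must be >= 100")
        if self.method not in ("mle", "semiparametric"):
            raise ValueError(f"unknown method {self.method!r}")


def exclude_outliers(values, multiplier: float = 3.0) -> tuple[np.ndarray, list[str]]:
    """Mask of values within ``multiplier`` SDs of the mean, plus a log.

    Computed once from the full sample (non-iterative).  A zero-SD sample
    excludes nothing and warns.  Returns (inclusion mask, log lines).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values to screen for outliers")
    mean = float(np.nanmean(v))
    sd = float(np.nanstd(v, ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance; no outliers excluded", RuntimeWarning, stacklevel=2)
        return np.ones(v.size, dtype=bool), []
    z = np.abs(v - mean) / sd
    include = (z <= multiplier) | np.isnan(v)
    log = [
        f"index {i}: value {v[i]:.4g} is {z[i]:.2f} SD from the mean (> {multiplier})"
        for i in np.flatnonzero(~include)
    ]
    return include, log


def zscore_by_reference(values, reference) -> np.ndarray:
    """Standardise ``values`` by the mean and SD of a reference sample."""
    ref = np.asarray(reference, dtype=float)
    ref = ref[np.isfinite(ref)]
    sd = float(np.std(ref, ddof=1))
    if sd == 0.0:
        raise ValueError("reference sample has zero standard deviation")
    return (np.asarray(values, dtype=float) - float(np.mean(ref))) / sd


def _group_test(x: np.ndarray, y: np.ndarray) -> dict:
    """Mann-Whitney + t statistic + JZS Bayes factor for two groups."""
    mw = rank_tests(x, y, "mann-whitney")
    t, p_t = stats.ttest_ind(x, y, equal_var=True)
    bf = jzs_ttest_bf(float(t), len(x), len(y))
    return dict(
        n1=len(x), n2=len(y), U=mw.statistic, p_mannwhitney=mw.p_value,
        t=float(t), p_ttest=float(p_t), bf10=bf.bf10, bf01=bf.bf01,
    )


@dataclass(frozen=True)
class Experiment1Report:
    subject_table: pd.DataFrame  # per subject: MAE, semiparametric estimates
    group_table: pd.DataFrame  # group-level parameter estimates + bootstrap CIs
    group_tests: pd.DataFrame  # subject-level group comparisons with BFs
    permutation: PermutationResult
    cutoff_deg: float
    exclusion_log: list[str] = field(default_factory=list)


def _bootstrap_group_ci(
    samples: list[ErrorSample], n_boot: int, rng: np.random.Generator
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap over subjects for pooled-fit group parameters."""
    boots = {"p_t": np.empty(n_boot), "kappa": np.empty(n_boot)}
    arrays = [s.errors for s in samples]
    n = len(arrays)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        pooled = ErrorSample(np.concatenate([arrays[i] for i in idx]))
        fit = fit_mixture_mle(pooled, FAST_FIT)
        boots["p_t"][b] = fit.params.p_t
        boots["kappa"][b] = fit.params.kappa
    return {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in boots.items()
    }


def run_experiment1(trials: pd.DataFrame, config: AnalysisConfig | None = None) -> Experiment1Report:
    """Two-group comparison of memory outcomes from a trial-level table.

    ``trials`` needs subject_id, group and error_deg columns (see
    ``memfid.io.read_trials``).  The guessing threshold for the
    semi-parametric subject-level estimates comes from a single mixture fit
    pooled over all trials, so every subject is scored against the same
    cutoff regardless of group.
    """
    cfg = config or AnalysisConfig()
    if "group" not in trials.columns:
        raise ValueError("trial table must have a group column")
    samples = trials_to_samples(trials, label_col="group")
    groups = sorted({s.label for s in samples})
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups!r}")
    rng = np.random.default_rng(cfg.seed)
    fit_cfg = FitConfig(min_trials=cfg.min_trials)

    pooled_fit = fit_mixture_mle(
        ErrorSample(np.concatenate([s.errors for s in samples])), fit_cfg
    )
    cutoff = guessing_threshold(pooled_fit.params)

    subj_rows = []
    for s in samples:
        est = semiparametric_estimates(s, cutoff)
        subj_rows.append(
            dict(
                subject_id=s.subject, group=s.label, n_trials=s.n_trials,
                mean_abs_error=float(np.mean(np.abs(s.errors))),
                retrieval=est.retrieval, precision=est.precision,
            )
        )
    subject_table = pd.DataFrame(subj_rows)

    # outlier screening per outcome, within the full sample
    exclusion_log: list[str] = []
    for col in ("mean_abs_error", "retrieval", "precision"):
        mask, log = exclude_outliers(subject_table[col].to_numpy(), cfg.outlier_sd)
        subject_table[f"{col}_included"] = mask
        exclusion_log += [f"{col}: subject {subject_table.subject_id[i]} excluded ({msg})"
                          for i, msg in zip(np.flatnonzero(~mask), log)]

    perm = permutation_group_test(samples, B=cfg.permutation_B, seed=cfg.seed)

    group_rows = []
    for g, fit in zip(perm.groups, perm.group_fits):
        gs = [s for s in samples if s.label == g]
        ci = _bootstrap_group_ci(gs, cfg.bootstrap_n, rng)
        group_rows.append(
            dict(group=g, n_subjects=len(gs), p_t=fit.params.p_t,
                 p_t_ci_low=ci["p_t"][0], p_t_ci_high=ci["p_t"][1],
                 kappa=fit.params.kappa,
                 kappa_ci_low=ci["kappa"][0], kappa_ci_high=ci["kappa"][1],
                 perm_p_p_t=perm.p_value["p_t"], perm_p_kappa=perm.p_value["kappa"],
                 perm_z_p_t=perm.z_score["p_t"], perm_z_kappa=perm.z_score["kappa"])
        )
    group_table = pd.DataFrame(group_rows)

    test_rows = []
    for col in ("mean_abs_error", "retrieval", "precision"):
        keep = subject_table[f"{col}_included"] & subject_table[col].notna()
        sub = subject_table[keep]
        x = sub.loc[sub.group == groups[0], col].to_numpy()
        y = sub.loc[sub.group == groups[1], col].to_numpy()
        test_rows.append(dict(outcome=col, **_group_test(x, y)))
    group_tests = pd.DataFrame(test_rows)

    return Experiment1Report(
        subject_table=subject_table,
        group_table=group_table,
        group_tests=group_tests,
        permutation=perm,
        cutoff_deg=cutoff,
        exclusion_log=exclusion_log,
    )


@dataclass(frozen=True)
class ChangeReport:
    outcome_table: pd.DataFrame  # per subject: T1/T2 outcomes, z-scores, changes
    lifestyle_tests: pd.DataFrame  # typical vs pandemic paired comparisons
    correlations: pd.DataFrame  # lifestyle change x memory change, incl. subgroups
    exclusion_log: list[str]
    subgroup_alpha: float


def _subject_outcomes(
    trials: pd.DataFrame, cfg: AnalysisConfig
) -> pd.DataFrame:
    """Per subject x timepoint retrieval and precision estimates."""
    fit_cfg = FitConfig(min_trials=cfg.min_trials)
    samples = trials_to_samples(trials, label_col="timepoint")
    rows = []
    if cfg.method == "semiparametric":
        pooled = fit_mixture_mle(
            ErrorSample(np.concatenate([s.errors for s in samples])), fit_cfg
        )
        cutoff = guessing_threshold(pooled.params)
        for s in samples:
            est = semiparametric_estimates(s, cutoff)
            rows.append(dict(subject_id=s.subject, timepoint=s.label,
                             retrieval=est.retrieval, precision=est.precision,
                             converged=True))
    else:
        for s in samples:
            fit = fit_mixture_mle(s, fit_cfg)
            rows.append(dict(subject_id=s.subject, timepoint=s.label,
                             retrieval=fit.params.p_t, precision=fit.params.kappa,
                             converged=fit.converged))
    return pd.DataFrame(rows)


def run_change_analysis(
    cohort: pd.DataFrame, trials: pd.DataFrame, config: AnalysisConfig | None = None
) -> ChangeReport:
    """Two-timepoint change analysis with lifestyle correlations.

    Memory outcomes are estimated per subject and timepoint (method per
    config), z-scored against the full T1 sample, and differenced as
    T1 - T2 (positive = decline).  Subjects missing either timepoint, or
    with a non-converged fit, are dropped with a log entry; outliers are
    excluded per outcome.  Lifestyle change (typical - pandemic) is then
    correlated with each memory-change score, overall and within
    family-history and median-split-depression subgroups, with stretched-
    beta Bayes factors; the subgroup alpha is Bonferroni-corrected for the
    number of subgroup tests per outcome.
    """
    cfg = config or AnalysisConfig()
    exclusion_log: list[str] = []

    outcomes = _subject_outcomes(trials, cfg)
    bad_fit = outcomes[~outcomes.converged]
    for _, row in bad_fit.iterrows():
        exclusion_log.append(f"{row.subject_id} {row.timepoint}: model fit failed to converge")
    outcomes = outcomes[outcomes.converged]

    wide = outcomes.pivot(index="subject_id", columns="timepoint",
                          values=["retrieval", "precision"])
    complete = wide.dropna()
    for sid in wide.index.difference(complete.index):
        exclusion_log.append(f"{sid}: missing a timepoint, dropped from change analysis")
    wide = complete

    # z-score each outcome at both timepoints against the full T1 sample
    table = pd.DataFrame(index=wide.index)
    for outcome in ("retrieval", "precision"):
        ref = wide[(outcome, "T1")].to_numpy()
        for tp in ("T1", "T2"):
            table[f"{outcome}_{tp}"] = wide[(outcome, tp)].to_numpy()
            table[f"{outcome}_{tp}_z"] = zscore_by_reference(
                wide[(outcome, tp)].to_numpy(), ref
            )
        table[f"{outcome}_change"] = (
            table[f"{outcome}_T1_z"] - table[f"{outcome}_T2_z"]
        )
        mask, log = exclude_outliers(table[f"{outcome}_change"].to_numpy(), cfg.outlier_sd)
        table[f"{outcome}_included"] = mask
        exclusion_log += [
            f"{outcome}: subject {table.index[i]} excluded ({msg})"
            for i, msg in zip(np.flatnonzero(~mask), log)
        ]

    subj_info = (
        cohort.drop_duplicates("subject_id")
        .set_index("subject_id")[
            [c for c in ("family_history", "depression", "lifestyle_typical",
                         "lifestyle_pandemic") if c in cohort.columns]
        ]
    )
    table = table.join(subj_info, how="left")
    table["lifestyle_change"] = table["lifestyle_typical"] - table["lifestyle_pandemic"]

    # typical vs pandemic lifestyle: paired t, Wilcoxon, JZS BF
    typ = table["lifestyle_typical"].to_numpy(dtype=float)
    pan = table["lifestyle_pandemic"].to_numpy(dtype=float)
    t_stat, p_t = stats.ttest_rel(typ, pan)
    wil = rank_tests(typ, pan, "wilcoxon-signed-rank")
    bf = jzs_ttest_bf(float(t_stat), len(typ))
    lifestyle_tests = pd.DataFrame(
        [dict(comparison="typical_vs_pandemic", n=len(typ),
              mean_typical=float(np.mean(typ)), sd_typical=float(np.std(typ, ddof=1)),
              mean_pandemic=float(np.mean(pan)), sd_pandemic=float(np.std(pan, ddof=1)),
              t=float(t_stat), p_ttest=float(p_t),
              W=wil.statistic, p_wilcoxon=wil.p_value,
              bf10=bf.bf10, bf01=bf.bf01,
              r_typical_pandemic=float(np.corrcoef(typ, pan)[0, 1]))]
    )

    # correlations: overall + subgroups, per memory outcome
    med_dep = float(table["depression"].median()) if "depression" in table else np.nan
    subgroups: list[tuple[str, pd.Series]] = [("all", pd.Series(True, index=table.index))]
    if "family_history" in table:
        subgroups += [
            ("family_history_yes", table["family_history"].astype(bool)),
            ("family_history_no", ~table["family_history"].astype(bool)),
        ]
    if "depression" in table:
        subgroups += [
            ("depression_above_median", table["depression"] > med_dep),
            ("depression_at_or_below_median", table["depression"] <= med_dep),
        ]
    n_subgroup_tests = max(len(subgroups) - 1, 1)
    subgroup_alpha = 0.05 / n_subgroup_tests

    corr_rows = []
    for outcome in ("retrieval", "precision"):
        for name, sel in subgroups:
            sub = table[sel & table[f"{outcome}_included"]]
            sub = sub.dropna(subset=[f"{outcome}_change", "lifestyle_change"])
            n = len(sub)
            if n < 4:
                corr_rows.append(dict(outcome=outcome, subgroup=name, n=n,
                                      r=np.nan, p=np.nan, bf10=np.nan, bf01=np.nan))
                continue
            r, p = stats.pearsonr(sub["lifestyle_change"], sub[f"{outcome}_change"])
            if abs(r) < 1.0:
                b = pearson_bf(float(r), n)
                bf10, bf01 = b.bf10, b.bf01
            else:
                bf10 = bf01 = np.nan
            corr_rows.append(dict(outcome=outcome, subgroup=name, n=n, df=n - 2,
                                  r=float(r), p=float(p), bf10=bf10, bf01=bf01))
    correlations = pd.DataFrame(corr_rows)

    return ChangeReport(
        outcome_table=table.reset_index(),
        lifestyle_tests=lifestyle_tests,
        correlations=correlations,
        exclusion_log=exclusion_log,
        subgroup_alpha=subgroup_alpha,
    )
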