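"""Synthetic data emulating a two-timepoint continuous-report memory study.

No raw data from the motivating study design are available, so every stage
of the pipeline is exercised on simulated data with known ground truth:

* ``generate_displays`` — task displays: scenes each showing a few objects
  at circular positions with a minimum pairwise separation (to prevent
  overlap on screen), each object paired with a perceptually similar lure
  for the mnemonic-discrimination question.
* ``generate_group_samples`` — trial-level response errors for a two-group,
  one-timepoint design (e.g. in-person vs online testing), with per-subject
  retrieval/precision heterogeneity.
* ``generate_cohort`` — an older-adult cohort tested at two timepoints
  (T1 pre-pandemic in person, T2 online during lockdown), with per-subject
  true mixture parameters, lifestyle sum scores for "typical" life and the
  pandemic period (strongly correlated, with a mean decline), and
  covariates (age, gender, family history of dementia, depression,
  follow-up interval).
* ``generate_lifestyle_items`` — item-level Likert (0-5 frequency)
  responses behind those sum scores, with configurable per-item pandemic
  shifts concentrated on social, event-based and vigorous physical
  activities.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import wrap_angle
from .mixture import ErrorSample, MixtureParams, simulate_errors

__all__ = [
    "Display",
    "DisplaySet",
    "CohortConfig",
    "ItemConfig",
    "DEFAULT_ITEMS",
    "generate_displays",
    "generate_group_samples",
    "generate_cohort",
    "generate_lifestyle_items",
]


# ---------------------------------------------------------------------------
# Task displays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Display:
    scene_id: int
    target_ids: tuple[int, ...]
    lure_ids: tuple[int, ...]
    positions_deg: tuple[float, ...]  # circular positions in [0, 360)


@dataclass(frozen=True)
class DisplaySet:
    displays: tuple[Display, ...]
    n_scenes: int
    objects_per_display: int
    min_separation_deg: float
    seed: int | None

    @property
    def n_objects(self) -> int:
        """Total distinct objects across all target/lure pairs."""
        return 2 * self.n_scenes * self.objects_per_display


def _min_circular_gap(positions: np.ndarray) -> float:
    order = np.sort(positions)
    gaps = np.diff(np.concatenate([order, [order[0] + 360.0]]))
    return float(gaps.min())


def generate_displays(
    n_scenes: int = 29,
    objects_per_display: int = 3,
    min_separation_deg: float = 62.04,
    seed: int | None = None,
    max_attempts: int = 10_000,
) -> DisplaySet:
    """Randomly place objects on each scene with a minimum angular separation.

    Positions are continuous in [0, 360) and rejection-sampled until all
    pairwise circular separations within a display reach
    ``min_separation_deg``.  Infeasible configurations (where the
    separations cannot fit on the circle) are refused up front; feasible
    but hard configurations fail loudly after ``max_attempts`` rejections.

    The defaults produce 29 displays of 3 objects — 87 target objects, 174
    objects in total once each target's lure is counted.
    """
    if n_scenes < 1 or objects_per_display < 1:
        raise ValueError("need at least one scene and one object per display")
    if objects_per_display > 1 and objects_per_display * min_separation_deg >= 360.0:
        raise ValueError(
            f"{objects_per_display} objects with {min_separation_deg} deg separation "
            "cannot fit on the circle"
        )
    rng = np.random.default_rng(seed)
    displays = []
    next_obj = 0
    for scene in range(n_scenes):
        for _ in range(max_attempts):
            pos = rng.uniform(0.0, 360.0, size=objects_per_display)
            if objects_per_display == 1 or _min_circular_gap(pos) >= min_separation_deg:
                break
        else:
            raise RuntimeError(
                f"could not satisfy the separation constraint in {max_attempts} attempts"
            )
        targets = tuple(range(next_obj, next_obj + objects_per_display))
        lures = tuple(t + n_scenes * objects_per_display for t in targets)
        next_obj += objects_per_display
        displays.append(
            Display(scene_id=scene, target_ids=targets, lure_ids=lures,
                    positions_deg=tuple(float(p) for p in pos))
        )
    return DisplaySet(
        displays=tuple(displays),
        n_scenes=n_scenes,
        objects_per_display=objects_per_display,
        min_separation_deg=min_separation_deg,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Two-group trial-level samples (test-environment comparison)
# ---------------------------------------------------------------------------

def generate_group_samples(
    n_subjects_per_group: int,
    trials_per_subject: int,
    group_params: dict[str, MixtureParams],
    between_subject_sd: tuple[float, float] = (0.6, 0.30),
    seed: int | None = None,
) -> list[ErrorSample]:
    """Per-subject error samples for a multi-group design.

    Each subject's true parameters scatter around their group's values:
    logit(p_t) gets Normal(0, sd_logit) noise and log(kappa) gets
    Normal(0, sd_log) noise, ``between_subject_sd = (sd_logit, sd_log)``.
    Pass ``(0, 0)`` for homogeneous subjects.
    """
    if n_subjects_per_group < 1 or trials_per_subject < 1:
        raise ValueError("need at least one subject and one trial")
    rng = np.random.default_rng(seed)
    sd_logit, sd_log = between_subject_sd
    samples: list[ErrorSample] = []
    for label, params in group_params.items():
        base_logit = np.log(params.p_t / (1 - params.p_t)) if 0 < params.p_t < 1 else None
        for i in range(n_subjects_per_group):
            if base_logit is None:
                p = params.p_t
            else:
                p = 1.0 / (1.0 + np.exp(-(base_logit + rng.normal(0, sd_logit))))
            k = params.kappa * np.exp(rng.normal(0, sd_log)) if params.kappa > 0 else 0.0
            subj = simulate_errors(
                MixtureParams(float(p), float(k)),
                trials_per_subject,
                seed=rng,
                subject=f"{label}_{i:03d}",
                label=label,
            )
            samples.append(subj)
    return samples


# ---------------------------------------------------------------------------
# Two-timepoint cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Population and effect structure of the simulated cohort.

    Defaults emulate an older-adult sample of 59 followed up online after a
    mean 2.8 years: retrieval success averaging ~0.70 with subject SD
    ~0.15 (logit-normal), concentration averaging ~14 (log-normal),
    lifestyle sum scores with typical mean 33.4 (SD 7.4) dropping to 28.9
    (SD 7.5) during the pandemic at correlation 0.86, and demographic
    covariates matching the cohort's published summary statistics.  The
    default lifestyle->memory effect is zero (the null the study reported);
    set ``lifestyle_memory_effect`` to a nonzero slope (change in logit
    retrieval / log concentration per SD of lifestyle decline) to simulate
    an effect.
    """

    n_subjects: int = 59
    trials_per_subject: int = 75
    # population of true parameters at T1
    pt_logit_mean: float = 0.90
    pt_logit_sd: float = 0.80
    kappa_log_mean: float = float(np.log(14.0))
    kappa_log_sd: float = 0.35
    # T1 -> T2 change in true parameters
    memory_change_mean: float = 0.0  # mean shift on the logit/log scales
    memory_change_sd: float = 0.30  # subject-level noise in the shift
    lifestyle_memory_effect: float = 0.0
    # lifestyle sum scores
    lifestyle_typical_mean: float = 33.37
    lifestyle_typical_sd: float = 7.39
    lifestyle_pandemic_mean: float = 28.90
    lifestyle_pandemic_sd: float = 7.53
    lifestyle_corr: float = 0.86
    lifestyle_max: int = 85  # 17 items x 5
    # covariates
    age_mean: float = 72.98
    age_sd: float = 5.78
    age_min: float = 60.0
    p_female: float = 39 / 59
    p_family_history: float = 18 / 59
    depression_mean: float = 7.14
    depression_sd: float = 4.21
    depression_max: int = 30
    followup_years_mean: float = 2.76
    followup_years_sd: float = 0.95
    # attrition: probability that a subject is missing at T2
    attrition: float = 0.0
    # slope of attrition log-odds on T1 retrieval z-score (0 = MCAR)
    attrition_performance_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("need at least one subject and one trial")
        if not (0 <= self.attrition < 1):
            raise ValueError("attrition must be in [0, 1)")
        if not (-1 < self.lifestyle_corr < 1):
            raise ValueError("lifestyle correlation must be in (-1, 1)")
        for name in ("pt_logit_sd", "kappa_log_sd", "lifestyle_typical_sd",
                     "lifestyle_pandemic_sd", "age_sd", "depression_sd",
                     "followup_years_sd", "memory_change_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the cohort table and its trial-level responses.

    Returns ``(cohort, trials)``.  ``cohort`` has one row per subject and
    timepoint (T1/T2) carrying the true mixture parameters, lifestyle
    scores and covariates; ``trials`` has one row per trial with target and
    response angles (degrees) plus the signed error.  Subjects lost to
    attrition have no T2 rows.  The same (config, seed) pair reproduces
    both tables exactly.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_subjects

    # lifestyle sum scores: bivariate normal, rounded and clipped to range
    cov = cfg.lifestyle_corr * cfg.lifestyle_typical_sd * cfg.lifestyle_pandemic_sd
    scores = rng.multivariate_normal(
        [cfg.lifestyle_typical_mean, cfg.lifestyle_pandemic_mean],
        [[cfg.lifestyle_typical_sd**2, cov], [cov, cfg.lifestyle_pandemic_sd**2]],
        size=n,
    )
    scores = np.clip(np.round(scores), 0, cfg.lifestyle_max).astype(int)
    lifestyle_typical, lifestyle_pandemic = scores[:, 0], scores[:, 1]
    lifestyle_change = lifestyle_typical - lifestyle_pandemic
    ls_z = (lifestyle_change - lifestyle_change.mean()) / (lifestyle_change.std() or 1.0)

    # covariates
    age = np.maximum(rng.normal(cfg.age_mean, cfg.age_sd, n), cfg.age_min)
    gender = np.where(rng.random(n) < cfg.p_female, "F", "M")
    family_history = rng.random(n) < cfg.p_family_history
    depression = np.clip(
        np.round(rng.normal(cfg.depression_mean, cfg.depression_sd, n)), 0, cfg.depression_max
    ).astype(int)
    followup = np.maximum(rng.normal(cfg.followup_years_mean, cfg.followup_years_sd, n), 0.25)

    # true parameters at T1 and their T2 shift
    logit_pt_t1 = rng.normal(cfg.pt_logit_mean, cfg.pt_logit_sd, n)
    log_k_t1 = rng.normal(cfg.kappa_log_mean, cfg.kappa_log_sd, n)
    shift = (
        cfg.memory_change_mean
        - cfg.lifestyle_memory_effect * ls_z
        + rng.normal(0.0, cfg.memory_change_sd, n)
    )
    logit_pt_t2 = logit_pt_t1 + shift
    log_k_t2 = log_k_t1 + shift

    pt_t1, pt_t2 = _logistic(logit_pt_t1), _logistic(logit_pt_t2)
    k_t1, k_t2 = np.exp(log_k_t1), np.exp(log_k_t2)

    # attrition (optionally performance-dependent)
    z_pt = (logit_pt_t1 - logit_pt_t1.mean()) / (logit_pt_t1.std() or 1.0)
    if cfg.attrition > 0:
        base = np.log(cfg.attrition / (1 - cfg.attrition))
        p_drop = _logistic(base - cfg.attrition_performance_slope * z_pt)
        dropped = rng.random(n) < p_drop
    else:
        dropped = np.zeros(n, dtype=bool)

    cohort_rows, trial_rows = [], []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        for tp, pt, kk in (("T1", pt_t1[i], k_t1[i]), ("T2", pt_t2[i], k_t2[i])):
            if tp == "T2" and dropped[i]:
                continue
            cohort_rows.append(
                dict(
                    subject_id=sid, timepoint=tp, group="older_adults",
                    age=round(float(age[i] + (followup[i] if tp == "T2" else 0.0)), 2),
                    gender=gender[i], family_history=bool(family_history[i]),
                    depression=int(depression[i]),
                    lifestyle_typical=int(lifestyle_typical[i]),
                    lifestyle_pandemic=int(lifestyle_pandemic[i]),
                    followup_years=round(float(followup[i]), 2),
                    true_pt=float(pt), true_kappa=float(kk),
                )
            )
            errs = simulate_errors(
                MixtureParams(float(pt), float(kk)), cfg.trials_per_subject, seed=rng
            )
            targets = rng.uniform(0.0, 360.0, cfg.trials_per_subject)
            responses = np.mod(targets + errs.errors, 360.0)
            for t, (tg, rs, er) in enumerate(zip(targets, responses, errs.errors)):
                trial_rows.append(
                    dict(subject_id=sid, timepoint=tp, group="older_adults", trial=t,
                         target_deg=float(tg), response_deg=float(rs), error_deg=float(er))
                )
    return pd.DataFrame(cohort_rows), pd.DataFrame(trial_rows)


# ---------------------------------------------------------------------------
# Item-level lifestyle responses
# ---------------------------------------------------------------------------

#: Default activity items: name, typical-phase mean response (0-5 frequency
#: scale), and mean pandemic reduction.  Reductions are concentrated on
#: social activities, events requiring leaving home, vigorous physical
#: activity and volunteering; home-based cognitive activities are spared.
DEFAULT_ITEMS: tuple[tuple[str, float, float], ...] = (
    ("socialising_family", 2.6, 0.9),
    ("socialising_friends", 2.4, 1.15),
    ("attending_events", 1.8, 1.2),
    ("mild_physical_activity", 3.0, 0.3),
    ("moderate_physical_activity", 2.2, 0.5),
    ("vigorous_physical_activity", 1.3, 0.8),
    ("reading", 3.4, 0.0),
    ("musical_instrument", 0.7, 0.15),
    ("artistic_pastime", 1.0, 0.2),
    ("second_language", 0.6, 0.05),
    ("cooking", 2.9, 0.0),
    ("gardening", 2.1, 0.1),
    ("games_puzzles", 2.3, 0.0),
    ("volunteering", 1.4, 1.0),
    ("religious_activities", 1.1, 0.65),
    ("documentaries", 2.7, -0.2),
    ("writing", 1.2, 0.0),
)


@dataclass(frozen=True)
class ItemConfig:
    """Item definitions for the Likert generator.

    ``items`` is a sequence of (name, typical mean, pandemic shift); the
    shift is subtracted from the typical latent response before rounding
    and clipping, so positive shifts mean reduced pandemic engagement.
    ``engagement_loading`` scales a shared per-subject engagement trait
    (inducing correlation between items and between phases);
    ``item_noise_sd`` and ``pandemic_noise_sd`` are the phase-specific
    latent noise levels.
    """

    items: tuple[tuple[str, float, float], ...] = DEFAULT_ITEMS
    engagement_loading: float = 0.42
    item_noise_sd: float = 0.85
    pandemic_noise_sd: float = 0.95
    scale_max: int = 5

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("need at least one item")
        if self.scale_max < 1:
            raise ValueError("scale_max must be >= 1")


def generate_lifestyle_items(
    n_subjects: int,
    config: ItemConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Item-level Likert responses for both phases, long format.

    Returns a DataFrame with columns (subject_id, item_id, phase, response),
    phase in {"typical", "pandemic"}, responses integers in
    [0, scale_max].  Pandemic responses are generated from the subject's
    typical latent response minus the item's configured shift plus noise,
    so the two phases are strongly positively correlated at the sum-score
    level while declining on the shifted items.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    cfg = config or ItemConfig()
    rng = np.random.default_rng(seed)
    engagement = rng.normal(0.0, 1.0, n_subjects)
    rows = []
    for s in range(n_subjects):
        sid = f"S{s + 1:03d}"
        for name, mean, shift in cfg.items:
            latent_typ = mean + cfg.engagement_loading * engagement[s] + rng.normal(
                0.0, cfg.item_noise_sd
            )
            typ = int(np.clip(np.round(latent_typ), 0, cfg.scale_max))
            latent_pan = latent_typ - shift + rng.normal(0.0, cfg.pandemic_noise_sd)
            pan = int(np.clip(np.round(latent_pan), 0, cfg.scale_max))
            rows.append(dict(subject_id=sid, item_id=name, phase="typical", response=typ))
            rows.append(dict(subject_id=sid, item_id=name, phase="pandemic", response=pan))
    return pd.DataFrame(rows)
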