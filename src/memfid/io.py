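"""CSV readers and writers for trial-level and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .circular import wrap_error, wrap_angle
from .mixture import ErrorSample, FitResult
from .semiparametric import SemiparametricEstimate

__all__ = [
    "read_trials",
    "trials_to_samples",
    "fit_results_to_frame",
    "semiparametric_to_frame",
    "write_json",
]

_TRIAL_KEYS = ["subject_id"]


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-level CSV and attach a signed ``error_deg`` column.

    Requires ``subject_id`` plus either ``error_deg`` or both
    ``target_deg`` and ``response_deg`` (errors are then computed by
    wrapping response - target into (-180, 180]).  ``group`` and
    ``timepoint`` columns are carried through when present.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("trial table must have a subject_id column")
    if "error_deg" in df.columns:
        df["error_deg"] = wrap_angle(df["error_deg"].to_numpy(dtype=float))
    elif {"target_deg", "response_deg"} <= set(df.columns):
        df["error_deg"] = wrap_error(
            df["target_deg"].to_numpy(dtype=float), df["response_deg"].to_numpy(dtype=float)
        )
    else:
        raise ValueError("need either error_deg or target_deg + response_deg columns")
    return df


def trials_to_samples(trials: pd.DataFrame, label_col: str = "group") -> list[ErrorSample]:
    """Group a trial table into one ErrorSample per subject (x label)."""
    if "error_deg" not in trials.columns:
        raise ValueError("trial table has no error_deg column; use read_trials")
    keys = ["subject_id"] + ([label_col] if label_col in trials.columns else [])
    samples = []
    for key, sub in trials.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        samples.append(
            ErrorSample(
                errors=sub["error_deg"].to_numpy(dtype=float),
                subject=str(key[0]),
                label=str(key[1]) if len(key) > 1 else "",
            )
        )
    return samples


def fit_results_to_frame(results: dict[str, FitResult]) -> pd.DataFrame:
    rows = [
        dict(
            subject_id=sid,
            method=r.method,
            p_t=r.params.p_t,
            kappa=r.params.kappa,
            loglik=r.loglik,
            converged=r.converged,
            n_trials=r.n_trials,
        )
        for sid, r in results.items()
    ]
    return pd.DataFrame(rows)


def semiparametric_to_frame(estimates: list[SemiparametricEstimate]) -> pd.DataFrame:
    rows = [
        dict(
            subject_id=e.subject,
            label=e.label,
            method=e.method,
            cutoff_deg=e.cutoff,
            retrieval=e.retrieval,
            precision=e.precision,
            n_within=e.n_within,
            n_trials=e.n_trials,
        )
        for e in estimates
    ]
    return pd.DataFrame(rows)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
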