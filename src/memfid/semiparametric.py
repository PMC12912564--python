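"""Semi-parametric retrieval/precision estimates via a guessing threshold.

When subject-level mixture fits are unreliable (too few trials, failed
convergence), a more robust route is: fit the mixture once to group-level
data, derive from that fit the absolute error magnitude beyond which a
response is more likely a guess than a noisy retrieval (the *guessing
threshold*), then summarise each subject by

* retrieval: the proportion of that subject's responses within the threshold;
* precision: minus one times the standard deviation of the within-threshold
  errors (sign-flipped so that higher values mean greater precision).

The threshold is the |error| at which the posterior responsibility of the
target component equals 0.5, i.e. where the two mixture component densities
are equal:  p_t f_vM(theta; kappa) = (1 - p_t)/360.  Solving gives

    cos(theta_c) = ln( (1 - p_t)/p_t * I0(kappa) ) / kappa .

If the von Mises component dominates everywhere the threshold is 180 deg
(no response is ever classified as a guess).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .mixture import ErrorSample, MixtureParams

__all__ = ["SemiparametricEstimate", "guessing_threshold", "semiparametric_estimates"]


@dataclass(frozen=True)
class SemiparametricEstimate:
    cutoff: float  # degrees, magnitude of the guessing threshold
    retrieval: float  # proportion of responses within the cutoff, in [0, 1]
    precision: float  # -1 * SD of within-cutoff errors (degrees); NaN if undefined
    n_within: int
    n_trials: int
    subject: str = ""
    label: str = ""
    method: str = "semiparametric"


def guessing_threshold(group_params: MixtureParams) -> float:
    """Guessing threshold (degrees) implied by a group-level mixture fit.

    Raises for degenerate fits (no target component, or a flat one).
    Returns 180 when the target component dominates at every angle and 0
    when the uniform component does (no response would be kept).
    """
    p, k = group_params.p_t, group_params.kappa
    if p == 0.0:
        raise ValueError("p_t = 0: no target component, threshold undefined")
    if k == 0.0:
        raise ValueError("kappa = 0: target component is flat, threshold undefined")
    if p >= 1.0:
        return 180.0
    # ln I0(k) via the scaled Bessel function to avoid overflow
    log_i0 = math.log(special.i0e(k)) + k
    cos_c = (math.log((1.0 - p) / p) + log_i0) / k
    if cos_c <= -1.0:
        return 180.0
    if cos_c >= 1.0:
        warnings.warn(
            "uniform component dominates everywhere; threshold is 0", RuntimeWarning, stacklevel=2
        )
        return 0.0
    return float(math.degrees(math.acos(cos_c)))


def semiparametric_estimates(
    sample: ErrorSample, cutoff: float, ddof: int = 1
) -> SemiparametricEstimate:
    """Subject-level retrieval and precision relative to a guessing threshold.

    ``ddof=1`` (sample SD) is the default for the within-cutoff spread;
    pass ``ddof=0`` for the population SD.  With no within-cutoff
    responses, retrieval is 0 and precision is NaN (missing).
    """
    if sample.n_trials == 0:
        raise ValueError("cannot estimate from an empty sample")
    if not (0.0 < cutoff <= 180.0):
        raise ValueError(f"cutoff must be in (0, 180], got {cutoff!r}")
    errors = sample.errors
    within = np.abs(errors) <= cutoff
    n_within = int(within.sum())
    retrieval = n_within / sample.n_trials
    if n_within > ddof:
        precision = -float(np.std(errors[within], ddof=ddof))
    else:
        precision = float("nan")
    return SemiparametricEstimate(
        cutoff=float(cutoff),
        retrieval=retrieval,
        precision=precision,
        n_within=n_within,
        n_trials=sample.n_trials,
        subject=sample.subject,
        label=sample.label,
    )
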