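"""Angle conventions and the circular-SD / concentration conversion.

All public interfaces take and return **degrees**; computation happens in
radians internally.  Signed response errors live in the half-open interval
(-180, 180], with the boundary assigned to +180 by convention.

The circular standard deviation of a von Mises distribution with
concentration kappa is

    SD(kappa) = sqrt(-2 ln R(kappa)),   R(kappa) = I1(kappa) / I0(kappa),

where I0, I1 are modified Bessel functions of the first kind.  ``sd_to_k``
inverts this relation numerically (the mapping is a strictly decreasing
bijection), matching the behaviour of the ``sd2k`` utility familiar from
working-memory toolboxes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special
from scipy.optimize import brentq

__all__ = [
    "KAPPA_MAX",
    "wrap_angle",
    "wrap_error",
    "bessel_ratio",
    "k_to_sd",
    "sd_to_k",
]

#: Concentrations are capped here; exponentially-scaled Bessel functions keep
#: the ratio I1/I0 finite well beyond this, but SD(700) is already < 2.2 deg.
KAPPA_MAX = 700.0

#: Below this the distribution is numerically indistinguishable from uniform.
_KAPPA_FLOOR = 1e-6


def wrap_angle(angle_deg):
    """Wrap arbitrary angles (degrees) into the signed interval (-180, 180].

    Accepts scalars or arrays.  +180 and -180 both map to +180.
    """
    a = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    wrapped = np.mod(a, 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # mod() of exactly -180 gives 180, which is already the chosen convention
    if np.isscalar(angle_deg):
        return float(wrapped)
    return wrapped


def wrap_error(target_deg, response_deg):
    """Signed angular deviation response - target, wrapped into (-180, 180].

    This is the trial-level response error of a continuous-report task:
    0 means a perfect reproduction, +/-180 the maximal possible error.
    """
    t = np.asarray(target_deg, dtype=float)
    r = np.asarray(response_deg, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("target and response angles must be finite")
    return wrap_angle(r - t)


def bessel_ratio(kappa):
    """R(kappa) = I1(kappa)/I0(kappa), computed with scaled Bessel functions."""
    return special.i1e(kappa) / special.i0e(kappa)


def k_to_sd(kappa: float) -> float:
    """Circular standard deviation (degrees) of a von Mises with given kappa.

    Strictly decreasing: kappa -> infinity gives SD -> 0, kappa -> 0 gives
    SD -> infinity (the uniform limit).
    """
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError(f"kappa must be positive and finite, got {kappa!r}")
    r = bessel_ratio(kappa)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def sd_to_k(sd_deg: float) -> float:
    """Concentration kappa whose circular SD (degrees) equals ``sd_deg``.

    Solved by bracketed root-finding to relative tolerance 1e-10; exact
    inversion rather than the small-/large-kappa series approximations.
    Returns 0.0 (with a warning) when the requested SD is so large that the
    concentration falls below the numeric floor.
    """
    if not np.isfinite(sd_deg) or sd_deg <= 0:
        raise ValueError(f"sd must be positive and finite, got {sd_deg!r}")
    if sd_deg >= k_to_sd(_KAPPA_FLOOR):
        warnings.warn(
            f"sd={sd_deg:.3g} deg implies kappa below {_KAPPA_FLOOR}; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    if sd_deg <= k_to_sd(KAPPA_MAX):
        return KAPPA_MAX
    return float(
        brentq(lambda k: k_to_sd(k) - sd_deg, _KAPPA_FLOOR, KAPPA_MAX, xtol=1e-12, rtol=1e-12)
    )
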