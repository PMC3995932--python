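"""Extended logistic model equations and parameter algebra.

Seasonal N uptake and biomass yield both follow logistic curves in applied N
with a shared rate parameter c:

    N_u(N) = A_N / (1 + exp(b_N - c N))        (uptake, kg ha^-1)
    Y(N)   = A   / (1 + exp(b   - c N))        (biomass, Mg ha^-1)

Eliminating N couples them through the hyperbolic phase relation
``Y = Y_m N_u / (k_N + N_u)``, and the ratio N_u/Y gives the N concentration
curve, rising from a lower limit N_cl at zero uptake to a maximum N_cm.  The
functions below evaluate the curves and convert between the logistic
parameterization (A, A_N, b, b_N, c) and the phase/concentration one
(Y_m, k_N, N_cm, N_cl), which are linked by Delta_b = b_N - b:

    N_cm = A_N / A                 N_cl = N_cm exp(-Delta_b)
    Y_m  = A / (1 - exp(-Delta_b)) k_N  = A_N / (exp(Delta_b) - 1)

With A in Mg ha^-1 and A_N in kg ha^-1, concentrations land directly in
g kg^-1.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Tuple, Union

import numpy as np
from scipy.special import expit

from .params import (
    GRAIN,
    DerivedParams,
    LogisticParams,
    PhaseParams,
    SiteParams,
)

__all__ = [
    "logistic_response",
    "phase_biomass",
    "n_concentration_vs_N",
    "n_concentration_vs_Nu",
    "derive_secondary",
    "n_half",
    "harvest_index",
    "delta_b_of",
    "max_concentration",
    "lower_concentration",
    "potential_biomass",
    "potential_biomass_from_phase",
    "uptake_response_k",
    "logistic_from_phase",
]

ArrayLike = Union[float, np.ndarray]


def logistic_response(N: ArrayLike, p: LogisticParams) -> ArrayLike:
    """Evaluate the logistic dose response ``A / (1 + exp(b - c N))``.

    Strictly increasing in N, approaching A as N grows; accepts scalars or
    arrays of applied N (kg ha^-1).
    """
    N = np.asarray(N, dtype=float)
    out = p.A * expit(p.c * N - p.b)
    return float(out) if out.ndim == 0 else out


def phase_biomass(Nu: ArrayLike, q: PhaseParams) -> ArrayLike:
    """Biomass from N uptake on the hyperbolic phase curve
    ``Y = Y_m Nu / (k_N + Nu)``."""
    Nu = np.asarray(Nu, dtype=float)
    denom = q.k_N + Nu
    if np.any(denom == 0):
        raise ZeroDivisionError("phase relation undefined where k_N + Nu = 0")
    out = q.Y_m * Nu / denom
    return float(out) if out.ndim == 0 else out


def n_concentration_vs_N(N: ArrayLike, sp: SiteParams, fraction: str = GRAIN) -> ArrayLike:
    """N concentration (g kg^-1) versus applied N.

    The ratio of the uptake and biomass logistics:
    ``N_c = N_cm (1 + exp(b - cN)) / (1 + exp(b_N - cN))`` — monotone
    increasing toward N_cm when Delta_b > 0.
    """
    N = np.asarray(N, dtype=float)
    n_cm = max_concentration(sp.amplitude(fraction, "n_uptake"),
                             sp.amplitude(fraction, "biomass"))
    # expit form keeps both exponentials overflow-safe for large |b - cN|
    out = n_cm * expit(sp.c * N - sp.b_N) / expit(sp.c * N - sp.b)
    return float(out) if out.ndim == 0 else out


def n_concentration_vs_Nu(Nu: ArrayLike, q: PhaseParams,
                          A_N: Optional[float] = None) -> ArrayLike:
    """N concentration versus N uptake: the line ``N_c = (k_N + Nu)/Y_m``.

    Slope 1/Y_m, intercept k_N/Y_m (= N_cl).  The phase segment is only
    meaningful for Nu in [0, A_N]; if ``A_N`` is supplied, values outside
    that range trigger an extrapolation warning but are still computed.
    """
    Nu = np.asarray(Nu, dtype=float)
    if A_N is not None and (np.any(Nu < 0) or np.any(Nu > A_N)):
        warnings.warn(
            "N uptake outside the phase segment [0, A_N]; extrapolating the "
            "concentration line",
            stacklevel=2,
        )
    out = (q.k_N + Nu) / q.Y_m
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# parameter algebra


def delta_b_of(b: float, b_N: float) -> float:
    """Shift difference Delta_b = b_N - b (dimensionless)."""
    return b_N - b


def max_concentration(A_N: float, A: float) -> float:
    """Maximum N concentration N_cm = A_N/A, in g kg^-1 when A_N is kg ha^-1
    and A is Mg ha^-1."""
    if A <= 0:
        raise ValueError("A must be positive")
    return A_N / A


def lower_concentration(N_cm: float, delta_b: float) -> float:
    """Lower-limit N concentration N_cl = N_cm exp(-Delta_b)."""
    return N_cm * math.exp(-delta_b)


def potential_biomass(A: float, delta_b: float) -> float:
    """Maximum potential biomass Y_m = A / (1 - exp(-Delta_b)); requires
    Delta_b > 0."""
    if delta_b <= 0:
        raise ValueError("Y_m undefined for delta_b <= 0")
    return A / (1.0 - math.exp(-delta_b))


def potential_biomass_from_phase(A: float, A_N: float, k_N: float) -> float:
    """Invert the phase identity A = Y_m A_N/(k_N + A_N) for Y_m."""
    if A_N <= 0:
        raise ValueError("A_N must be positive")
    return A * (k_N + A_N) / A_N


def uptake_response_k(A_N: float, delta_b: float) -> float:
    """Phase response parameter k_N = A_N / (exp(Delta_b) - 1); requires
    Delta_b > 0."""
    if delta_b <= 0:
        raise ValueError("k_N undefined for delta_b <= 0")
    return A_N / math.expm1(delta_b)


def logistic_from_phase(Y_m: float, k_N: float, A_N: float, b_N: float) -> Tuple[float, float]:
    """Recover the biomass logistic (A, b) from phase and uptake parameters:
    ``A = Y_m A_N/(k_N + A_N)`` and ``b = b_N - ln(1 + A_N/k_N)``."""
    if k_N <= 0:
        raise ValueError("k_N must be positive")
    A = Y_m * A_N / (k_N + A_N)
    b = b_N - math.log1p(A_N / k_N)
    return A, b


def derive_secondary(sp: SiteParams, fraction: str = GRAIN) -> DerivedParams:
    """All secondary quantities for one site x fraction.

    Delta_b, N_cm, N_cl, N_half and the yield at N_half are always defined;
    the phase parameters Y_m and k_N require Delta_b > 0 and are reported as
    ``None`` otherwise (the hyperbolic phase relation needs a positive k_N).
    """
    A = sp.amplitude(fraction, "biomass")
    A_N = sp.amplitude(fraction, "n_uptake")
    db = sp.delta_b
    n_cm = max_concentration(A_N, A)
    n_cl = lower_concentration(n_cm, db)
    nh, y_nh = n_half(sp, fraction)
    if db > 0:
        y_m: Optional[float] = potential_biomass(A, db)
        k_n: Optional[float] = uptake_response_k(A_N, db)
    else:
        y_m = k_n = None
    return DerivedParams(
        delta_b=db, N_cm=n_cm, N_cl=n_cl, N_half=nh, Y_at_N_half=y_nh,
        Y_m=y_m, k_N=k_n,
    )


def n_half(sp: SiteParams, fraction: str = GRAIN) -> Tuple[float, float]:
    """Applied N at peak uptake efficiency and the biomass there.

    ``N_0.5 = b_N / c`` is the inflection (half-maximum) of the uptake
    logistic — the rate maximizing N removed per unit N applied.  The yield
    at that rate is ``Y(N_0.5) = A / (1 + exp(-Delta_b))``, on the upper
    part of the biomass curve whenever Delta_b > 0.
    """
    n05 = sp.b_N / sp.c
    y = sp.amplitude(fraction, "biomass") / (1.0 + math.exp(-sp.delta_b))
    return n05, y


def harvest_index(sp: SiteParams) -> float:
    """Grain-to-total biomass ratio A_g/A_t.

    Because b and c are shared between fractions, the ratio of the grain and
    total logistic curves is independent of applied N.
    """
    return sp.A_g / sp.A_t
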