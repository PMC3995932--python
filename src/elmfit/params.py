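"""Parameter containers for the extended logistic model (ELM).

The canonical parameterization of one site is ``(A_g, A_t, A_Ng, A_Nt, b,
b_N, c)``: relative maxima for grain/total biomass (Mg ha^-1) and grain/total
N uptake (kg ha^-1), the two dimensionless shifting parameters and the common
applied-N response parameter c (ha kg^-1).  Phase-plane and concentration
parameters (Y_m, k_N, N_cm, N_cl, ...) are always *derived* from these, never
stored independently, so a parameter set can never be internally inconsistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

__all__ = [
    "GRAIN",
    "TOTAL",
    "FRACTIONS",
    "LogisticParams",
    "PhaseParams",
    "DerivedParams",
    "SiteParams",
]

GRAIN = "grain"
TOTAL = "total"
FRACTIONS = (GRAIN, TOTAL)


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class LogisticParams:
    """One logistic dose-response curve ``y(N) = A / (1 + exp(b - c*N))``.

    A is the relative maximum (Mg ha^-1 for biomass, kg ha^-1 for N uptake),
    b the dimensionless shifting parameter (unrestricted in sign) and c the
    applied-N response parameter in ha kg^-1.
    """

    A: float
    b: float
    c: float

    def __post_init__(self) -> None:
        _require_finite(A=self.A, b=self.b, c=self.c)
        if self.A <= 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")


@dataclass(frozen=True)
class PhaseParams:
    """Hyperbolic biomass-versus-uptake phase curve ``Y = Y_m*Nu/(k_N+Nu)``.

    Y_m is the maximum potential biomass (Mg ha^-1) and k_N the N uptake
    response parameter (kg ha^-1); both must be positive.
    """

    Y_m: float
    k_N: float

    def __post_init__(self) -> None:
        _require_finite(Y_m=self.Y_m, k_N=self.k_N)
        if self.Y_m <= 0:
            raise ValueError(f"Y_m must be positive, got {self.Y_m}")
        if self.k_N <= 0:
            raise ValueError(f"k_N must be positive, got {self.k_N}")


@dataclass(frozen=True)
class DerivedParams:
    """Secondary ELM quantities for one site x plant fraction.

    delta_b   difference b_N - b (dimensionless)
    N_cm      maximum N concentration A_N/A (g kg^-1)
    N_cl      lower-limit N concentration N_cm*exp(-delta_b) (g kg^-1)
    N_half    applied N at peak uptake efficiency, b_N/c (kg ha^-1)
    Y_at_N_half  biomass at N_half, A/(1+exp(-delta_b)) (Mg ha^-1)
    Y_m, k_N  phase parameters; ``None`` when delta_b <= 0 (the hyperbolic
              phase relation is then undefined).
    """

    delta_b: float
    N_cm: float
    N_cl: float
    N_half: float
    Y_at_N_half: float
    Y_m: Optional[float] = None
    k_N: Optional[float] = None

    @property
    def phase(self) -> Optional[PhaseParams]:
        if self.Y_m is None or self.k_N is None:
            return None
        return PhaseParams(Y_m=self.Y_m, k_N=self.k_N)


@dataclass(frozen=True)
class SiteParams:
    """Full seven-parameter ELM description of one site.

    b, b_N and c are shared between the grain and total-plant fractions
    (constant harvest index); only the four maxima differ by fraction.
    """

    site_id: str
    A_g: float
    A_t: float
    A_Ng: float
    A_Nt: float
    b: float
    b_N: float
    c: float

    def __post_init__(self) -> None:
        _require_finite(
            A_g=self.A_g, A_t=self.A_t, A_Ng=self.A_Ng, A_Nt=self.A_Nt,
            b=self.b, b_N=self.b_N, c=self.c,
        )
        for name in ("A_g", "A_t", "A_Ng", "A_Nt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")

    @property
    def delta_b(self) -> float:
        return self.b_N - self.b

    def amplitude(self, fraction: str, response: str) -> float:
        """Relative maximum for a fraction ('grain'|'total') and response
        ('biomass'|'n_uptake')."""
        _check_fraction(fraction)
        if response == "biomass":
            return self.A_g if fraction == GRAIN else self.A_t
        if response == "n_uptake":
            return self.A_Ng if fraction == GRAIN else self.A_Nt
        raise ValueError(f"unknown response {response!r}")

    def logistic(self, fraction: str, response: str) -> LogisticParams:
        """Logistic curve parameters for one fraction x response."""
        shift = self.b if response == "biomass" else self.b_N
        return LogisticParams(A=self.amplitude(fraction, response), b=shift, c=self.c)

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "grain": {"A": self.A_g, "A_N": self.A_Ng},
            "total": {"A": self.A_t, "A_N": self.A_Nt},
            "b": self.b,
            "b_N": self.b_N,
            "c": self.c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SiteParams":
        try:
            return cls(
                site_id=str(d["site_id"]),
                A_g=float(d["grain"]["A"]),
                A_t=float(d["total"]["A"]),
                A_Ng=float(d["grain"]["A_N"]),
                A_Nt=float(d["total"]["A_N"]),
                b=float(d["b"]),
                b_N=float(d["b_N"]),
                c=float(d["c"]),
            )
        except KeyError as exc:
            raise ValueError(f"site parameter dict missing key {exc}") from exc

    def flat_dict(self) -> dict:
        return asdict(self)


def _check_fraction(fraction: str) -> None:
    if fraction not in FRACTIONS:
        raise ValueError(f"fraction must be one of {FRACTIONS}, got {fraction!r}")
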