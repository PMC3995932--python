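"""Synthetic multi-site N-rate trial data from known ELM parameters.

Emulates the design of the North Carolina corn N-rate study the model was
developed against: three sites (Dothan, Goldsboro and Portsmouth soils),
grain and total-plant fractions, seasonal biomass and N removal measured at
applied-N rates 0/56/112/168/224 kg ha^-1, each reported value the average
of four year-observations.  Year-to-year variation is modelled as
multiplicative Gaussian noise around the model curve (additive available),
truncated so a single year can never go negative; block-level structure of
the original randomized-complete-block layout is not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import RESPONSES, ResponseSeries
from .model import logistic_response
from .params import FRACTIONS, SiteParams

__all__ = [
    "DEFAULT_N_RATES",
    "TrialDesign",
    "TruthSet",
    "generate",
    "fixture_kamprath_params",
    "constrain_truth",
]

DEFAULT_N_RATES = (0.0, 56.0, 112.0, 168.0, 224.0)


@dataclass(frozen=True)
class TrialDesign:
    """Layout and error model of one simulated trial.

    noise_cv is the coefficient of variation of the multiplicative noise on
    each year-observation; reported values average ``n_years`` of them, so
    their effective CV is about ``noise_cv/sqrt(n_years)``.
    """

    site_ids: Optional[Tuple[str, ...]] = None  # default: the truth's sites
    n_rates: Tuple[float, ...] = DEFAULT_N_RATES
    n_years: int = 4
    noise_cv: float = 0.02
    noise_model: str = "multiplicative"
    truncation: float = -0.9
    seed: int = 0

    def __post_init__(self) -> None:
        rates = np.asarray(self.n_rates, dtype=float)
        if rates.ndim != 1 or len(rates) < 4:
            raise ValueError("n_rates must list at least four applied-N levels")
        if rates[0] < 0 or np.any(np.diff(rates) <= 0):
            raise ValueError("n_rates must be nonnegative and strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.noise_model not in ("multiplicative", "additive"):
            raise ValueError("noise_model must be 'multiplicative' or 'additive'")


@dataclass(frozen=True)
class TruthSet:
    """Known site parameters a simulation is generated from.

    ``mode_structure`` records which sharing constraints the truth satisfies
    ("I": none imposed, "II": common Delta_b, "III": common Delta_b and
    N_cm) so null and alternative scenarios are explicit.
    """

    sites: Tuple[SiteParams, ...]
    mode_structure: str = "I"

    def by_id(self) -> Dict[str, SiteParams]:
        return {sp.site_id: sp for sp in self.sites}

    def to_dict(self) -> dict:
        return {
            "mode_structure": self.mode_structure,
            "sites": [sp.to_dict() for sp in self.sites],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSet":
        return cls(
            sites=tuple(SiteParams.from_dict(s) for s in d["sites"]),
            mode_structure=str(d.get("mode_structure", "I")),
        )


def fixture_kamprath_params() -> TruthSet:
    """The published per-site parameter estimates for the three-soil corn
    study (Dothan, Goldsboro, Portsmouth), verbatim.

    Per-site Delta_b and N_cm values differ slightly between sites (rounding
    of the printed estimates); use :func:`constrain_truth` for truths that
    satisfy a sharing structure exactly.
    """
    return TruthSet(
        sites=(
            SiteParams("Dothan", A_g=11.5, A_t=21.5, A_Ng=161.0, A_Nt=198.0,
                       b=0.319, b_N=0.978, c=0.0161),
            SiteParams("Goldsboro", A_g=7.76, A_t=14.4, A_Ng=108.0, A_Nt=132.0,
                       b=0.282, b_N=0.941, c=0.0209),
            SiteParams("Portsmouth", A_g=9.50, A_t=16.7, A_Ng=133.0, A_Nt=154.0,
                       b=-0.105, b_N=0.555, c=0.0111),
        ),
        mode_structure="I",
    )


def constrain_truth(
    truth: TruthSet,
    delta_b: Optional[float] = 0.660,
    N_cm_g: Optional[float] = None,
    N_cm_t: Optional[float] = None,
) -> TruthSet:
    """Project a truth set onto a sharing structure.

    With only ``delta_b`` given, every site's b_N is reset to b + delta_b
    (a common-Delta_b, Mode II truth).  Supplying ``N_cm_g``/``N_cm_t`` as
    well also resets A_g = A_Ng/N_cm_g and A_t = A_Nt/N_cm_t (a Mode III
    truth).  The defaults for the invariants published for the corn study
    are delta_b = 0.660, N_cm_g = 14.0, N_cm_t = 9.18 g kg^-1.
    """
    sites = []
    for sp in truth.sites:
        kw: Dict[str, float] = {}
        if delta_b is not None:
            kw["b_N"] = sp.b + delta_b
        if N_cm_g is not None:
            kw["A_g"] = sp.A_Ng / N_cm_g
        if N_cm_t is not None:
            kw["A_t"] = sp.A_Nt / N_cm_t
        sites.append(replace(sp, **kw))
    mode = "III" if (N_cm_g is not None and N_cm_t is not None) else ("II" if delta_b is not None else truth.mode_structure)
    return TruthSet(sites=tuple(sites), mode_structure=mode)


def generate(design: TrialDesign, truth: TruthSet,
             rng: Optional[np.random.Generator] = None) -> Tuple[List[ResponseSeries], TruthSet]:
    """Simulate one trial: reported series of N-rate means plus the truth echo.

    For every site x fraction, the uptake mean curve comes from the uptake
    logistic and the biomass mean curve from the biomass logistic of the
    truth's canonical parameters.  Each year-observation perturbs the mean
    (multiplicative: ``mean*(1+eps)`` with ``eps ~ N(0, noise_cv)`` clipped
    below at ``truncation``; additive: ``mean + eps*series_mean_level``) and
    the reported value is the average over ``n_years``.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    by_id = truth.by_id()
    site_ids = design.site_ids if design.site_ids is not None else tuple(by_id)
    unknown = [s for s in site_ids if s not in by_id]
    if unknown:
        raise ValueError(f"design references sites absent from the truth set: {unknown}")

    rates = np.asarray(design.n_rates, dtype=float)
    out: List[ResponseSeries] = []
    for site in site_ids:
        sp = by_id[site]
        for fraction in FRACTIONS:
            for response in RESPONSES:
                mean = logistic_response(rates, sp.logistic(fraction, response))
                if design.noise_cv == 0:
                    reported = mean.copy()
                else:
                    eps = rng.normal(0.0, design.noise_cv, size=(design.n_years, len(rates)))
                    eps = np.maximum(eps, design.truncation)
                    if design.noise_model == "multiplicative":
                        years = mean[None, :] * (1.0 + eps)
                    else:
                        years = mean[None, :] + eps * float(np.mean(mean))
                    reported = np.maximum(years, 0.0).mean(axis=0)
                out.append(ResponseSeries(
                    site_id=site, fraction=fraction, response=response,
                    n_applied=rates.copy(), values=reported,
                ))
    return out, truth
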