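"""Joint normalized nonlinear least-squares estimation of ELM parameters.

All twelve dose-response series of a multi-site trial (site x {grain, total}
x {biomass, N uptake}) are fitted *simultaneously* by minimizing a
dimensionless objective: each residual is divided by a per-series scale
(the series mean by default), so that biomass in Mg ha^-1 and N uptake in
kg ha^-1 — an order of magnitude apart — contribute comparably.

Three nested parameter-sharing configurations ("Modes") are supported for
``n`` sites:

    Mode I    7n parameters: per site (A_g, A_t, A_Ng, A_Nt, b, b_N, c)
    Mode II   6n+1: per site (A_g, A_t, A_Ng, A_Nt, b, c) plus one common
              Delta_b, with b_N = b + Delta_b
    Mode III  4n+3: per site (A_Ng, A_Nt, b, c) plus common (Delta_b,
              N_cm_grain, N_cm_total), with A = A_N / N_cm

The optimizer is Gauss-Newton on the normal equations with an analytic
Jacobian, a step-halving line search, a Levenberg ridge fallback for
ill-conditioned steps, and projection onto a parameter box.  Starting values
and the box come from a shared-slope linearization of each logistic
(``init_params``).

The public surface follows the statsmodels convention: build an
:class:`ExtendedLogisticModel` from data, call :meth:`~ExtendedLogisticModel.fit`,
and inspect the returned :class:`ELMResults` (``summary()``,
``compare_f_test()``, ``derived()``, ``plot_fit()``).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import RESPONSES, ResponseSeries, group_series, require_complete, site_order
from .model import logistic_response
from .params import FRACTIONS, GRAIN, TOTAL, LogisticParams, SiteParams

__all__ = [
    "MODES",
    "ModeSpec",
    "count_parameters",
    "normalized_sse",
    "init_params",
    "LinearizationInit",
    "ExtendedLogisticModel",
    "ELMResults",
    "fit",
    "fit_logistic_series",
    "SingleFitResult",
]

logger = logging.getLogger(__name__)

MODES = ("I", "II", "III")

_PER_SITE = {"I": 7, "II": 6, "III": 4}
_SHARED = {"I": 0, "II": 1, "III": 3}

#: column offset of each amplitude within a site block (Modes I and II)
_AMP_OFFSET = {
    (GRAIN, "biomass"): 0,
    (TOTAL, "biomass"): 1,
    (GRAIN, "n_uptake"): 2,
    (TOTAL, "n_uptake"): 3,
}


@dataclass(frozen=True)
class ModeSpec:
    """A nested fitting configuration; see the module docstring."""

    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def n_params(self, n_sites: int) -> int:
        return count_parameters(self.mode, n_sites)

    @property
    def rank(self) -> int:
        """Nesting rank: higher rank = more constrained (fewer parameters)."""
        return MODES.index(self.mode)


def count_parameters(mode: str, n_sites: int) -> int:
    """Free-parameter count of a Mode over ``n_sites`` sites
    (I: 7n, II: 6n+1, III: 4n+3)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    return _PER_SITE[mode] * n_sites + _SHARED[mode]


# ---------------------------------------------------------------------------
# objective


def _series_scale(s: ResponseSeries, scale: str) -> float:
    if scale == "mean":
        v = float(np.mean(s.values))
    elif scale == "max":
        v = float(np.max(s.values))
    elif scale == "A":
        v = 1.02 * float(np.max(s.values))
    else:
        raise ValueError(f"unknown scale {scale!r}; expected 'mean', 'max' or 'A'")
    if v <= 0:
        raise ValueError(
            f"degenerate series {s.key()}: scale statistic {scale!r} is not positive"
        )
    return v


def normalized_sse(
    series: Sequence[ResponseSeries],
    params: Mapping[str, SiteParams],
    scale: str = "mean",
) -> float:
    """Dimensionless residual sum of squares over all series.

    Each series contributes ``sum(((y - yhat)/s)**2)`` with ``s`` its scale
    statistic (default: observed mean), making the objective additive over
    sites and invariant to a change of units applied jointly to a series and
    its parameters.
    """
    total = 0.0
    for s in series:
        if s.site_id not in params:
            raise KeyError(f"no parameters supplied for site {s.site_id!r}")
        sp = params[s.site_id]
        yhat = logistic_response(s.n_applied, sp.logistic(s.fraction, s.response))
        sc = _series_scale(s, scale)
        total += float(np.sum(((s.values - yhat) / sc) ** 2))
    return total


# ---------------------------------------------------------------------------
# linearized initialization


@dataclass
class LinearizationInit:
    """Starting values and bound boxes from the shared-slope linearization."""

    sites: Dict[str, SiteParams]
    c_estimates: np.ndarray
    c_bounds: Tuple[float, float]
    b_bounds: Dict[str, Tuple[float, float]]
    b_N_bounds: Dict[str, Tuple[float, float]]


def _linearize(N: np.ndarray, y: np.ndarray, A_prov: float, key) -> Tuple[np.ndarray, np.ndarray]:
    """Transform y = A/(1+e^(b-cN)) to the line z = ln(A/y - 1) = b - cN,
    dropping points where the log is undefined (y <= 0 or y >= A_prov)."""
    usable = (y > 0) & (y < A_prov)
    if not np.all(usable):
        warnings.warn(
            f"{int((~usable).sum())} point(s) of series {key} excluded from "
            "linearization (outside (0, provisional A))",
            stacklevel=3,
        )
    if usable.sum() < 3:
        raise ValueError(
            f"series {key}: fewer than 3 usable points for linearized initialization"
        )
    Nn, yy = N[usable], y[usable]
    z = np.log(A_prov / yy - 1.0)
    return Nn, z


def _slope_stats(N: np.ndarray, z: np.ndarray) -> Tuple[float, float, float, float]:
    Nbar, zbar = float(np.mean(N)), float(np.mean(z))
    Sxx = float(np.sum((N - Nbar) ** 2))
    Sxz = float(np.sum((N - Nbar) * (z - zbar)))
    return Nbar, zbar, Sxx, Sxz


def init_params(series: Sequence[ResponseSeries], a_factor: float = 1.02) -> LinearizationInit:
    """Starting values for the joint fit from per-series linearization.

    Each series is linearized as ``z = ln(A/y - 1) = b - cN`` with a
    provisional ``A = a_factor * max(y)``.  The twelve individual slopes give
    twelve c estimates (initial c = their mean; bounds = their min/max).  For
    each site x fraction, the biomass and uptake lines share the N sampling,
    so a single best-fit shared slope ``m = (S_xz1 + S_xz2)/(S_xx1 + S_xx2)``
    determines the intercepts ``z_bar - m*N_bar`` that become the six b and
    six b_N estimates; each site's initial b (b_N) is the mean of its two
    fraction intercepts, bounded by their min/max.
    """
    grouped = group_series(series)
    require_complete(grouped)

    c_ests: List[float] = []
    sites: Dict[str, SiteParams] = {}
    b_bounds: Dict[str, Tuple[float, float]] = {}
    b_N_bounds: Dict[str, Tuple[float, float]] = {}

    for site, per_site in grouped.items():
        b_ests: List[float] = []
        bN_ests: List[float] = []
        A_prov: Dict[Tuple[str, str], float] = {}
        for fr in FRACTIONS:
            bio = per_site[(fr, "biomass")]
            upt = per_site[(fr, "n_uptake")]
            A_bio = a_factor * float(np.max(bio.values))
            A_upt = a_factor * float(np.max(upt.values))
            A_prov[(fr, "biomass")] = A_bio
            A_prov[(fr, "n_uptake")] = A_upt

            N1, z1 = _linearize(bio.n_applied, bio.values, A_bio, bio.key())
            N2, z2 = _linearize(upt.n_applied, upt.values, A_upt, upt.key())
            Nb1, zb1, Sxx1, Sxz1 = _slope_stats(N1, z1)
            Nb2, zb2, Sxx2, Sxz2 = _slope_stats(N2, z2)

            # individual slopes -> two of the twelve c estimates
            c_ests.append(-Sxz1 / Sxx1)
            c_ests.append(-Sxz2 / Sxx2)

            # shared slope of the pair -> intercepts for b and b_N
            m = (Sxz1 + Sxz2) / (Sxx1 + Sxx2)
            b_ests.append(zb1 - m * Nb1)
            bN_ests.append(zb2 - m * Nb2)

        b0 = float(np.mean(b_ests))
        bN0 = float(np.mean(bN_ests))
        b_bounds[site] = (min(b_ests), max(b_ests))
        b_N_bounds[site] = (min(bN_ests), max(bN_ests))
        sites[site] = _make_init_site(site, A_prov, b0, bN0)

    c0 = float(np.mean(c_ests))
    if c0 <= 0:
        raise ValueError(
            "linearized initialization produced a non-positive response "
            "parameter c; the data do not show an increasing dose response"
        )
    out_sites = {
        site: SiteParams(
            site_id=sp.site_id, A_g=sp.A_g, A_t=sp.A_t, A_Ng=sp.A_Ng, A_Nt=sp.A_Nt,
            b=sp.b, b_N=sp.b_N, c=c0,
        )
        for site, sp in sites.items()
    }
    return LinearizationInit(
        sites=out_sites,
        c_estimates=np.asarray(c_ests),
        c_bounds=(min(c_ests), max(c_ests)),
        b_bounds=b_bounds,
        b_N_bounds=b_N_bounds,
    )


def _make_init_site(site: str, A_prov: Dict[Tuple[str, str], float], b0: float, bN0: float) -> SiteParams:
    return SiteParams(
        site_id=site,
        A_g=A_prov[(GRAIN, "biomass")],
        A_t=A_prov[(TOTAL, "biomass")],
        A_Ng=A_prov[(GRAIN, "n_uptake")],
        A_Nt=A_prov[(TOTAL, "n_uptake")],
        b=b0,
        b_N=bN0,
        c=1.0,  # placeholder; replaced with the pooled estimate by the caller
    )


# ---------------------------------------------------------------------------
# parameter vector layout


class _ParamMap:
    """Flat parameter vector <-> per-site parameters for one Mode."""

    def __init__(self, mode: str, site_ids: Sequence[str]):
        self.mode = mode
        self.site_ids = list(site_ids)
        self.n_sites = len(self.site_ids)
        self.per_site = _PER_SITE[mode]
        self.n_params = count_parameters(mode, self.n_sites)

    # -- naming -------------------------------------------------------------
    def names(self) -> List[str]:
        per_site_names = {
            "I": ("A_g", "A_t", "A_Ng", "A_Nt", "b", "b_N", "c"),
            "II": ("A_g", "A_t", "A_Ng", "A_Nt", "b", "c"),
            "III": ("A_Ng", "A_Nt", "b", "c"),
        }[self.mode]
        shared_names = {"I": (), "II": ("delta_b",), "III": ("delta_b", "N_cm_g", "N_cm_t")}[self.mode]
        out = [f"{site}:{n}" for site in self.site_ids for n in per_site_names]
        out.extend(shared_names)
        return out

    # -- pack / unpack ------------------------------------------------------
    def pack(self, init: LinearizationInit) -> np.ndarray:
        theta = np.empty(self.n_params)
        sps = [init.sites[s] for s in self.site_ids]
        for i, sp in enumerate(sps):
            base = self.per_site * i
            if self.mode == "I":
                theta[base:base + 7] = (sp.A_g, sp.A_t, sp.A_Ng, sp.A_Nt, sp.b, sp.b_N, sp.c)
            elif self.mode == "II":
                theta[base:base + 6] = (sp.A_g, sp.A_t, sp.A_Ng, sp.A_Nt, sp.b, sp.c)
            else:
                theta[base:base + 4] = (sp.A_Ng, sp.A_Nt, sp.b, sp.c)
        if self.mode == "II":
            theta[-1] = float(np.mean([sp.delta_b for sp in sps]))
        elif self.mode == "III":
            theta[-3] = float(np.mean([sp.delta_b for sp in sps]))
            theta[-2] = float(np.mean([sp.A_Ng / sp.A_g for sp in sps]))
            theta[-1] = float(np.mean([sp.A_Nt / sp.A_t for sp in sps]))
        return theta

    def unpack(self, theta: np.ndarray) -> Tuple[Dict[str, SiteParams], Dict[str, float]]:
        sites: Dict[str, SiteParams] = {}
        shared: Dict[str, float] = {}
        if self.mode == "II":
            shared["delta_b"] = float(theta[-1])
        elif self.mode == "III":
            shared["delta_b"] = float(theta[-3])
            shared["N_cm_g"] = float(theta[-2])
            shared["N_cm_t"] = float(theta[-1])
        for i, site in enumerate(self.site_ids):
            base = self.per_site * i
            if self.mode == "I":
                A_g, A_t, A_Ng, A_Nt, b, b_N, c = theta[base:base + 7]
            elif self.mode == "II":
                A_g, A_t, A_Ng, A_Nt, b, c = theta[base:base + 6]
                b_N = b + shared["delta_b"]
            else:
                A_Ng, A_Nt, b, c = theta[base:base + 4]
                b_N = b + shared["delta_b"]
                A_g = A_Ng / shared["N_cm_g"]
                A_t = A_Nt / shared["N_cm_t"]
            sites[site] = SiteParams(
                site_id=site, A_g=float(A_g), A_t=float(A_t),
                A_Ng=float(A_Ng), A_Nt=float(A_Nt),
                b=float(b), b_N=float(b_N), c=float(c),
            )
        return sites, shared

    # -- bounds -------------------------------------------------------------
    def bounds(
        self,
        init: LinearizationInit,
        theta0: np.ndarray,
        pad_c: float,
        pad_b: float,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Box constraints: padded linearization boxes for b, b_N and c;
        positivity for amplitudes, Delta_b and N_cm.

        The raw min-max boxes collapse when the per-fraction estimates
        coincide (exactly shared shifts, low noise), so each box is widened
        before use — c relatively by ``pad_c``, the shift boxes by
        ``max(half-width, pad_b)`` absolutely.
        """
        lb = np.full(self.n_params, -np.inf)
        ub = np.full(self.n_params, np.inf)

        c_lo, c_hi = init.c_bounds
        c_lo = max(c_lo * (1.0 - pad_c), 1e-12)
        c_hi = c_hi * (1.0 + pad_c)

        def shift_box(lo: float, hi: float) -> Tuple[float, float]:
            pad = max(0.5 * (hi - lo), pad_b)
            return lo - pad, hi + pad

        for i, site in enumerate(self.site_ids):
            base = self.per_site * i
            n_amp = 4 if self.mode in ("I", "II") else 2
            for j in range(n_amp):
                lb[base + j] = 1e-6 * theta0[base + j]
            b_lo, b_hi = shift_box(*init.b_bounds[site])
            if self.mode == "I":
                bN_lo, bN_hi = shift_box(*init.b_N_bounds[site])
                lb[base + 4], ub[base + 4] = b_lo, b_hi
                lb[base + 5], ub[base + 5] = bN_lo, bN_hi
                lb[base + 6], ub[base + 6] = c_lo, c_hi
            elif self.mode == "II":
                lb[base + 4], ub[base + 4] = b_lo, b_hi
                lb[base + 5], ub[base + 5] = c_lo, c_hi
            else:
                lb[base + 2], ub[base + 2] = b_lo, b_hi
                lb[base + 3], ub[base + 3] = c_lo, c_hi
        if self.mode == "II":
            lb[-1] = 1e-6
            ub[-1] = max(max(h for _, h in init.b_N_bounds.values())
                         - min(l for l, _ in init.b_bounds.values()) + pad_b, 1.0)
        elif self.mode == "III":
            lb[-3] = 1e-6
            ub[-3] = max(max(h for _, h in init.b_N_bounds.values())
                         - min(l for l, _ in init.b_bounds.values()) + pad_b, 1.0)
            lb[-2] = lb[-1] = 1e-6
        return lb, ub

    # -- per-series terms for prediction and Jacobian -----------------------
    def terms(self, theta: np.ndarray, i: int, fraction: str, response: str):
        """Return (amp, shift, c, amp_cols, shift_cols, c_col) for one series.

        ``amp_cols`` and ``shift_cols`` are (column, chain factor) pairs
        mapping the partials w.r.t. the effective amplitude and shift onto
        the flat parameter vector.
        """
        if self.mode == "I":
            base = 7 * i
            a_col = base + _AMP_OFFSET[(fraction, response)]
            s_col = base + (4 if response == "biomass" else 5)
            return (
                theta[a_col], theta[s_col], theta[base + 6],
                ((a_col, 1.0),), ((s_col, 1.0),), base + 6,
            )
        if self.mode == "II":
            base = 6 * i
            a_col = base + _AMP_OFFSET[(fraction, response)]
            db_col = self.n_params - 1
            if response == "biomass":
                shift = theta[base + 4]
                s_cols = ((base + 4, 1.0),)
            else:
                shift = theta[base + 4] + theta[db_col]
                s_cols = ((base + 4, 1.0), (db_col, 1.0))
            return theta[a_col], shift, theta[base + 5], ((a_col, 1.0),), s_cols, base + 5
        # Mode III
        base = 4 * i
        an_col = base + (0 if fraction == GRAIN else 1)
        db_col = self.n_params - 3
        ncm_col = self.n_params - (2 if fraction == GRAIN else 1)
        A_N = theta[an_col]
        if response == "n_uptake":
            amp = A_N
            a_cols = ((an_col, 1.0),)
            shift = theta[base + 2] + theta[db_col]
            s_cols = ((base + 2, 1.0), (db_col, 1.0))
        else:
            ncm = theta[ncm_col]
            amp = A_N / ncm
            a_cols = ((an_col, 1.0 / ncm), (ncm_col, -A_N / ncm ** 2))
            shift = theta[base + 2]
            s_cols = ((base + 2, 1.0),)
        return amp, shift, theta[base + 3], a_cols, s_cols, base + 3


# ---------------------------------------------------------------------------
# Gauss-Newton engine

_FLOOR_NRSS = 1e-24  # numerical zero for a dimensionless residual sum


def _gauss_newton_box(resid, jac, theta0, lb, ub, *, tol, gtol, max_iter):
    """Minimize ||resid(theta)||^2 over the box [lb, ub].

    Gauss-Newton steps from the normal equations, halved until the objective
    decreases; a Levenberg ridge scaled by diag(J'J) is engaged when the
    equations are singular or the plain step fails.  Returns
    (theta, nrss, trace, converged, n_iter); on failure to descend the best
    iterate so far is returned with ``converged=False`` unless the projected
    gradient is already below ``gtol``.
    """
    theta = np.clip(np.asarray(theta0, dtype=float), lb, ub)
    r = resid(theta)
    f = float(r @ r)
    trace = [f]
    converged = False
    n_iter = 0
    eps_act = 1e-12

    for it in range(max_iter):
        n_iter = it + 1
        J = jac(theta)
        g = 2.0 * (J.T @ r)
        pg = g.copy()
        with np.errstate(invalid="ignore"):
            lo_act = np.isfinite(lb) & (theta <= lb + eps_act * (1.0 + np.abs(lb)))
            hi_act = np.isfinite(ub) & (theta >= ub - eps_act * (1.0 + np.abs(ub)))
        pg[lo_act & (g > 0)] = 0.0
        pg[hi_act & (g < 0)] = 0.0
        if float(np.max(np.abs(pg))) < gtol or f <= _FLOOR_NRSS:
            converged = True
            break

        H = J.T @ J
        d = np.diag(H).copy()
        d[d <= 0] = 1.0
        rhs = -0.5 * g

        accepted = False
        lam = 0.0
        for _attempt in range(25):
            try:
                delta = np.linalg.solve(H + lam * np.diag(d) if lam > 0 else H, rhs)
            except np.linalg.LinAlgError:
                lam = 1e-8 if lam == 0 else lam * 100.0
                logger.debug("singular normal equations; ridge fallback lam=%g", lam)
                continue
            if not np.all(np.isfinite(delta)):
                lam = 1e-8 if lam == 0 else lam * 100.0
                continue
            step = delta
            for _half in range(40):
                cand = np.clip(theta + step, lb, ub)
                rc = resid(cand)
                fc = float(rc @ rc)
                if fc < f:
                    theta, r, f = cand, rc, fc
                    accepted = True
                    break
                step = 0.5 * step
            if accepted:
                break
            lam = 1e-4 if lam == 0 else lam * 100.0
        if not accepted:
            # no descent direction found: stationary to numerical precision
            converged = float(np.max(np.abs(pg))) < max(gtol, 1e-6)
            break
        trace.append(f)
        if abs(trace[-2] - f) <= tol * max(f, _FLOOR_NRSS):
            converged = True
            break

    return theta, f, np.asarray(trace), converged, n_iter


# ---------------------------------------------------------------------------
# results object


@dataclass
class ELMResults:
    """Joint fit of the extended logistic model under one Mode.

    Carries the per-site parameter estimates (``params``), any shared
    parameters (``shared``: Delta_b and/or the two N_cm values), the
    normalized residual sum of squares (``nrss``), degrees of freedom, and
    per-series diagnostics.  Stubs with only ``mode``/``nrss``/``df`` can be
    constructed directly, e.g. to run an ANOVA on published fit summaries.
    """

    mode: str
    nrss: float
    df: int
    n_obs: int = 0
    n_params: int = 0
    params: Dict[str, SiteParams] = field(default_factory=dict)
    shared: Dict[str, float] = field(default_factory=dict)
    per_series: List[dict] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    trace: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    scale: str = "mean"
    options: Dict[str, object] = field(default_factory=dict)
    param_names: List[str] = field(default_factory=list)
    theta: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    data: Optional[List[ResponseSeries]] = field(default=None, repr=False)

    @property
    def df_resid(self) -> int:
        return self.df

    @property
    def site_ids(self) -> List[str]:
        return list(self.params)

    def derived(self, site: str, fraction: str = GRAIN):
        """Secondary parameters (Delta_b, N_cm, N_cl, Y_m, k_N, N_0.5) for
        one fitted site x fraction."""
        from .model import derive_secondary

        return derive_secondary(self.params[site], fraction)

    def predict(self, site: str, fraction: str, response: str, N) -> np.ndarray:
        sp = self.params[site]
        return logistic_response(np.asarray(N, dtype=float), sp.logistic(fraction, response))

    def compare_f_test(self, restricted: "ELMResults", alpha: float = 0.05):
        """Extra-sum-of-squares F test of this fit (full) against a more
        constrained one; returns an :class:`~elmfit.model_selection.AnovaTable`."""
        from .model_selection import anova_compare

        return anova_compare(self, restricted, alpha=alpha)

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for site, sp in self.params.items():
            rows.append({"site": site, **{k: v for k, v in sp.flat_dict().items() if k != "site_id"}})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Extended Logistic Model — joint normalized fit",
            "=" * 54,
            f"Mode: {self.mode}    sites: {len(self.params)}    "
            f"observations: {self.n_obs}",
            f"free parameters: {self.n_params}    df: {self.df}",
            f"normalized residual SS: {self.nrss:.6g}    "
            f"converged: {self.converged} in {self.n_iter} iterations",
            f"residual scaling: per-series {self.scale}",
            "",
        ]
        if self.params:
            lines.append("Per-site parameters")
            lines.append(self.params_frame().to_string(index=False, float_format=lambda v: f"{v:.6g}"))
            lines.append("")
        if self.shared:
            shared = "    ".join(f"{k} = {v:.6g}" for k, v in self.shared.items())
            lines.append(f"Shared parameters: {shared}")
            lines.append("")
        if self.per_series:
            lines.append("Per-series goodness of fit")
            lines.append(pd.DataFrame(self.per_series).to_string(index=False, float_format=lambda v: f"{v:.6g}"))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "nrss": self.nrss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "df": self.df,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "scale": self.scale,
            "options": dict(self.options),
            "shared": dict(self.shared),
            "sites": [sp.to_dict() for sp in self.params.values()],
            "per_series": list(self.per_series),
            "trace": [float(v) for v in self.trace],
        }

    def plot_fit(self, data: Optional[Sequence[ResponseSeries]] = None, axes=None):
        from .plotting import plot_fit

        return plot_fit(self, data if data is not None else self.data, axes=axes)


# ---------------------------------------------------------------------------
# model object


class ExtendedLogisticModel:
    """Joint ELM over a multi-site N-rate trial, statsmodels-style.

    Parameters
    ----------
    series
        All dose-response series; every site must contribute the four
        fraction x response combinations on its applied-N grid.
    scale
        Per-series residual scaling statistic: ``'mean'`` (default),
        ``'max'`` or ``'A'`` (1.02 x series maximum).
    """

    def __init__(self, series: Sequence[ResponseSeries], scale: str = "mean"):
        self.series = list(series)
        grouped = group_series(self.series)
        require_complete(grouped)
        self.site_ids = site_order(self.series)
        self.scale = scale
        self._scales = {s.key(): _series_scale(s, scale) for s in self.series}
        self.n_obs = sum(len(s) for s in self.series)
        self._init_cache: Optional[LinearizationInit] = None

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale: str = "mean") -> "ExtendedLogisticModel":
        """Build from a long-format frame with columns
        site, fraction, response, n_applied, value."""
        from .io import series_from_dataframe

        return cls(series_from_dataframe(df), scale=scale)

    @classmethod
    def from_csv(cls, path, scale: str = "mean") -> "ExtendedLogisticModel":
        from .io import read_trial_csv

        return cls(read_trial_csv(path), scale=scale)

    # -- initialization -----------------------------------------------------
    def initialize(self) -> LinearizationInit:
        if self._init_cache is None:
            self._init_cache = init_params(self.series)
        return self._init_cache

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        mode: str = "I",
        *,
        tol: float = 1e-10,
        gtol: float = 1e-8,
        max_iter: int = 500,
        start: Optional[Mapping[str, SiteParams]] = None,
        pad_c: float = 0.5,
        pad_b: float = 0.3,
    ) -> ELMResults:
        """Minimize the normalized residual SS over the Mode's free parameters.

        ``tol`` is the relative objective-change stopping rule, ``gtol`` the
        projected-gradient infinity-norm rule.  ``start`` may override the
        linearized starting values (per-site SiteParams); the bound box still
        comes from the linearization, padded by ``pad_c``/``pad_b``.
        """
        spec = ModeSpec(mode)
        pmap = _ParamMap(mode, self.site_ids)
        init = self.initialize()
        if start is not None:
            init = LinearizationInit(
                sites={s: start[s] for s in self.site_ids},
                c_estimates=init.c_estimates,
                c_bounds=init.c_bounds,
                b_bounds=init.b_bounds,
                b_N_bounds=init.b_N_bounds,
            )
        theta0 = pmap.pack(init)
        lb, ub = pmap.bounds(self.initialize(), theta0, pad_c=pad_c, pad_b=pad_b)
        clipped = np.clip(theta0, lb, ub)
        if np.any(clipped != theta0):
            logger.info("initial guess clamped to the bound box for %d parameter(s)",
                        int(np.sum(clipped != theta0)))
        theta0 = clipped

        structs = []
        row = 0
        site_index = {s: i for i, s in enumerate(self.site_ids)}
        for s in self.series:
            rows = slice(row, row + len(s))
            structs.append((site_index[s.site_id], s.fraction, s.response,
                            s.n_applied, s.values, self._scales[s.key()], rows))
            row += len(s)
        n_total = row

        def resid(theta: np.ndarray) -> np.ndarray:
            r = np.empty(n_total)
            for i, fr, resp, N, y, sc, rows in structs:
                amp, shift, c, _, _, _ = pmap.terms(theta, i, fr, resp)
                r[rows] = (y - amp * expit(c * N - shift)) / sc
            return r

        def jac(theta: np.ndarray) -> np.ndarray:
            J = np.zeros((n_total, pmap.n_params))
            for i, fr, resp, N, y, sc, rows in structs:
                amp, shift, c, a_cols, s_cols, c_col = pmap.terms(theta, i, fr, resp)
                L = expit(c * N - shift)
                LL = L * (1.0 - L)
                d_amp = -L / sc               # d r / d amp
                d_shift = amp * LL / sc       # d r / d shift
                d_c = -amp * N * LL / sc      # d r / d c
                for col, fac in a_cols:
                    J[rows, col] += fac * d_amp
                for col, fac in s_cols:
                    J[rows, col] += fac * d_shift
                J[rows, c_col] += d_c
            return J

        theta, f, trace, converged, n_iter = _gauss_newton_box(
            resid, jac, theta0, lb, ub, tol=tol, gtol=gtol, max_iter=max_iter,
        )
        if not converged:
            logger.warning("fit (mode %s) did not meet convergence criteria in %d iterations; "
                           "best iterate returned", mode, n_iter)

        sites, shared = pmap.unpack(theta)
        per_series = self._diagnostics(sites)
        n_params = spec.n_params(len(self.site_ids))
        return ELMResults(
            mode=mode,
            nrss=f,
            df=self.n_obs - n_params,
            n_obs=self.n_obs,
            n_params=n_params,
            params=sites,
            shared=shared,
            per_series=per_series,
            converged=converged,
            n_iter=n_iter,
            trace=trace,
            scale=self.scale,
            options={"tol": tol, "gtol": gtol, "max_iter": max_iter,
                     "pad_c": pad_c, "pad_b": pad_b},
            param_names=pmap.names(),
            theta=theta,
            data=self.series,
        )

    def _diagnostics(self, sites: Mapping[str, SiteParams]) -> List[dict]:
        from .model_selection import nash_sutcliffe

        out = []
        for s in self.series:
            yhat = logistic_response(s.n_applied, sites[s.site_id].logistic(s.fraction, s.response))
            sse = float(np.sum((s.values - yhat) ** 2))
            out.append({
                "site": s.site_id,
                "fraction": s.fraction,
                "response": s.response,
                "sse": sse,
                "r2_ns": nash_sutcliffe(s.values, yhat),
                "nrss": sse / self._scales[s.key()] ** 2,
            })
        return out


def fit(data: Sequence[ResponseSeries], mode: str = "I", *, scale: str = "mean",
        **options) -> ELMResults:
    """Functional wrapper: ``ExtendedLogisticModel(data, scale).fit(mode, ...)``."""
    return ExtendedLogisticModel(data, scale=scale).fit(mode=mode, **options)


# ---------------------------------------------------------------------------
# single-series fit (used for oracle comparisons and quick looks)


@dataclass
class SingleFitResult:
    params: LogisticParams
    nrss: float
    converged: bool
    n_iter: int
    trace: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


def fit_logistic_series(N, y, *, scale: str = "mean", tol: float = 1e-12,
                        gtol: float = 1e-10, max_iter: int = 200) -> SingleFitResult:
    """Normalized least-squares fit of a single logistic (A, b, c) curve."""
    N = np.asarray(N, dtype=float)
    y = np.asarray(y, dtype=float)
    if scale == "mean":
        sc = float(np.mean(y))
    elif scale == "max":
        sc = float(np.max(y))
    elif scale == "A":
        sc = 1.02 * float(np.max(y))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if sc <= 0:
        raise ValueError("degenerate series: non-positive scale statistic")

    A0 = 1.02 * float(np.max(y))
    Nn, z = _linearize(N, y, A0, ("single", "series"))
    _, zbar, Sxx, Sxz = _slope_stats(Nn, z)
    c0 = -Sxz / Sxx
    if c0 <= 0:
        c0 = 2.0 / max(float(N[-1] - N[0]), 1.0)
    b0 = zbar + c0 * float(np.mean(Nn))

    theta0 = np.array([A0, b0, c0])
    lb = np.array([0.2 * float(np.max(y)), -30.0, 1e-8])
    ub = np.array([np.inf, 30.0, 10.0])

    def resid(theta):
        A, b, c = theta
        return (y - A * expit(c * N - b)) / sc

    def jac(theta):
        A, b, c = theta
        L = expit(c * N - b)
        LL = L * (1.0 - L)
        return np.column_stack([-L / sc, A * LL / sc, -A * N * LL / sc])

    theta, f, trace, converged, n_iter = _gauss_newton_box(
        resid, jac, theta0, lb, ub, tol=tol, gtol=gtol, max_iter=max_iter,
    )
    return SingleFitResult(
        params=LogisticParams(A=float(theta[0]), b=float(theta[1]), c=float(theta[2])),
        nrss=f, converged=converged, n_iter=n_iter, trace=trace,
    )
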