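"""Nested-model comparison and goodness of fit.

The parameter-invariance hypotheses (common Delta_b; common Delta_b and
N_cm) are tested with the extra-sum-of-squares F ratio for nested nonlinear
models: with RSS_f, df_f from the full (less constrained) fit and RSS_r,
df_r from the reduced one,

    F = [(RSS_r - RSS_f) / (df_r - df_f)] / (RSS_f / df_f)

compared against the upper alpha quantile of F(df_r - df_f, df_f).  The
denominator is always the *full* model's mean square, as in a classical
variance-ratio table.  Goodness of fit per series uses the Nash-Sutcliffe
model efficiency, the nonlinear analogue of R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaRow", "AnovaTable", "anova_compare", "f_critical", "nash_sutcliffe"]

#: slack for Delta RSS < 0 caused by optimizer tolerance on nested fits
_NEST_TOL = 1e-9


@dataclass(frozen=True)
class AnovaRow:
    label: str
    n_params: Optional[int]
    df: int
    rss: float
    mean_square: float
    F: Optional[float] = None
    F_crit: Optional[float] = None
    significant: Optional[bool] = None


@dataclass
class AnovaTable:
    """Variance-ratio table for one nested Mode comparison.

    Three rows: the full fit, the reduced fit, and their difference (which
    carries the F ratio, the critical value and the verdict).
    """

    rows: List[AnovaRow]
    alpha: float = 0.05
    conclusion: str = ""

    @property
    def difference(self) -> AnovaRow:
        return self.rows[-1]

    @property
    def F(self) -> float:
        return self.difference.F  # type: ignore[return-value]

    @property
    def significant(self) -> bool:
        return bool(self.difference.significant)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def round_sig(self, x: Optional[float], sig: int = 3) -> Optional[float]:
        if x is None or x == 0:
            return x
        from math import floor, log10

        return round(x, -int(floor(log10(abs(x)))) + (sig - 1))

    def __str__(self) -> str:
        df = self.to_dataframe().astype(object)
        for col in ("rss", "mean_square", "F", "F_crit"):
            df[col] = df[col].map(lambda v: self.round_sig(v) if pd.notna(v) else "")
        df["n_params"] = df["n_params"].map(
            lambda v: "" if v is None or (isinstance(v, float) and pd.isna(v)) else int(v))
        df["significant"] = df["significant"].map(lambda v: "" if v is None else v)
        return df.to_string(index=False) + f"\n{self.conclusion}"

    def to_markdown_table(self) -> str:
        df = self.to_dataframe()
        cols = list(df.columns)
        lines = ["| " + " | ".join(cols) + " |",
                 "| " + " | ".join("---" for _ in cols) + " |"]
        for _, row in df.iterrows():
            cells = []
            for col in cols:
                v = row[col]
                if isinstance(v, float):
                    cells.append(f"{self.round_sig(v)}" if pd.notna(v) else "")
                else:
                    cells.append("" if v is None or (isinstance(v, float) and pd.isna(v)) else str(v))
            lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
        lines.append(self.conclusion)
        return "\n".join(lines)


def anova_compare(full, reduced, alpha: float = 0.05) -> AnovaTable:
    """Extra-sum-of-squares ANOVA of a full fit against a reduced (nested)
    one on the same data.

    ``full`` and ``reduced`` need ``nrss``, ``df`` and optionally
    ``n_params``/``n_obs``/``mode`` attributes — fitted :class:`ELMResults`
    or stubs built from published numbers both work.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if reduced.df <= full.df:
        raise ValueError(
            "reduced model must have more residual degrees of freedom than the "
            f"full model (got df {reduced.df} vs {full.df}); models are not nested"
        )
    n_obs_f = getattr(full, "n_obs", 0)
    n_obs_r = getattr(reduced, "n_obs", 0)
    if n_obs_f and n_obs_r and n_obs_f != n_obs_r:
        raise ValueError("full and reduced fits use different numbers of observations")

    d_df = reduced.df - full.df
    d_rss = reduced.nrss - full.nrss
    if d_rss < -_NEST_TOL * max(1.0, full.nrss):
        warnings.warn(
            "reduced model has a lower residual SS than the full model beyond "
            "optimizer tolerance; consider refitting with tighter tolerances",
            stacklevel=2,
        )
    ms_full = full.nrss / full.df
    ms_diff = d_rss / d_df
    F = ms_diff / ms_full
    F_crit = f_critical(d_df, full.df, 1.0 - alpha)
    significant = F > F_crit

    label_f = f"Mode {full.mode}" if getattr(full, "mode", None) else "full"
    label_r = f"Mode {reduced.mode}" if getattr(reduced, "mode", None) else "reduced"
    rows = [
        AnovaRow(label=label_f, n_params=getattr(full, "n_params", None) or None,
                 df=full.df, rss=full.nrss, mean_square=ms_full),
        AnovaRow(label=label_r, n_params=getattr(reduced, "n_params", None) or None,
                 df=reduced.df, rss=reduced.nrss, mean_square=reduced.nrss / reduced.df),
        AnovaRow(label=f"{label_r} - {label_f}", n_params=None, df=d_df,
                 rss=d_rss, mean_square=ms_diff, F=F, F_crit=F_crit,
                 significant=significant),
    ]
    pct = 100.0 * (1.0 - alpha)
    if significant:
        conclusion = (
            f"F = {F:.3g} > F({d_df},{full.df},{pct:g}%) = {F_crit:.3g}: significant "
            f"difference between {label_f} and {label_r}; the shared-parameter "
            "constraint degrades the fit."
        )
    else:
        conclusion = (
            f"F = {F:.3g} <= F({d_df},{full.df},{pct:g}%) = {F_crit:.3g}: no significant "
            f"difference between {label_f} and {label_r}; the constrained "
            "parameters can be treated as invariant."
        )
    return AnovaTable(rows=rows, alpha=alpha, conclusion=conclusion)


def f_critical(df_num: int, df_den: int, level: float = 0.95) -> float:
    """Upper ``level`` quantile of the F(df_num, df_den) distribution,
    computed through the inverse regularized incomplete beta function."""
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    return float(stats.f.ppf(level, df_num, df_den))


def nash_sutcliffe(observed, predicted) -> float:
    """Nash-Sutcliffe model efficiency: ``1 - SSE/SStot``.

    Equals 1 for a perfect fit, 0 for a fit no better than the observed
    mean, and can be negative.  Undefined (error) when the observations have
    zero variance.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have the same shape")
    if y.size < 2:
        raise ValueError("at least two observations are required")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("Nash-Sutcliffe efficiency undefined: observations have zero variance")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
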