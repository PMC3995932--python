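"""Observed dose-response series and grouping helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .params import FRACTIONS

__all__ = ["RESPONSES", "ResponseSeries", "group_series", "series_key"]

RESPONSES = ("biomass", "n_uptake")

#: minimum points per series: three to identify (A, b, c) plus one df
MIN_POINTS = 4


@dataclass
class ResponseSeries:
    """One observed dose-response series: a site x plant fraction x response
    kind over the applied-N grid.

    ``n_applied`` is in kg ha^-1 (strictly increasing, nonnegative);
    ``values`` are Mg ha^-1 for biomass and kg ha^-1 for N uptake.
    """

    site_id: str
    fraction: str
    response: str
    n_applied: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.n_applied = np.asarray(self.n_applied, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.fraction not in FRACTIONS:
            raise ValueError(f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}, got {self.response!r}")
        if self.n_applied.ndim != 1 or self.values.ndim != 1:
            raise ValueError("n_applied and values must be one-dimensional")
        if len(self.n_applied) != len(self.values):
            raise ValueError("n_applied and values must have equal length")
        if len(self.n_applied) < MIN_POINTS:
            raise ValueError(
                f"series {self.key()} has {len(self.n_applied)} points; "
                f"at least {MIN_POINTS} are required"
            )
        if not np.all(np.isfinite(self.n_applied)) or not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.key()} contains non-finite entries")
        if self.n_applied[0] < 0:
            raise ValueError("applied N must be nonnegative")
        if np.any(np.diff(self.n_applied) <= 0):
            raise ValueError(f"applied N must be strictly increasing in series {self.key()}")
        if np.any(self.values < 0):
            raise ValueError(f"observed values must be nonnegative in series {self.key()}")

    def key(self) -> Tuple[str, str, str]:
        return (self.site_id, self.fraction, self.response)

    def __len__(self) -> int:
        return len(self.n_applied)


def series_key(s: ResponseSeries) -> Tuple[str, str, str]:
    return s.key()


def group_series(series: Iterable[ResponseSeries]) -> Dict[str, Dict[Tuple[str, str], ResponseSeries]]:
    """Group series by site, then (fraction, response); duplicate keys are an
    error.  Site order follows first appearance."""
    out: Dict[str, Dict[Tuple[str, str], ResponseSeries]] = {}
    for s in series:
        per_site = out.setdefault(s.site_id, {})
        k = (s.fraction, s.response)
        if k in per_site:
            raise ValueError(f"duplicate series for {s.key()}")
        per_site[k] = s
    return out


def require_complete(grouped: Dict[str, Dict[Tuple[str, str], ResponseSeries]]) -> None:
    """Every site must carry all four fraction x response series."""
    for site, per_site in grouped.items():
        for fr in FRACTIONS:
            for resp in RESPONSES:
                if (fr, resp) not in per_site:
                    raise ValueError(f"site {site!r} is missing the {fr} {resp} series")


def site_order(series: Sequence[ResponseSeries]) -> List[str]:
    seen: List[str] = []
    for s in series:
        if s.site_id not in seen:
            seen.append(s.site_id)
    return seen
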