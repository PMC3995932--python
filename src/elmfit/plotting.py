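"""Diagnostic figures: fitted response, concentration and phase curves
overlaid on observations."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .data import ResponseSeries
from .model import (
    derive_secondary,
    logistic_response,
    n_concentration_vs_N,
    n_concentration_vs_Nu,
    phase_biomass,
)
from .params import FRACTIONS

__all__ = ["plot_fit"]

_STYLES = {"grain": dict(color="tab:blue"), "total": dict(color="tab:orange")}


def plot_fit(results, data: Optional[Sequence[ResponseSeries]] = None, axes=None):
    """One row of panels per site: biomass and uptake vs applied N,
    N concentration vs applied N, and the biomass-uptake phase curve."""
    import matplotlib.pyplot as plt

    sites = results.site_ids
    if axes is None:
        fig, axes = plt.subplots(len(sites), 4, figsize=(16, 3.2 * len(sites)),
                                 squeeze=False)
    else:
        fig = axes[0][0].figure

    by_key = {}
    for s in data or []:
        by_key[s.key()] = s

    n_grid = np.linspace(0, 300, 200)
    for row, site in enumerate(sites):
        sp = results.params[site]
        ax_bio, ax_upt, ax_conc, ax_phase = axes[row]
        for fraction in FRACTIONS:
            style = _STYLES[fraction]
            ax_bio.plot(n_grid, logistic_response(n_grid, sp.logistic(fraction, "biomass")),
                        label=f"{fraction}", **style)
            ax_upt.plot(n_grid, logistic_response(n_grid, sp.logistic(fraction, "n_uptake")),
                        label=f"{fraction}", **style)
            ax_conc.plot(n_grid, n_concentration_vs_N(n_grid, sp, fraction), **style)
            d = derive_secondary(sp, fraction)
            if d.phase is not None:
                nu = np.linspace(0, sp.amplitude(fraction, "n_uptake"), 100)
                ax_phase.plot(nu, phase_biomass(nu, d.phase), **style)
            obs_b = by_key.get((site, fraction, "biomass"))
            obs_u = by_key.get((site, fraction, "n_uptake"))
            if obs_b is not None:
                ax_bio.plot(obs_b.n_applied, obs_b.values, "o", **style)
            if obs_u is not None:
                ax_upt.plot(obs_u.n_applied, obs_u.values, "o", **style)
            if obs_b is not None and obs_u is not None:
                ax_conc.plot(obs_b.n_applied, obs_u.values / obs_b.values, "o", **style)
                ax_phase.plot(obs_u.values, obs_b.values, "o", **style)
        ax_bio.set_title(f"{site}: biomass vs applied N")
        ax_bio.set_ylabel("Mg ha$^{-1}$")
        ax_upt.set_title("N uptake vs applied N")
        ax_upt.set_ylabel("kg ha$^{-1}$")
        ax_conc.set_title("N concentration vs applied N")
        ax_conc.set_ylabel("g kg$^{-1}$")
        ax_phase.set_title("biomass vs N uptake (phase)")
        ax_phase.set_xlabel("N uptake, kg ha$^{-1}$")
        for ax in (ax_bio, ax_upt, ax_conc):
            ax.set_xlabel("applied N, kg ha$^{-1}$")
        ax_bio.legend(fontsize=8)
    fig.tight_layout()
    return fig
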