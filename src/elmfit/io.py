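"""Reading and writing trial data, parameter sets, fits and report tables.

One long-format CSV covers everything the fitter consumes:

    site,fraction,response,n_applied,value

with fraction in {grain, total}, response in {biomass, n_uptake}, applied N
in kg ha^-1, biomass in Mg ha^-1 and N uptake in kg ha^-1.  Parameter sets
and fit results travel as JSON, trial designs as YAML, report tables as CSV
and markdown.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import RESPONSES, ResponseSeries
from .fitting import ELMResults
from .model import derive_secondary
from .params import FRACTIONS, SiteParams
from .simulate import TrialDesign, TruthSet

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trial_csv",
    "write_trial_csv",
    "series_from_dataframe",
    "series_to_dataframe",
    "save_truth",
    "load_truth",
    "load_design",
    "save_fit",
    "load_fit",
    "derived_table",
    "report",
]

REQUIRED_COLUMNS = ("site", "fraction", "response", "n_applied", "value")


def series_from_dataframe(df: pd.DataFrame, source: str = "<dataframe>") -> List[ResponseSeries]:
    """Validate a long-format frame and group it into response series.

    Rows duplicating a (site, fraction, response, n_applied) cell are
    averaged with a warning.  Errors cite 1-based data line numbers
    (header = line 1).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    df.index = np.arange(2, len(df) + 2)  # line numbers: header is line 1

    for col in ("n_applied", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad) > 0:
            raise ValueError(
                f"{source}: non-numeric {col!r} value(s) at line(s) "
                f"{', '.join(map(str, bad[:5]))}"
            )
        if numeric.isna().any():
            bad = df.index[numeric.isna()]
            raise ValueError(
                f"{source}: empty {col!r} value(s) at line(s) {', '.join(map(str, bad[:5]))}"
            )
        df[col] = numeric

    for col, allowed in (("fraction", FRACTIONS), ("response", RESPONSES)):
        bad = df.index[~df[col].isin(allowed)]
        if len(bad) > 0:
            raise ValueError(
                f"{source}: unknown {col!r} label(s) at line(s) "
                f"{', '.join(map(str, bad[:5]))}; allowed: {', '.join(allowed)}"
            )

    key_cols = ["site", "fraction", "response", "n_applied"]
    dups = df.duplicated(subset=key_cols, keep=False)
    if dups.any():
        warnings.warn(
            f"{source}: {int(dups.sum())} duplicate (site, fraction, response, "
            "n_applied) row(s) averaged",
            stacklevel=2,
        )
        df = df.groupby(key_cols, as_index=False, sort=False)["value"].mean()

    out: List[ResponseSeries] = []
    for (site, fraction, response), grp in df.groupby(
            ["site", "fraction", "response"], sort=False):
        grp = grp.sort_values("n_applied")
        out.append(ResponseSeries(
            site_id=str(site), fraction=str(fraction), response=str(response),
            n_applied=grp["n_applied"].to_numpy(), values=grp["value"].to_numpy(),
        ))
    return out


def read_trial_csv(path) -> List[ResponseSeries]:
    """Read and validate a long-format trial CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"site": str, "fraction": str, "response": str},
                         float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ValueError(f"{path}: could not parse CSV ({exc})") from exc
    return series_from_dataframe(df, source=str(path))


def series_to_dataframe(series: Sequence[ResponseSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for n, v in zip(s.n_applied, s.values):
            rows.append({"site": s.site_id, "fraction": s.fraction,
                         "response": s.response, "n_applied": n, "value": v})
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_trial_csv(series: Sequence[ResponseSeries], path) -> None:
    """Write series in long format at full float precision (round-trip exact)."""
    df = series_to_dataframe(series)
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# parameters / fits / designs


def save_truth(truth: TruthSet, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n")


def load_truth(path) -> TruthSet:
    return TruthSet.from_dict(json.loads(Path(path).read_text()))


def load_design(path) -> TrialDesign:
    """Read a trial design from YAML; keys mirror TrialDesign fields."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: design YAML must be a mapping")
    known = {f.name for f in dataclasses.fields(TrialDesign)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown design key(s) {sorted(unknown)}")
    if "site_ids" in raw and raw["site_ids"] is not None:
        raw["site_ids"] = tuple(raw["site_ids"])
    if "n_rates" in raw:
        raw["n_rates"] = tuple(float(v) for v in raw["n_rates"])
    return TrialDesign(**raw)


def save_fit(result: ELMResults, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def load_fit(path) -> ELMResults:
    d = json.loads(Path(path).read_text())
    params = {s["site_id"]: SiteParams.from_dict(s) for s in d.get("sites", [])}
    return ELMResults(
        mode=d["mode"], nrss=float(d["nrss"]), df=int(d["df"]),
        n_obs=int(d.get("n_obs", 0)), n_params=int(d.get("n_params", 0)),
        params=params, shared=dict(d.get("shared", {})),
        per_series=list(d.get("per_series", [])),
        converged=bool(d.get("converged", True)), n_iter=int(d.get("n_iter", 0)),
        trace=np.asarray(d.get("trace", []), dtype=float),
        scale=d.get("scale", "mean"), options=dict(d.get("options", {})),
    )


# ---------------------------------------------------------------------------
# report tables


def derived_table(params: Dict[str, SiteParams]) -> pd.DataFrame:
    """Flat per-site x fraction table of primary and derived parameters
    (phase parameters, concentration limits, N_0.5), mirroring the standard
    reporting layout."""
    rows = []
    for site, sp in params.items():
        for fraction in FRACTIONS:
            d = derive_secondary(sp, fraction)
            rows.append({
                "site": site, "fraction": fraction,
                "A": sp.amplitude(fraction, "biomass"),
                "A_N": sp.amplitude(fraction, "n_uptake"),
                "b": sp.b, "b_N": sp.b_N, "c": sp.c,
                "delta_b": d.delta_b, "N_cm": d.N_cm, "N_cl": d.N_cl,
                "Y_m": d.Y_m, "k_N": d.k_N,
                "N_half": d.N_half, "Y_at_N_half": d.Y_at_N_half,
            })
    return pd.DataFrame(rows)


def report(fits: Sequence[ELMResults], anova=None, out_dir=".",
           data: Optional[Sequence[ResponseSeries]] = None,
           plots: bool = False) -> List[Path]:
    """Write the standard result tables (and optionally figures).

    Emits five files: primary parameters, phase parameters, invariant-group
    parameters, per-series goodness of fit, and the ANOVA table (a
    placeholder note when no comparison was supplied).  Returns the paths
    written.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("report requires at least one fit result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    primary_rows, phase_rows, invariant_rows, gof_rows = [], [], [], []
    for res in fits:
        tbl = derived_table(res.params)
        tbl.insert(0, "mode", res.mode)
        primary_rows.append(tbl[["mode", "site", "fraction", "A", "A_N", "b", "b_N", "c"]])
        phase_rows.append(tbl[["mode", "site", "fraction", "Y_m", "k_N", "N_half", "Y_at_N_half"]])
        if res.shared:
            for name, value in res.shared.items():
                invariant_rows.append({"mode": res.mode, "parameter": name, "estimate": value})
            for fraction, key in ((("grain"), "N_cm_g"), (("total"), "N_cm_t")):
                if key in res.shared and "delta_b" in res.shared:
                    invariant_rows.append({
                        "mode": res.mode, "parameter": f"N_cl_{fraction[0]}",
                        "estimate": res.shared[key] * float(np.exp(-res.shared["delta_b"])),
                    })
        else:
            for _, row in tbl.iterrows():
                invariant_rows.append({
                    "mode": res.mode,
                    "parameter": f"delta_b[{row['site']}]",
                    "estimate": row["delta_b"],
                })
        for d in res.per_series:
            gof_rows.append({"mode": res.mode, **d})

    tables = {
        "parameters_primary.csv": pd.concat(primary_rows, ignore_index=True),
        "parameters_phase.csv": pd.concat(phase_rows, ignore_index=True),
        "parameters_invariant.csv": pd.DataFrame(invariant_rows),
        "goodness_of_fit.csv": pd.DataFrame(gof_rows),
    }
    for name, frame in tables.items():
        p = out / name
        frame.to_csv(p, index=False)
        written.append(p)

    anova_path = out / "anova.md"
    if anova is not None:
        anova_path.write_text(anova.to_markdown_table() + "\n")
        anova.to_dataframe().to_csv(out / "anova.csv", index=False)
        written.append(out / "anova.csv")
    else:
        anova_path.write_text("No nested-mode comparison was requested.\n")
    written.append(anova_path)

    if plots:
        from .plotting import plot_fit

        for res in fits:
            fig = plot_fit(res, data if data is not None else res.data)
            p = out / f"curves_mode_{res.mode}.png"
            fig.savefig(p, dpi=150)
            written.append(p)
    return written
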