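"""Plain-text input/output: TSV tables, GMT gene sets, JSON fit results.

All tabular outputs are TSV with optional ``#``-prefixed metadata header
lines; gene-set collections use the standard GMT format (name, optional
description, then member symbols, tab-separated, one set per line).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exposure import ExposureCondition, cumulative_dose, printed_dose
from .kinetics import FitResult, TimeSeries
from .omics import DeregEntry, DeregulationList, EnrichmentRow, GeneSet
from .trends import TrendComparison, TrendFit

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_dereg_list", "read_dereg_list",
    "write_gmt", "read_gmt",
    "fit_result_to_dict", "write_fit_results", "fit_results_table",
    "dose_table", "trend_table", "enrichment_table",
]

TIMESERIES_COLUMNS = ["condition", "endpoint", "week", "mean", "sem", "n"]
DEREG_COLUMNS = ["condition", "layer", "identifier", "direction", "log_ratio"]


def write_timeseries(series: Iterable[TimeSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame({
            "condition": s.condition, "endpoint": s.endpoint,
            "week": s.t, "mean": s.mean, "sem": s.sem, "n": s.n.astype(int),
        })
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path) -> list[TimeSeries]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TIMESERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (cond, endpoint), grp in df.groupby(["condition", "endpoint"], sort=False):
        grp = grp.sort_values("week")
        out.append(TimeSeries(str(cond), str(endpoint), grp["week"].to_numpy(),
                              grp["mean"].to_numpy(), grp["sem"].to_numpy(),
                              grp["n"].to_numpy()))
    return out


def write_dereg_list(lists: Iterable[DeregulationList], path: str | Path) -> None:
    rows = [
        {"condition": dl.condition, "layer": dl.layer, "identifier": e.identifier,
         "direction": e.direction,
         "log_ratio": "" if e.magnitude is None else e.magnitude}
        for dl in lists for e in dl.entries
    ]
    pd.DataFrame(rows, columns=DEREG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dereg_list(path: str | Path) -> list[DeregulationList]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(DEREG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (cond, layer), grp in df.groupby(["condition", "layer"], sort=False):
        entries = tuple(
            DeregEntry(
                str(row.identifier),
                int(row.direction) if not pd.isna(row.direction) else 0,
                None if pd.isna(row.log_ratio) else float(row.log_ratio),
            )
            for row in grp.itertuples()
        )
        out.append(DeregulationList(str(cond), str(layer), entries))
    return out


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.members)]) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not line.strip():
                continue
            sets.append(GeneSet(parts[0], frozenset(parts[2:])))
    return sets


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "condition": fit.condition,
        "endpoint": fit.endpoint,
        "params": {n: getattr(fit.params, n)
                   for n in fit.params.__dataclass_fields__},
        "param_sd": fit.param_sd,
        "dof": fit.dof,
        "weighted_rss": None if np.isnan(fit.weighted_rss) else fit.weighted_rss,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
    }


def write_fit_results(fits: Sequence[FitResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([fit_result_to_dict(f) for f in fits], fh, indent=2)


def fit_results_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Human-readable per-condition parameter table (value +/- SD, dof)."""
    rows = []
    for f in fits:
        row: dict = {"condition": f.condition, "endpoint": f.endpoint,
                     "dof": f.dof, "converged": f.converged}
        for name in f.free_names:
            value = getattr(f.params, name)
            sd = f.param_sd.get(name, float("nan"))
            row[name] = value
            row[f"{name}_sd"] = sd
            row[f"{name}_pct_error"] = 100 * sd / value if value else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def dose_table(conditions: Sequence[ExposureCondition]) -> pd.DataFrame:
    """Per-condition cumulative dose, unrounded and at reporting precision."""
    return pd.DataFrame({
        "condition": [c.label for c in conditions],
        "dose_rate_mGy_h": [c.dose_rate for c in conditions],
        "duration_weeks": [c.duration for c in conditions],
        "cumulative_dose_Gy": [cumulative_dose(c) for c in conditions],
        "printed_dose_Gy": [printed_dose(cumulative_dose(c)) for c in conditions],
    })


def trend_table(entries: Sequence[tuple[str, TrendFit, TrendComparison | None]]
                ) -> pd.DataFrame:
    rows = []
    for endpoint, fit, cmp_ in entries:
        coef = list(fit.coefficients) + [float("nan")] * (3 - len(fit.coefficients))
        sd = list(fit.coefficient_sd) + [float("nan")] * (3 - len(fit.coefficient_sd))
        rows.append({
            "endpoint": endpoint, "degree": fit.degree,
            "intercept": coef[0], "intercept_sd": sd[0],
            "linear": coef[1], "linear_sd": sd[1],
            "quadratic": coef[2], "quadratic_sd": sd[2],
            "weighted_rss": fit.weighted_rss, "dof": fit.dof,
            "F": cmp_.f_statistic if cmp_ else float("nan"),
            "p": cmp_.p_value if cmp_ else float("nan"),
            "preferred_degree": cmp_.preferred_degree if cmp_ else fit.degree,
        })
    return pd.DataFrame(rows)


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "pathway": [r.set_name for r in rows],
        "set_size": [r.set_size for r in rows],
        "hits": [r.hits for r in rows],
        "p_value": [r.p_value for r in rows],
        "fdr": [r.fdr for r in rows],
        "hit_identifiers": [";".join(sorted(r.hit_ids)) for r in rows],
    })
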