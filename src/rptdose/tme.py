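"""Derived tumor-microenvironment immune metrics.

Operates on tidy tables (pandas DataFrames or CSV) with columns
``group, day, animal_id, population, value`` where ``value`` is an immune
population frequency (% of parent gate) or an analyte concentration (pg/mL).

Metrics: the CD8/Treg ratio (cytotoxic-to-regulatory T cell balance — higher
reads as a more pro-inflammatory microenvironment), log2 fold change of group
means versus vehicle controls, and the t-distribution confidence interval of
the control mean used as the reference band in time-course plots.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "validate_population_table",
    "cd8_treg_ratio",
    "log2_fold_change",
    "control_interval",
]

REQUIRED_COLUMNS = ["group", "day", "animal_id", "population", "value"]
CONTROL_GROUP = "control"


def validate_population_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"population table missing columns {missing}")
    if (table["value"] < 0).any():
        bad = table.loc[table["value"] < 0].iloc[0]
        raise ValueError(f"negative value for {bad['population']!r} in group {bad['group']!r}")
    return table


def _stratum(table: pd.DataFrame, group, day) -> pd.DataFrame:
    sel = table[(table["group"] == group) & (table["day"] == day)]
    if sel.empty:
        raise ValueError(f"no rows for group={group!r}, day={day!r}")
    return sel


def cd8_treg_ratio(
    table: pd.DataFrame,
    group,
    day,
    cd8_population: str = "CD8",
    treg_population: str = "Treg",
) -> dict:
    """Per-animal CD8/Treg ratios for one group × day stratum.

    Returns ``{"per_animal": {animal: ratio}, "mean": …, "sd": …}``. Animals
    with a zero Treg frequency yield an infinite ratio; these are flagged with
    a warning and excluded from the mean/SD.
    """
    validate_population_table(table)
    sel = _stratum(table, group, day)
    cd8 = sel[sel["population"] == cd8_population].set_index("animal_id")["value"]
    treg = sel[sel["population"] == treg_population].set_index("animal_id")["value"]
    animals = cd8.index.intersection(treg.index)
    if animals.empty:
        raise ValueError(f"need both {cd8_population!r} and {treg_population!r} in group={group!r}, day={day!r}")
    per_animal: dict[str, float] = {}
    finite: list[float] = []
    for a in animals:
        if treg[a] == 0:
            warnings.warn(f"animal {a!r}: Treg frequency 0, infinite ratio excluded from mean", stacklevel=2)
            per_animal[a] = math.inf
        else:
            per_animal[a] = float(cd8[a] / treg[a])
            finite.append(per_animal[a])
    mean = float(np.mean(finite)) if finite else math.nan
    sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else math.nan
    return {"per_animal": per_animal, "mean": mean, "sd": sd, "n": len(finite)}


def log2_fold_change(
    table: pd.DataFrame,
    analyte: str,
    group,
    day,
    control_group=CONTROL_GROUP,
) -> float:
    """log2(mean(treated) / mean(control)) for one analyte at one day."""
    validate_population_table(table)
    treated = _stratum(table, group, day)
    control = _stratum(table, control_group, day)
    t_vals = treated.loc[treated["population"] == analyte, "value"]
    c_vals = control.loc[control["population"] == analyte, "value"]
    if t_vals.empty or c_vals.empty:
        raise ValueError(f"analyte {analyte!r} missing in treated or control stratum (day {day!r})")
    c_mean = float(c_vals.mean())
    if c_mean <= 0:
        raise ValueError(f"control mean for {analyte!r} must be > 0, got {c_mean}")
    # log difference rather than log of the quotient: keeps the swap of
    # treated and control exactly antisymmetric in floating point
    return float(np.log2(float(t_vals.mean())) - np.log2(c_mean))


def control_interval(
    table: pd.DataFrame,
    population: str,
    level: float = 0.95,
    control_group=CONTROL_GROUP,
    day=None,
) -> tuple[float, float]:
    """t-distribution CI of the control mean (the gray reference band).

    Pools control animals across days unless ``day`` is given; requires ≥ 2
    control values. ``level=0`` degenerates to (mean, mean).
    """
    validate_population_table(table)
    sel = table[table["group"] == control_group]
    if day is not None:
        sel = sel[sel["day"] == day]
    vals = sel.loc[sel["population"] == population, "value"].to_numpy(float)
    if len(vals) < 2:
        raise ValueError(f"need ≥ 2 control values for {population!r}, got {len(vals)}")
    if not 0.0 <= level < 1.0:
        raise ValueError(f"level must be in [0, 1), got {level}")
    mean = float(np.mean(vals))
    sem = float(np.std(vals, ddof=1)) / math.sqrt(len(vals))
    if level == 0.0 or sem == 0.0:
        return (mean, mean) if level == 0.0 else (mean - 0.0, mean + 0.0)
    half = float(stats.t.ppf(0.5 + level / 2.0, df=len(vals) - 1)) * sem
    return (mean - half, mean + half)
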