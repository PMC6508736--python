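"""Donor cohort summary arithmetic with explicit missing-data and rounding
rules.

Means are computed per histology group (CS / SCO) over non-missing values
only and rounded half-up to per-field decimals: age and weight to 1
decimal, FSH to 2 decimals.  Egg and embryo means are reported both raw
(2 decimals) and rounded to the nearest integer, mirroring the mixed
precision conventionally used in clinical tables.  Height strings
(feet'inches") are parsed for completeness but excluded from means, since a
modal height string is not a defined arithmetic mean.
"""

from __future__ import annotations

import math
import re
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .data_io import GROUPS

DEFAULT_ROUNDING = {
    "age": 1,
    "weight_lbs": 1,
    "fsh_miu_ml": 2,
    "eggs_injected": 2,
    "embryos": 2,
}

#: Fields whose mean is additionally reported rounded to the nearest integer.
INTEGER_REPORTED = ("eggs_injected", "embryos")

_HEIGHT_RE = re.compile(r"^\s*(\d+)'\s*(\d+(?:\.\d+)?)\"?\s*$")


def round_half_up(value: float, decimals: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def parse_height(height: str) -> float:
    """Parse a feet'inches" string into total inches (NaN if unparseable)."""
    if not isinstance(height, str):
        return float("nan")
    m = _HEIGHT_RE.match(height)
    if not m:
        return float("nan")
    return int(m.group(1)) * 12 + float(m.group(2))


def summarize_cohort(
    samples: pd.DataFrame,
    rounding: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-group donor summary: n, rounded means and missing counts.

    Every group in {CS, SCO} must have at least one donor.  Row order of
    the input never affects the result.
    """
    rounding = dict(DEFAULT_ROUNDING if rounding is None else rounding)
    fields = [f for f in rounding if f in samples.columns]
    present = set(samples["group"])
    absent = [g for g in GROUPS if g not in present]
    if absent:
        raise ValueError(f"groups with zero donors: {absent}")
    rows = []
    for group in GROUPS:
        sub = samples[samples["group"] == group]
        row: dict[str, object] = {"group": group, "n": len(sub)}
        for f in fields:
            vals = pd.to_numeric(sub[f], errors="coerce")
            n_missing = int(vals.isna().sum())
            row[f"{f}_missing"] = n_missing
            if n_missing == len(sub):
                row[f"{f}_mean"] = float("nan")
            else:
                mean = float(vals.mean())
                row[f"{f}_mean"] = round_half_up(mean, rounding[f])
                if f in INTEGER_REPORTED:
                    row[f"{f}_mean_int"] = int(round_half_up(mean, 0))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("group")
    return out
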