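"""Packaged transcriptions of the published province-level result tables and
summary operations over them.

Five CSVs ship with the package: per-province sample sizes (``table4``) and
per-province prevalence estimates with 95% CI and MSE for the direct
(``table5``), post-stratified synthetic (``table6``), composite
(``table7``) and hierarchical Bayes (``table8``) methods, each for the
total, male and female populations across the 31 provinces of Iran.

``table5`` is transcribed verbatim but carries a ``suspect`` flag: its Male
CI columns are internally inconsistent in the published source (upper bound
below the point estimate on most rows) and its point estimates duplicate
the hierarchical-Bayes table, so the direct table should not be treated as
an independent source of truth.

Printed percentages follow round-half-away-from-zero to one decimal.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SOURCES",
    "load_table",
    "table4_sample_sizes",
    "summarize_table",
    "count_small_areas",
    "mse_ci_consistency",
    "percent",
]

SOURCES = {
    "table4": "table4_sample_sizes.csv",
    "table5": "table5_direct.csv",
    "table6": "table6_pssyn.csv",
    "table7": "table7_composite.csv",
    "table8": "table8_hb.csv",
}

METHOD_OF = {"table5": "direct", "table6": "psyn",
             "table7": "composite", "table8": "hb"}

N_AREAS = 31
GROUPS = ("total", "male", "female")


def percent(x: float, decimals: int = 1) -> float:
    """Value as a percentage, rounded half-away-from-zero (the published
    convention, unlike banker's rounding)."""
    scale = 10.0**decimals
    v = x * 100.0 * scale
    return float(np.sign(v) * np.floor(np.abs(v) + 0.5) / scale)


def load_table(source: str) -> pd.DataFrame:
    """Load and validate one packaged table by its short name."""
    if source not in SOURCES:
        raise ValueError(f"unknown table {source!r}; choose from {sorted(SOURCES)}")
    ref = resources.files("saeprev.fixtures") / "data" / SOURCES[source]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if len(df) != N_AREAS:
        raise ValueError(f"{source}: expected {N_AREAS} rows, found {len(df)}")
    if df["area_id"].duplicated().any():
        raise ValueError(f"{source}: duplicated provinces")
    if source == "table4":
        if not (df["n_male"] + df["n_female"] == df["n_total"]).all():
            raise ValueError("table4: male + female != total")
    df.attrs["source"] = source
    df.attrs["suspect"] = source == "table5"
    return df


def table4_sample_sizes(group: str = "total") -> pd.Series:
    """Per-province sample sizes from the published design table."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    df = load_table("table4")
    return df.set_index("area_id")[f"n_{group}"]


def summarize_table(fixture: pd.DataFrame | str, group: str = "total") -> dict:
    """Order statistics of the 31 estimates and their CI widths.

    Median is the middle order statistic (31 rows, so the 16th).
    """
    if isinstance(fixture, str):
        fixture = load_table(fixture)
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    est = fixture[f"est_{group}"].to_numpy(dtype=float)
    width = (fixture[f"hi_{group}"] - fixture[f"lo_{group}"]).to_numpy(dtype=float)
    return {
        "min": float(est.min()),
        "max": float(est.max()),
        "median": float(np.median(est)),
        "ci_width_min": float(width.min()),
        "ci_width_max": float(width.max()),
        "ci_width_median": float(np.median(width)),
        "n_rows": int(len(fixture)),
    }


def count_small_areas(threshold: float = 450,
                      table4: pd.DataFrame | None = None) -> int:
    """Number of provinces whose total sample is below ``threshold`` (the
    conventional minimum for a stable direct estimate)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    df = load_table("table4") if table4 is None else table4
    return int((df["n_total"] < threshold).sum())


def mse_ci_consistency(fixture: pd.DataFrame | str, group: str = "total",
                       tolerance: float = 0.15) -> pd.DataFrame:
    """Check the Wald identity mse = ((U - L) / 3.92)^2 on a printed table.

    Returns a per-province frame with the implied MSE, the printed MSE and
    the relative deviation; rows beyond ``tolerance`` (default 0.15, sized
    for 3-decimal CI rounding) are flagged. The frame's ``max_deviation``
    attr gives the worst row.
    """
    if isinstance(fixture, str):
        fixture = load_table(fixture)
    width = fixture[f"hi_{group}"] - fixture[f"lo_{group}"]
    implied = (width / 3.92) ** 2
    printed = fixture[f"mse_{group}"].astype(float)
    dev = (implied - printed).abs() / printed
    out = pd.DataFrame({
        "area_id": fixture["area_id"],
        "implied_mse": implied,
        "printed_mse": printed,
        "relative_deviation": dev,
        "flagged": dev > tolerance,
    })
    out.attrs["max_deviation"] = float(dev.max())
    return out
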