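"""Validation of small-area estimates against region-level direct estimates.

Small-area methods cannot be checked area-by-area (the areas have no
reliable reference), so area estimates are aggregated to a small number of
regions whose pooled samples are large enough for a stable direct estimate,
and the two region vectors are compared with distance / association
statistics: MSE, mean absolute difference (MAD), mean relative absolute
difference (MRAD), a rank statistic (RS, the normalized Spearman footrule
mean|rank(e) - rank(d)| / (R - 1), average ranks on ties), and the Pearson
correlation coefficient (CC). All four distance measures are 0 and CC is 1
when the aggregated estimates equal the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiscrepancyReport",
    "aggregate_to_regions",
    "discrepancy",
    "external_correlation",
    "cv_profile",
]


@dataclass
class DiscrepancyReport:
    """Region-level discrepancy statistics versus a reference vector."""

    mse: float
    mad: float
    mrad: float
    rs: float
    cc: float          # NaN when either vector is constant
    n_regions: int

    def as_dict(self) -> dict:
        return {"mse": self.mse, "mad": self.mad, "mrad": self.mrad,
                "rs": self.rs, "cc": self.cc, "n_regions": self.n_regions}


def aggregate_to_regions(area_estimates: pd.DataFrame,
                         region_map: pd.DataFrame) -> pd.Series:
    """Population-weighted aggregation P_r = sum_i N_i p_i / sum_i N_i.

    ``region_map`` needs columns area_id, region_id, population; every
    estimated area must be mapped.
    """
    need = {"area_id", "region_id", "population"}
    if not need <= set(region_map.columns):
        raise ValueError(f"region_map needs columns {sorted(need)}")
    if (region_map["population"] <= 0).any():
        raise ValueError("region populations must be positive")
    est = area_estimates.set_index("domain_id")["estimate"]
    unmapped = sorted(set(est.index) - set(region_map["area_id"]))
    if unmapped:
        raise ValueError(f"areas missing from region map: {unmapped}")
    rm = region_map.set_index("area_id").loc[est.index]
    w = rm["population"].astype(float)
    num = (w * est).groupby(rm["region_id"].to_numpy()).sum()
    den = w.groupby(rm["region_id"].to_numpy()).sum()
    out = (num / den).sort_index()
    out.name = "estimate"
    return out


def discrepancy(estimates: pd.Series | np.ndarray,
                reference: pd.Series | np.ndarray) -> DiscrepancyReport:
    """Discrepancy statistics between aligned region vectors."""
    e = np.asarray(estimates, dtype=float)
    d = np.asarray(reference, dtype=float)
    if (isinstance(estimates, pd.Series) and isinstance(reference, pd.Series)
            and not estimates.index.equals(reference.index)):
        d = np.asarray(reference.reindex(estimates.index), dtype=float)
    if e.shape != d.shape or e.ndim != 1:
        raise ValueError("estimates and reference must be aligned 1-d vectors")
    if e.size < 2:
        raise ValueError("need at least 2 regions")
    if np.any(d == 0):
        raise ValueError("zero reference value: MRAD undefined")
    diff = e - d
    R = e.size
    re = stats.rankdata(e)
    rd = stats.rankdata(d)
    cc = float("nan") if (np.ptp(e) == 0 or np.ptp(d) == 0) \
        else float(np.corrcoef(e, d)[0, 1])
    return DiscrepancyReport(
        mse=float(np.mean(diff**2)),
        mad=float(np.mean(np.abs(diff))),
        mrad=float(np.mean(np.abs(diff) / d)),
        rs=float(np.mean(np.abs(re - rd)) / (R - 1)),
        cc=cc,
        n_regions=R)


def external_correlation(area_estimates: pd.Series, external_scores: pd.Series,
                         outlier_rule: str = "iqr-1.5") -> tuple[float, list]:
    """Pearson correlation with an external per-area score after outlier
    removal.

    ``outlier_rule``: "none", "iqr-1.5" (outside 1.5 IQR fences on either
    vector) or "z-3" (|z| > 3 on either vector). Returns (r, removed_areas).
    """
    if outlier_rule not in ("none", "iqr-1.5", "z-3"):
        raise ValueError(f"unknown outlier rule {outlier_rule!r}")
    e = area_estimates.astype(float)
    s = external_scores.reindex(e.index).astype(float)

    def flags(x: pd.Series) -> pd.Series:
        if outlier_rule == "none":
            return pd.Series(False, index=x.index)
        if outlier_rule == "iqr-1.5":
            q1, q3 = x.quantile([0.25, 0.75])
            iqr = q3 - q1
            return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
        z = (x - x.mean()) / x.std(ddof=1)
        return z.abs() > 3

    drop = flags(e) | flags(s)
    removed = sorted(e.index[drop])
    e, s = e[~drop], s[~drop]
    if len(e) < 3:
        raise ValueError("fewer than 3 areas remain after outlier removal")
    return float(np.corrcoef(e, s)[0, 1]), removed


def cv_profile(estimate_sets: dict[str, pd.DataFrame],
               sample_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Long-format (area, n, method, cv) table sorted by increasing sample
    size (ties broken by area_id), for CV-versus-n comparison plots.

    ``estimate_sets`` maps a method name to its per-area estimate frame;
    all methods must cover the same areas. Sample sizes default to the ``n``
    column of the first method.
    """
    methods = list(estimate_sets)
    base = estimate_sets[methods[0]].set_index("domain_id")
    areas = set(base.index)
    for m in methods[1:]:
        cover = set(estimate_sets[m]["domain_id"])
        if cover != areas:
            raise ValueError(f"method {m!r} does not cover all areas")
    n = (base["n"] if sample_sizes is None
         else sample_sizes.reindex(base.index)).astype(int)
    rows = []
    for m in methods:
        df = estimate_sets[m].set_index("domain_id")
        for area in base.index:
            rows.append({"area_id": area, "n": int(n[area]), "method": m,
                         "cv": float(df.loc[area, "cv"])})
    out = pd.DataFrame(rows).sort_values(["n", "area_id"], kind="stable")
    return out.reset_index(drop=True)
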