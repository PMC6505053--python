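"""Post-stratified synthetic and composite small-area estimators.

The synthetic estimator assumes post-stratum rates are exchangeable across
areas: the national design-weighted rate of each post-stratum g is pushed
through the area's census composition,

    p_syn,i = sum_g (N_ig / N_i) p_hat_g,

giving very low variance but a bias that grows with real between-area
heterogeneity. Its MSE is estimated area-specifically from the contrast with
the (unbiased) direct estimate,

    mse_syn,i = max(0, (p_syn,i - p_dir,i)^2 - v(p_dir,i)),

optionally smoothed by averaging the un-truncated contrast over areas.

The composite estimator is the convex combination

    p_comp,i = phi_i p_dir,i + (1 - phi_i) p_syn,i,
    phi_i = mse_syn,i / (mse_syn,i + mse_dir,i),

the MSE-optimal weight under independent errors (0/0 resolved to 1/2); a
sample-size weight phi_i = n_i / (n_i + delta) is available as an
alternative. Its reported MSE is phi^2 mse_dir + (1-phi)^2 mse_syn, ignoring
the error covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .direct import (ESTIMATE_COLUMNS, DirectEstimator, wald_interval,
                     weighted_prevalence)

__all__ = [
    "CompositeWeights",
    "poststratified_synthetic",
    "synthetic_mse",
    "composite",
    "PostStratifiedSynthetic",
    "CompositeEstimator",
]


@dataclass
class CompositeWeights:
    """Per-area composite weight phi on the direct component."""

    phi: pd.Series            # indexed by area_id, in [0, 1]
    provenance: str           # which MSE inputs produced it


def _stratum_key(df: pd.DataFrame, strata_factors: list[str]) -> pd.Series:
    return df[list(strata_factors)].astype(str).agg(":".join, axis=1)


def poststratified_synthetic(survey: pd.DataFrame, census: pd.DataFrame,
                             strata_factors: list[str],
                             clip01: bool = False) -> pd.DataFrame:
    """Post-stratified synthetic estimate per area, with the naive variance
    sum_g (N_ig/N_i)^2 v(p_hat_g) carried through a Wald interval.

    Every census stratum with positive population must have at least one
    sampled unit nationally; otherwise the offending strata are listed.
    """
    missing_cols = [f for f in strata_factors if f not in census.columns]
    if missing_cols:
        raise ValueError(f"strata factors not in census: {missing_cols}")

    s_key = _stratum_key(survey, strata_factors)
    nat = {}
    for g, grp in survey.groupby(s_key.to_numpy()):
        nat[g] = weighted_prevalence(grp, domain_id=str(g), method="national")
    c_key = _stratum_key(census, strata_factors)
    counts = census.groupby([census["area_id"], c_key.to_numpy()])["count"].sum()

    needed = {g for (_, g), N in counts.items() if N > 0}
    unsampled = sorted(needed - set(nat))
    if unsampled:
        raise ValueError(f"strata with zero national sample: {unsampled}")

    n_area = survey.groupby("area_id").size()
    rows = []
    for area in pd.unique(census["area_id"]):
        sub = counts.loc[area]
        N_i = sub.sum()
        share = sub / N_i
        est = float(sum(share[g] * nat[g].estimate for g in sub.index if sub[g] > 0))
        var = float(sum(share[g] ** 2 * nat[g].mse for g in sub.index if sub[g] > 0))
        lo, hi = wald_interval(est, var, clip01=clip01)
        cv = float(np.sqrt(var) / est) if est > 0 else float("nan")
        rows.append({"domain_id": area, "method": "psyn", "estimate": est,
                     "mse": var, "ci_low": lo, "ci_high": hi, "cv": cv,
                     "n": int(n_area.get(area, 0))})
    return pd.DataFrame(rows)[ESTIMATE_COLUMNS]


def synthetic_mse(syn_estimates: pd.DataFrame, dir_estimates: pd.DataFrame,
                  smoothed: bool = False) -> pd.Series:
    """Design-based MSE of the synthetic estimator from its contrast with the
    direct estimator.

    Area-specific form: max(0, (p_syn - p_dir)^2 - v_dir) per area; the
    truncation at 0 absorbs the sampling noise of the contrast. The smoothed
    form replaces every area's value with the over-area average of the
    un-truncated contrast (then truncates once), trading area detail for
    stability. Areas lacking a direct estimate get NaN and are reported via
    the ``flagged`` attribute of the result.
    """
    syn = syn_estimates.set_index("domain_id")
    dire = dir_estimates.set_index("domain_id")
    contrast = (syn["estimate"] - dire["estimate"].reindex(syn.index)) ** 2 \
        - dire["mse"].reindex(syn.index)
    if smoothed:
        out = pd.Series(max(0.0, float(contrast.mean())), index=syn.index)
        out[contrast.isna()] = np.nan
    else:
        out = contrast.clip(lower=0.0)
    out.name = "mse_syn"
    out.attrs["flagged"] = sorted(contrast.index[contrast.isna()])
    return out


def composite(dir_estimates: pd.DataFrame, syn_estimates: pd.DataFrame,
              mse_dir: pd.Series | None = None,
              mse_syn: pd.Series | None = None,
              clip01: bool = False) -> tuple[pd.DataFrame, CompositeWeights]:
    """Composite (convex-combination) estimate per area.

    ``mse_dir`` / ``mse_syn`` default to the ``mse`` columns of the two
    estimate frames; all inputs are aligned by domain_id.
    """
    dire = dir_estimates.set_index("domain_id")
    syn = syn_estimates.set_index("domain_id").reindex(dire.index)
    a = (dire["mse"] if mse_dir is None else mse_dir.reindex(dire.index)).astype(float)
    b = (mse_syn.reindex(dire.index).astype(float) if mse_syn is not None
         else syn["mse"].astype(float))
    if (a < 0).any() or (b < 0).any():
        raise ValueError("MSE inputs must be non-negative")

    with np.errstate(invalid="ignore"):
        phi = b / (a + b)
    phi[(a + b) == 0] = 0.5
    est = phi * dire["estimate"] + (1 - phi) * syn["estimate"]
    mse = phi**2 * a + (1 - phi) ** 2 * b

    rows = []
    for area in dire.index:
        lo, hi = wald_interval(float(est[area]), float(mse[area]), clip01=clip01)
        e = float(est[area])
        rows.append({"domain_id": area, "method": "composite", "estimate": e,
                     "mse": float(mse[area]), "ci_low": lo, "ci_high": hi,
                     "cv": float(np.sqrt(mse[area]) / e) if e > 0 else float("nan"),
                     "n": int(dire.loc[area, "n"])})
    weights = CompositeWeights(phi=phi.rename("phi"),
                               provenance="mse_syn/(mse_syn+mse_dir)")
    return pd.DataFrame(rows)[ESTIMATE_COLUMNS], weights


class PostStratifiedSynthetic(BaseEstimator):
    """Post-stratified synthetic estimator as a fit-shaped class.

    Parameters
    ----------
    census : DataFrame
        Area x cell population table (area_id, cell_id, factors..., count).
    strata_factors : list of str
        Census factors defining the post-strata (typically the screened
        predictors).
    mse_method : {"rao", "rao-smoothed", "naive"}
        Reported MSE: the direct-contrast estimator (default), its smoothed
        variant, or the naive aggregation variance only.

    Attributes
    ----------
    estimates_ : per-area DomainEstimate frame (method tag "psyn").
    """

    def __init__(self, census: pd.DataFrame = None,
                 strata_factors: list[str] | None = None,
                 mse_method: str = "rao", clip01: bool = False):
        self.census = census
        self.strata_factors = strata_factors
        self.mse_method = mse_method
        self.clip01 = clip01

    def fit(self, X: pd.DataFrame, y=None) -> "PostStratifiedSynthetic":
        if self.mse_method not in ("rao", "rao-smoothed", "naive"):
            raise ValueError(f"unknown mse_method {self.mse_method!r}")
        syn = poststratified_synthetic(X, self.census, self.strata_factors,
                                       clip01=self.clip01)
        if self.mse_method != "naive":
            dire = DirectEstimator().fit(X).estimates_
            mse = synthetic_mse(syn, dire,
                                smoothed=self.mse_method == "rao-smoothed")
            syn = syn.copy()
            syn["mse"] = mse.reindex(syn["domain_id"]).to_numpy()
            ci = [wald_interval(e, m, clip01=self.clip01) if np.isfinite(m)
                  else (np.nan, np.nan)
                  for e, m in zip(syn["estimate"], syn["mse"])]
            syn[["ci_low", "ci_high"]] = ci
            with np.errstate(invalid="ignore"):
                syn["cv"] = np.sqrt(syn["mse"]) / syn["estimate"]
        self.estimates_ = syn
        return self

    def predict(self, domains=None) -> pd.Series:
        est = self.estimates_.set_index("domain_id")["estimate"]
        return est if domains is None else est.reindex(domains)


class CompositeEstimator(BaseEstimator):
    """Composite of the direct and post-stratified synthetic estimators.

    ``phi_method="mse"`` uses the MSE-optimal weight; ``"sample-size"`` uses
    phi_i = n_i / (n_i + delta).

    Attributes
    ----------
    estimates_ : per-area DomainEstimate frame (method tag "composite").
    phi_ : Series of composite weights on the direct component.
    components_ : dict with the underlying "direct" and "psyn" frames.
    """

    def __init__(self, census: pd.DataFrame = None,
                 strata_factors: list[str] | None = None,
                 phi_method: str = "mse", delta: float = 100.0,
                 clip01: bool = False):
        self.census = census
        self.strata_factors = strata_factors
        self.phi_method = phi_method
        self.delta = delta
        self.clip01 = clip01

    def fit(self, X: pd.DataFrame, y=None) -> "CompositeEstimator":
        if self.phi_method not in ("mse", "sample-size"):
            raise ValueError(f"unknown phi_method {self.phi_method!r}")
        dire = DirectEstimator(clip01=self.clip01).fit(X).estimates_
        syn = poststratified_synthetic(X, self.census, self.strata_factors,
                                       clip01=self.clip01)
        mse_syn = synthetic_mse(syn, dire)
        if self.phi_method == "mse":
            comp, weights = composite(dire, syn, mse_syn=mse_syn,
                                      clip01=self.clip01)
        else:
            n = dire.set_index("domain_id")["n"].astype(float)
            phi = n / (n + self.delta)
            d = dire.set_index("domain_id")
            s = syn.set_index("domain_id").reindex(d.index)
            est = phi * d["estimate"] + (1 - phi) * s["estimate"]
            mse = phi**2 * d["mse"] + (1 - phi) ** 2 * mse_syn.reindex(d.index)
            rows = []
            for area in d.index:
                lo, hi = wald_interval(float(est[area]), float(mse[area]),
                                       clip01=self.clip01)
                e = float(est[area])
                rows.append({"domain_id": area, "method": "composite",
                             "estimate": e, "mse": float(mse[area]),
                             "ci_low": lo, "ci_high": hi,
                             "cv": float(np.sqrt(mse[area]) / e) if e > 0
                             else float("nan"),
                             "n": int(d.loc[area, "n"])})
            comp = pd.DataFrame(rows)[ESTIMATE_COLUMNS]
            weights = CompositeWeights(phi=phi.rename("phi"),
                                       provenance=f"n/(n+{self.delta})")
        self.estimates_ = comp
        self.phi_ = weights.phi
        self.components_ = {"direct": dire, "psyn": syn}
        return self

    def predict(self, domains=None) -> pd.Series:
        est = self.estimates_.set_index("domain_id")["estimate"]
        return est if domains is None else est.reindex(domains)
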