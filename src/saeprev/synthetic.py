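"""Synthetic census and survey generator for a stratified national household
survey with post-stratified design weights.

The generator emulates the structure of a national mental-health household
survey: ~7,900 respondents aged 15-64 spread very unevenly over 31 provinces,
a census cross-classification of demographic post-strata per province, and a
binary diagnosis outcome driven by a logistic model with province-level
random intercepts,

    y_ij | v_i ~ Bernoulli( expit( x_g(j)' beta + v_i ) ),
    v_i ~ Normal(0, sigma_v^2),

where g(j) is the census post-stratum (cell) of unit j. True area prevalence
is the census-weighted cell prevalence

    P_i = sum_g (N_ig / N_i) * expit(x_g' beta + v_i),

which every estimator in this package is judged against.

Weights follow the exact post-stratified expansion w = N_ig / n_ig, so the
weights of a fully sampled area sum to its census population exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._rng import substream

__all__ = [
    "DEFAULT_FACTORS",
    "DEFAULT_MARGINALS",
    "DEFAULT_BETA",
    "TruthSpec",
    "generate_census",
    "generate_truth",
    "draw_survey",
    "design_matrix",
    "design_columns",
    "cell_prevalence",
]

#: Post-strata are the cross-classification of these factors (first level of
#: each factor is the reference level in the design encoding).
DEFAULT_FACTORS: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "age": ["15-29", "30-49", "50-64"],
    "residence": ["urban", "rural"],
}

#: Population marginal shares per factor level (national census shape).
DEFAULT_MARGINALS: dict[str, list[float]] = {
    "sex": [0.503, 0.497],
    "age": [0.469, 0.380, 0.151],
    "residence": [0.729, 0.271],
}

#: Default fixed effects on the logit scale: ~23.6% national prevalence, a
#: female odds ratio of ~1.39, a rural odds ratio of ~0.78, and a mild
#: decline at older ages.
DEFAULT_BETA: dict[str, float] = {
    "intercept": -1.23,
    "sex=female": 0.329,
    "age=30-49": -0.05,
    "age=50-64": -0.15,
    "residence=rural": -0.247,
}

DEFAULT_SIGMA_V = 0.3


def design_columns(factors: dict[str, list[str]]) -> list[str]:
    """Dummy-encoded design column names: intercept plus one ``factor=level``
    column per non-reference level, in factor order."""
    cols = ["intercept"]
    for name, levels in factors.items():
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} needs at least 2 levels")
        cols += [f"{name}={lv}" for lv in levels[1:]]
    return cols


def _cell_table(factors: dict[str, list[str]]) -> pd.DataFrame:
    """All cells of the cross-classification, with a canonical cell_id."""
    idx = pd.MultiIndex.from_product(list(factors.values()), names=list(factors))
    cells = idx.to_frame(index=False)
    cells.insert(0, "cell_id", cells.agg(":".join, axis=1))
    return cells


def design_matrix(cells: pd.DataFrame, factors: dict[str, list[str]]) -> pd.DataFrame:
    """Design matrix (one row per row of ``cells``) under dummy encoding."""
    X = pd.DataFrame(index=cells.index)
    X["intercept"] = 1.0
    for name, levels in factors.items():
        for lv in levels[1:]:
            X[f"{name}={lv}"] = (cells[name] == lv).astype(float)
    return X


def generate_census(
    n_areas: int = 31,
    factors: dict[str, list[str]] | None = None,
    mean_area_pop: int = 1_700_000,
    marginals: dict[str, list[float]] | None = None,
    area_pop_sigma: float = 0.6,
    composition_concentration: float = 300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an area x post-stratum census table.

    Per-area populations are lognormal around ``mean_area_pop`` (a few large
    metropolitan areas, many small ones); each area's cell composition is a
    Dirichlet perturbation of the national product-of-marginals shape, with
    larger ``composition_concentration`` meaning areas that look more alike.

    Returns a DataFrame with columns ``area_id, cell_id, <factor...>, count``
    covering the full cross-classification of every area.
    """
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    factors = dict(DEFAULT_FACTORS if factors is None else factors)
    if marginals is None:
        marginals = {
            k: (DEFAULT_MARGINALS[k] if k in DEFAULT_MARGINALS and
                len(DEFAULT_MARGINALS[k]) == len(v)
                else [1.0 / len(v)] * len(v))
            for k, v in factors.items()
        }
    for k, v in factors.items():
        if abs(sum(marginals[k]) - 1.0) > 1e-8 or len(marginals[k]) != len(v):
            raise ValueError(f"marginals for factor {k!r} must match levels and sum to 1")

    rng = substream(seed, "census")
    cells = _cell_table(factors)
    base = np.ones(len(cells))
    for name in factors:
        probs = dict(zip(factors[name], marginals[name]))
        base *= cells[name].map(probs).to_numpy()

    # heavier right tail: a handful of much larger areas
    pops = rng.lognormal(mean=np.log(mean_area_pop) - area_pop_sigma**2 / 2,
                         sigma=area_pop_sigma, size=n_areas)
    pops = np.maximum(pops.round().astype(np.int64), len(cells))

    frames = []
    for i in range(n_areas):
        area = f"area_{i + 1:02d}"
        shape = rng.dirichlet(composition_concentration * base)
        counts = rng.multinomial(pops[i], shape)
        if counts.sum() <= 0:
            raise ValueError(f"area {area} has zero total population")
        df = cells.copy()
        df.insert(0, "area_id", area)
        df["count"] = counts
        frames.append(df)
    census = pd.concat(frames, ignore_index=True)
    census.attrs["factors"] = factors
    return census


def _census_factors(census: pd.DataFrame,
                    factors: dict[str, list[str]] | None) -> dict[str, list[str]]:
    if factors is not None:
        return factors
    if "factors" in census.attrs:
        return census.attrs["factors"]
    # infer: every column that is not structural is a factor; observed level
    # order, reference = first seen
    out = {}
    for c in census.columns:
        if c in ("area_id", "cell_id", "count"):
            continue
        out[c] = list(pd.unique(census[c]))
    return out


@dataclass
class TruthSpec:
    """Realized simulation truth: fixed effects, area random intercepts and
    the implied census-weighted true prevalence per area."""

    beta: pd.Series                 # indexed by design column
    sigma_v: float
    v: pd.Series                    # indexed by area_id
    true_prevalence: pd.Series      # indexed by area_id
    factors: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area_id": self.v.index, "v": self.v.to_numpy(),
             "true_prevalence": self.true_prevalence.to_numpy()}
        )


def _beta_vector(beta, cols: list[str]) -> pd.Series:
    if isinstance(beta, dict):
        unknown = set(beta) - set(cols)
        if unknown:
            raise ValueError(f"unknown design columns in beta: {sorted(unknown)}")
        return pd.Series({c: float(beta.get(c, 0.0)) for c in cols})
    arr = np.asarray(beta, dtype=float)
    if arr.shape != (len(cols),):
        raise ValueError(
            f"beta has length {arr.size}, design implies {len(cols)} columns {cols}"
        )
    return pd.Series(arr, index=cols)


def cell_prevalence(census: pd.DataFrame, truth: "TruthSpec") -> pd.Series:
    """expit(x_g' beta + v_i) for every census row, aligned to ``census``."""
    factors = truth.factors or _census_factors(census, None)
    X = design_matrix(census, factors)
    eta = X.to_numpy() @ truth.beta.reindex(X.columns).to_numpy()
    eta = eta + census["area_id"].map(truth.v).to_numpy()
    return pd.Series(expit(eta), index=census.index)


def generate_truth(
    census: pd.DataFrame,
    beta: dict[str, float] | np.ndarray | None = None,
    sigma_v: float = DEFAULT_SIGMA_V,
    factors: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> TruthSpec:
    """Draw area random intercepts v_i ~ N(0, sigma_v^2) and compute the
    implied true prevalence of every area through its census composition."""
    if sigma_v < 0:
        raise ValueError("sigma_v must be >= 0")
    factors = _census_factors(census, factors)
    cols = design_columns(factors)
    if beta is None:
        beta = {k: b for k, b in DEFAULT_BETA.items() if k in cols}
    beta_s = _beta_vector(beta, cols)

    areas = list(pd.unique(census["area_id"]))
    rng = substream(seed, "truth")
    v = (rng.normal(0.0, sigma_v, size=len(areas)) if sigma_v > 0
         else np.zeros(len(areas)))
    truth = TruthSpec(beta=beta_s, sigma_v=float(sigma_v),
                      v=pd.Series(v, index=areas), true_prevalence=pd.Series(dtype=float),
                      factors=factors)

    p_cell = cell_prevalence(census, truth)
    w = census["count"].to_numpy(dtype=float)
    num = pd.Series(w * p_cell.to_numpy()).groupby(census["area_id"].to_numpy()).sum()
    den = pd.Series(w).groupby(census["area_id"].to_numpy()).sum()
    if (den <= 0).any():
        bad = den.index[den <= 0].tolist()
        raise ValueError(f"zero total population in areas: {bad}")
    truth.true_prevalence = (num / den).reindex(areas)
    return truth


def _allocate(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n draws over cells with the given
    nonnegative weights; never allocates to a zero-weight cell."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot allocate over all-zero weights")
    quota = n * w / total
    alloc = np.floor(quota).astype(int)
    short = n - alloc.sum()
    if short > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:short]] += 1
    return alloc


def draw_survey(
    census: pd.DataFrame,
    truth: TruthSpec,
    per_area_n: dict[str, int] | list[int] | int,
    allocation: str = "proportional",
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a stratified survey with post-stratified weights w = N_ig / n_ig.

    ``per_area_n`` gives the total sample size of each area (a dict keyed by
    area_id, a list in area order, or one int for all areas); it is allocated
    to cells either proportional to cell population (``"proportional"``) or
    as evenly as possible over non-empty cells (``"uniform"``). Outcomes are
    Bernoulli draws at the cell's true prevalence. Cells that receive no
    sample contribute no rows.
    """
    if allocation not in ("proportional", "uniform"):
        raise ValueError("allocation must be 'proportional' or 'uniform'")
    areas = list(pd.unique(census["area_id"]))
    if isinstance(per_area_n, int):
        n_by_area = {a: per_area_n for a in areas}
    elif isinstance(per_area_n, dict):
        n_by_area = {a: int(per_area_n[a]) for a in areas}
    else:
        if len(per_area_n) != len(areas):
            raise ValueError("per_area_n list length must equal number of areas")
        n_by_area = dict(zip(areas, (int(n) for n in per_area_n)))

    p_cell = cell_prevalence(census, truth)
    rng = substream(seed, "survey")
    factor_cols = list(truth.factors or _census_factors(census, None))

    recs = []
    uid = 0
    for area, grp in census.groupby("area_id", sort=False):
        counts = grp["count"].to_numpy(dtype=float)
        N_i = counts.sum()
        n_i = n_by_area[area]
        if n_i > N_i:
            raise ValueError(
                f"requested n={n_i} exceeds population N={int(N_i)} in area {area}"
            )
        weights = counts if allocation == "proportional" else (counts > 0).astype(float)
        n_cells = _allocate(n_i, weights)
        n_cells = np.minimum(n_cells, counts.astype(int))  # cannot exceed cell pop
        short = n_i - n_cells.sum()
        while short > 0:  # spill over into cells with remaining capacity
            room = counts.astype(int) - n_cells
            j = int(np.argmax(room))
            take = min(short, room[j])
            n_cells[j] += take
            short -= take
        for (idx, row), n_ig in zip(grp.iterrows(), n_cells):
            if n_ig == 0:
                continue
            y = rng.binomial(1, p_cell.loc[idx], size=n_ig)
            w = row["count"] / n_ig
            for yy in y:
                recs.append(
                    (uid, area, row["cell_id"],
                     *[row[c] for c in factor_cols], int(yy), w)
                )
                uid += 1
    survey = pd.DataFrame(
        recs, columns=["unit_id", "area_id", "cell_id", *factor_cols, "y", "w"]
    )
    survey.attrs["factors"] = dict(truth.factors)
    return survey
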