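"""Hierarchical Bayesian random-intercept logit model for small-area
prevalence, fitted by a self-contained Metropolis-within-Gibbs sampler.

Model
-----
For unit j in post-stratum (cell) g of area i,

    y_ij | beta, v_i ~ Bernoulli( expit( x_g' beta + v_i ) )
    v_i ~ Normal(0, sigma_v^2)            (area random intercepts)
    beta_k ~ Normal(0, tau_beta^2)        (weakly informative, tau_beta = 10)
    sigma_v ~ half-Normal(scale)          (default; Inverse-Gamma on
                                           sigma_v^2 available for parity
                                           with BUGS conventions)

Because covariates live at the cell level, the likelihood collapses to a
product of cell binomials, so each MCMC sweep costs O(#cells), not O(#units).

Area prevalence is a *derived* quantity: every retained draw is pushed
through the census composition,

    P_i^(t) = sum_g (N_ig / N_i) expit( x_g' beta^(t) + v_i^(t) ),

so the posterior of P_i reflects both parameter uncertainty and the area's
true population mix — the two-step small-area logic of fitting a unit-level
model and predicting at the area level through census counts.

Sampler: random-walk Metropolis per beta coordinate, a vectorized
random-walk update of all v_i at once (they are conditionally independent),
and either a log-scale random-walk for sigma_v (half-Normal prior) or a
conjugate Gibbs draw of sigma_v^2 (Inverse-Gamma prior). Proposal scales
adapt toward 44% acceptance during burn-in only, so the retained chain is a
valid time-homogeneous Markov chain and is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from ._rng import substream
from .direct import ESTIMATE_COLUMNS
from .synthetic import _census_factors, design_matrix

__all__ = [
    "HBModelSpec",
    "PosteriorDraws",
    "fit_hb",
    "summarize_posterior",
    "convergence_diagnostics",
    "variance_component_summary",
    "effective_sample_size",
    "split_rhat",
    "HierarchicalBayes",
]


@dataclass
class HBModelSpec:
    """Model and MCMC configuration for the hierarchical Bayes fit."""

    factors: dict[str, list[str]] | None = None
    prior_beta_sd: float = 10.0
    sigma_prior: str = "halfnormal"       # or "invgamma"
    sigma_scale: float = 1.0              # half-Normal scale
    sigma_ig: tuple[float, float] = (0.001, 0.001)  # Inverse-Gamma (a, b)
    sigma_fixed: float | None = None      # fix sigma_v (0 disables v entirely)
    weighted: bool = False                # weighted pseudo-likelihood variant
    n_iter: int = 25_000
    n_burnin: int = 5_000
    thin: int = 1
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.sigma_prior not in ("halfnormal", "invgamma"):
            raise ValueError(f"unknown sigma prior {self.sigma_prior!r}")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, per chain, plus derived area prevalences."""

    beta: np.ndarray              # (chains, draws, p)
    v: np.ndarray                 # (chains, draws, areas)
    sigma_v: np.ndarray           # (chains, draws)
    area_prevalence: np.ndarray   # (chains, draws, areas)
    beta_names: list[str]
    areas: list[str]
    n_by_area: pd.Series
    acceptance: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    # flattened (all chains pooled) views
    @property
    def beta_draws(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    @property
    def v_draws(self) -> np.ndarray:
        return self.v.reshape(-1, self.v.shape[-1])

    @property
    def sigma_v_draws(self) -> np.ndarray:
        return self.sigma_v.reshape(-1)

    @property
    def area_prevalence_draws(self) -> np.ndarray:
        return self.area_prevalence.reshape(-1, self.area_prevalence.shape[-1])


def _aggregate_cells(survey: pd.DataFrame, census: pd.DataFrame,
                     factors: dict[str, list[str]], weighted: bool):
    """Collapse the survey to per-(area, cell) binomial counts aligned with
    the census cell definitions."""
    cen_cells = set(zip(census["area_id"], census["cell_id"]))
    stray = set(zip(survey["area_id"], survey["cell_id"])) - cen_cells
    if stray:
        raise ValueError(
            f"survey cells absent from census: {sorted(stray)[:5]} ...")
    if weighted:
        w = survey["w"].to_numpy(dtype=float)
        w = w * len(survey) / w.sum()      # normalize to sample scale
        df = survey.assign(_n=w, _y=w * survey["y"])
    else:
        df = survey.assign(_n=1.0, _y=survey["y"].astype(float))
    agg = (df.groupby(["area_id", "cell_id"], sort=True)
             .agg(n=("_n", "sum"), y=("_y", "sum")).reset_index())
    cells = agg.merge(
        census.drop(columns=["count"]), on=["area_id", "cell_id"], how="left")
    X = design_matrix(cells, factors).to_numpy(dtype=float)
    return agg, X


def _binom_loglik(eta, y, n):
    return y * eta - n * np.logaddexp(0.0, eta)


def _run_chain(spec: HBModelSpec, X, y, n, area_idx, area_bounds, n_areas,
               rng: np.random.Generator):
    p = X.shape[1]
    kept = (spec.n_iter - spec.n_burnin) // spec.thin

    pooled = float(np.clip(y.sum() / n.sum(), 1e-3, 1 - 1e-3))
    beta = np.zeros(p)
    beta[0] = logit(pooled)
    sigma_fixed = spec.sigma_fixed
    sigma = (sigma_fixed if sigma_fixed is not None
             else 0.5 * spec.sigma_scale if spec.sigma_prior == "halfnormal"
             else 0.5)
    sample_v = not (sigma_fixed is not None and sigma_fixed == 0.0)
    v = np.zeros(n_areas)

    eta = X @ beta + v[area_idx]
    cell_ll = _binom_loglik(eta, y, n)
    if not np.isfinite(cell_ll.sum()):
        raise ValueError("non-finite likelihood at initialization")

    scale_beta = np.full(p, 0.3)
    scale_v = np.full(n_areas, 0.5)
    scale_logsig = 0.4
    scale_nc = 0.5
    acc_beta = np.zeros(p)
    acc_v = np.zeros(n_areas)
    acc_sig = 0.0
    batch_beta = np.zeros(p)
    batch_v = np.zeros(n_areas)
    batch_sig = 0.0
    batch_nc = 0.0
    prior_prec = 1.0 / spec.prior_beta_sd**2

    out_beta = np.empty((kept, p))
    out_v = np.empty((kept, n_areas))
    out_sigma = np.empty(kept)
    k = 0

    for it in range(spec.n_iter):
        # --- beta, one coordinate at a time ---
        for j in range(p):
            prop = rng.normal(0.0, scale_beta[j])
            eta_new = eta + prop * X[:, j]
            ll_new = _binom_loglik(eta_new, y, n)
            b_new = beta[j] + prop
            dlp = -0.5 * prior_prec * (b_new**2 - beta[j] ** 2)
            if np.log(rng.random()) < ll_new.sum() - cell_ll.sum() + dlp:
                beta[j] = b_new
                eta, cell_ll = eta_new, ll_new
                if it >= spec.n_burnin:
                    acc_beta[j] += 1
                batch_beta[j] += 1

        # --- all area intercepts at once (conditionally independent) ---
        if sample_v:
            prop = rng.normal(0.0, scale_v)
            eta_new = eta + prop[area_idx]
            ll_new = _binom_loglik(eta_new, y, n)
            # per-area sums of cell log-likelihood (rows sorted by area)
            la_old = np.add.reduceat(cell_ll, area_bounds)
            la_new = np.add.reduceat(ll_new, area_bounds)
            v_new = v + prop
            if sigma > 0:
                dprior = -0.5 * (v_new**2 - v**2) / sigma**2
            else:
                dprior = np.where(prop == 0.0, 0.0, -np.inf)
            accept = np.log(rng.random(n_areas)) < la_new - la_old + dprior
            v = np.where(accept, v_new, v)
            upd = accept[area_idx]
            eta = np.where(upd, eta_new, eta)
            cell_ll = np.where(upd, ll_new, cell_ll)
            if it >= spec.n_burnin:
                acc_v += accept
            batch_v += accept

            # --- variance component, centered update ---
            if sigma_fixed is None:
                if spec.sigma_prior == "invgamma":
                    a0, b0 = spec.sigma_ig
                    sigma = float(np.sqrt(
                        1.0 / rng.gamma(a0 + n_areas / 2.0,
                                        1.0 / (b0 + 0.5 * (v**2).sum()))))
                else:
                    th = np.log(sigma)
                    th_new = th + rng.normal(0.0, scale_logsig)
                    s_new = np.exp(th_new)

                    def lp(s, t):
                        return (-n_areas * t - 0.5 * (v**2).sum() / s**2
                                - 0.5 * s**2 / spec.sigma_scale**2 + t)

                    if np.log(rng.random()) < lp(s_new, th_new) - lp(sigma, th):
                        sigma = float(s_new)
                        if it >= spec.n_burnin:
                            acc_sig += 1
                        batch_sig += 1

                # --- interweaved non-centered update: rescale (sigma, v)
                # jointly along the funnel axis, holding u = v/sigma fixed.
                # Target in (log sigma, u): L(sigma*u) p(sigma) sigma.
                th = np.log(sigma)
                th_new = th + rng.normal(0.0, scale_nc)
                s_new = np.exp(th_new)
                v_new = v * (s_new / sigma)
                eta_new = eta + (v_new - v)[area_idx]
                ll_new = _binom_loglik(eta_new, y, n)
                dlp = ll_new.sum() - cell_ll.sum() + (th_new - th)
                if spec.sigma_prior == "invgamma":
                    a0, b0 = spec.sigma_ig
                    dlp += (-(2 * a0 + 1) * (th_new - th)
                            - b0 * (1.0 / s_new**2 - 1.0 / sigma**2))
                else:
                    dlp += -0.5 * (s_new**2 - sigma**2) / spec.sigma_scale**2
                if np.log(rng.random()) < dlp:
                    sigma = float(s_new)
                    v = v_new
                    eta, cell_ll = eta_new, ll_new
                    batch_nc += 1

        # --- burn-in adaptation toward 44% acceptance, batches of 50 ---
        if it < spec.n_burnin and (it + 1) % 50 == 0:
            gain = min(0.5, 5.0 / np.sqrt((it + 1) / 50.0))
            scale_beta *= np.exp(gain * (batch_beta / 50.0 - 0.44))
            scale_v *= np.exp(gain * (batch_v / 50.0 - 0.44))
            if sample_v and sigma_fixed is None:
                if spec.sigma_prior == "halfnormal":
                    scale_logsig *= np.exp(gain * (batch_sig / 50.0 - 0.44))
                scale_nc *= np.exp(gain * (batch_nc / 50.0 - 0.44))
            batch_beta[:] = 0
            batch_v[:] = 0
            batch_sig = 0.0
            batch_nc = 0.0

        if it >= spec.n_burnin and (it - spec.n_burnin) % spec.thin == 0:
            out_beta[k] = beta
            out_v[k] = v
            out_sigma[k] = sigma
            k += 1

    post = spec.n_iter - spec.n_burnin
    acc = {"beta": acc_beta / post, "v": acc_v / post,
           "sigma_v": acc_sig / post if sigma_fixed is None else np.nan}
    if np.any(acc["beta"] < 0.01) or (sample_v and np.any(acc["v"] < 0.01)):
        raise RuntimeError(
            "MCMC divergence: post-adaptation acceptance below 1% "
            f"(beta: {np.round(acc['beta'], 4).tolist()}, "
            f"v min: {float(np.min(acc['v'])):.4f})")
    return out_beta[:k], out_v[:k], out_sigma[:k], acc


def fit_hb(survey: pd.DataFrame, census: pd.DataFrame,
           spec: HBModelSpec | None = None) -> PosteriorDraws:
    """Fit the hierarchical model by MCMC and derive per-draw area
    prevalences through the census post-strata."""
    spec = spec or HBModelSpec()
    factors = spec.factors or _census_factors(census, None)
    y_all = survey["y"].to_numpy()
    if y_all.min() == y_all.max():
        raise ValueError("outcome has a single class; model is not identified")

    agg, X = _aggregate_cells(survey, census, factors, spec.weighted)
    areas = sorted(pd.unique(census["area_id"]))  # agg rows are area-sorted
    a_lookup = {a: i for i, a in enumerate(areas)}
    area_idx = agg["area_id"].map(a_lookup).to_numpy()
    # agg is sorted by area_id; reduceat boundaries at each area's first row
    area_bounds = np.searchsorted(area_idx, np.arange(len(areas)))
    y = agg["y"].to_numpy(dtype=float)
    n = agg["n"].to_numpy(dtype=float)

    # census prediction machinery
    Xc = design_matrix(census, factors).to_numpy(dtype=float)
    c_idx = census["area_id"].map(a_lookup).to_numpy()
    cnt = census["count"].to_numpy(dtype=float)
    N_i = np.bincount(c_idx, weights=cnt, minlength=len(areas))
    share = cnt / N_i[c_idx]

    chains_b, chains_v, chains_s, chains_p, accs = [], [], [], [], []
    for c in range(spec.n_chains):
        rng = substream(spec.seed, f"hb-chain-{c}")
        b, v, s, acc = _run_chain(spec, X, y, n, area_idx, area_bounds,
                                  len(areas), rng)
        # push draws through the census: P (draws, areas)
        P = np.empty((b.shape[0], len(areas)))
        for lo in range(0, b.shape[0], 2000):
            hi = min(lo + 2000, b.shape[0])
            eta = b[lo:hi] @ Xc.T + v[lo:hi][:, c_idx]
            pr = expit(eta) * share
            P[lo:hi] = np.stack(
                [np.bincount(c_idx, weights=row, minlength=len(areas))
                 for row in pr])
        chains_b.append(b)
        chains_v.append(v)
        chains_s.append(s)
        chains_p.append(P)
        accs.append(acc)

    n_by_area = survey.groupby("area_id").size().reindex(areas).fillna(0).astype(int)
    return PosteriorDraws(
        beta=np.stack(chains_b), v=np.stack(chains_v),
        sigma_v=np.stack(chains_s), area_prevalence=np.stack(chains_p),
        beta_names=list(design_matrix(census.iloc[:1], factors).columns),
        areas=areas, n_by_area=n_by_area,
        acceptance={f"chain_{i}": a for i, a in enumerate(accs)})


def summarize_posterior(draws: PosteriorDraws,
                        min_draws: int = 100) -> pd.DataFrame:
    """Per-area posterior summary: mean, central 95% credible interval,
    posterior variance (reported as MSE) and CV."""
    P = draws.area_prevalence_draws
    if P.shape[0] < min_draws:
        raise ValueError(f"need >= {min_draws} retained draws, have {P.shape[0]}")
    est = P.mean(axis=0)
    var = P.var(axis=0, ddof=1) if P.shape[0] > 1 else np.zeros(P.shape[1])
    lo, hi = np.percentile(P, [2.5, 97.5], axis=0)
    rows = []
    for i, area in enumerate(draws.areas):
        rows.append({"domain_id": area, "method": "hb",
                     "estimate": float(est[i]), "mse": float(var[i]),
                     "ci_low": float(lo[i]), "ci_high": float(hi[i]),
                     "cv": float(np.sqrt(var[i]) / est[i]),
                     "n": int(draws.n_by_area.iloc[i])})
    return pd.DataFrame(rows)[ESTIMATE_COLUMNS]


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of draws shaped (chains, draws) via Geyer's initial positive
    sequence on the pooled, per-chain-centered autocorrelation. A constant
    chain is reported as ESS = 1 (one independent piece of information)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m, nd = x.shape
    if nd < 2 or np.allclose(x.var(axis=1).sum(), 0.0):
        return 1.0
    acov = np.zeros(nd)
    for c in range(m):
        z = x[c] - x[c].mean()
        f = np.fft.rfft(z, 2 * nd)
        ac = np.fft.irfft(f * np.conj(f))[:nd].real / nd
        acov += ac / m
    rho = acov / acov[0]
    # sum consecutive pairs while positive (initial positive sequence)
    s = 0.0
    t = 1
    while t + 1 < nd:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    return float(max(1.0, m * nd / (1.0 + 2.0 * s)))


def split_rhat(x: np.ndarray) -> float:
    """Split potential-scale-reduction factor; NaN for a single split or a
    zero-variance chain."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m, nd = x.shape
    half = nd // 2
    if half < 2:
        return float("nan")
    splits = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    W = splits.var(axis=1, ddof=1).mean()
    B = half * splits.mean(axis=1).var(ddof=1)
    if W == 0:
        return float("nan")
    return float(np.sqrt(((half - 1) / half * W + B / half) / W))


def convergence_diagnostics(draws: PosteriorDraws,
                            rhat_threshold: float = 1.1) -> pd.DataFrame:
    """ESS and split-Rhat for every model parameter.

    With a single chain the PSRF is computed on split halves (still useful,
    flagged as within-chain); warnings are attached for Rhat above threshold
    and for degenerate ESS.
    """
    params = {name: draws.beta[:, :, j]
              for j, name in enumerate(draws.beta_names)}
    for i, a in enumerate(draws.areas):
        params[f"v[{a}]"] = draws.v[:, :, i]
    if np.ptp(draws.sigma_v) > 0 or draws.sigma_v.ravel()[0] > 0:
        params["sigma_v"] = draws.sigma_v
    rows = []
    for name, x in params.items():
        ess = effective_sample_size(x)
        rhat = split_rhat(x)
        warn = []
        if np.isfinite(rhat) and rhat > rhat_threshold:
            warn.append(f"rhat>{rhat_threshold}")
        if ess <= 1.5:
            warn.append("degenerate ESS")
        rows.append({"parameter": name, "ess": ess, "rhat": rhat,
                     "n_draws": x.size, "warnings": ";".join(warn)})
    out = pd.DataFrame(rows)
    out.attrs["between_chain"] = draws.beta.shape[0] >= 2
    return out


def variance_component_summary(draws: PosteriorDraws,
                               epsilon: float = 0.01) -> dict:
    """Posterior summary of the between-area variance component.

    The random effect is called ``supported`` when the central 95% interval
    of sigma_v lies entirely above ``epsilon`` — i.e. the data rule out a
    (practically) zero variance component.
    """
    s = draws.sigma_v_draws
    if s.size < 100:
        raise ValueError("need >= 100 draws of sigma_v")
    q = np.percentile(s, [2.5, 25, 50, 75, 97.5])
    v_mean = pd.Series(draws.v_draws.mean(axis=0), index=draws.areas, name="v_mean")
    return {
        "sigma_v_quantiles": dict(zip(["q2.5", "q25", "q50", "q75", "q97.5"],
                                      map(float, q))),
        "sigma_v_mean": float(s.mean()),
        "supported": bool(q[0] > epsilon),
        "epsilon": epsilon,
        "v_posterior_means": v_mean,
    }


class HierarchicalBayes(BaseEstimator):
    """Hierarchical Bayes small-area estimator (fit-shaped wrapper).

    Constructor parameters mirror :class:`HBModelSpec`; ``fit`` runs the
    sampler on a survey frame and exposes ``draws_`` (PosteriorDraws) and
    ``estimates_`` (per-area DomainEstimate frame, method tag "hb").
    """

    def __init__(self, census: pd.DataFrame = None,
                 factors: dict[str, list[str]] | None = None,
                 prior_beta_sd: float = 10.0, sigma_prior: str = "halfnormal",
                 sigma_scale: float = 1.0, sigma_fixed: float | None = None,
                 weighted: bool = False, n_iter: int = 25_000,
                 n_burnin: int = 5_000, thin: int = 1, n_chains: int = 1,
                 seed: int = 0):
        self.census = census
        self.factors = factors
        self.prior_beta_sd = prior_beta_sd
        self.sigma_prior = sigma_prior
        self.sigma_scale = sigma_scale
        self.sigma_fixed = sigma_fixed
        self.weighted = weighted
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.thin = thin
        self.n_chains = n_chains
        self.seed = seed

    def _spec(self) -> HBModelSpec:
        return HBModelSpec(
            factors=self.factors, prior_beta_sd=self.prior_beta_sd,
            sigma_prior=self.sigma_prior, sigma_scale=self.sigma_scale,
            sigma_fixed=self.sigma_fixed, weighted=self.weighted,
            n_iter=self.n_iter, n_burnin=self.n_burnin, thin=self.thin,
            n_chains=self.n_chains, seed=self.seed)

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalBayes":
        self.draws_ = fit_hb(X, self.census, self._spec())
        self.estimates_ = summarize_posterior(self.draws_)
        return self

    def predict(self, domains=None) -> pd.Series:
        est = self.estimates_.set_index("domain_id")["estimate"]
        return est if domains is None else est.reindex(domains)
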