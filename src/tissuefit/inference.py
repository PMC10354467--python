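"""Likelihood-based calibration of the growth models.

The parameter vector is theta = (D, r, K, sigma), where sigma is the s.d.
of the additive Gaussian observation error. With that error model the
log-likelihood of a set of voxel observations is

    l(theta) = -1/2 sum_{i,j} [ log(2 pi sigma^2)
                                + ((rho(x_i, t_j) - rho_D(x_i, t_j)) / sigma)^2 ],

with rho the model solution voxel-averaged at the observation voxels.

Priors are uniform on log10 scale inside a per-parameter box. Maximum
likelihood uses bound-constrained local optimization on log10 parameters
from multiple starts sampled uniformly in the box. The posterior is
explored with Metropolis-Hastings on log10 parameters whose Gaussian
proposal covariance adapts to the running sample covariance of the chain
(scaled by 2.38^2/d), the standard adaptive-Metropolis recipe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .grids import MultiSpeciesState
from .observations import ObservationSet, voxel_lattice
from .params import ModelParams
from .solver import solve

__all__ = [
    "PARAM_NAMES",
    "PriorBox",
    "default_priors",
    "ExpansionLikelihood",
    "log_likelihood",
    "MLFit",
    "ml_fit",
    "ChainSet",
    "mcmc_sample",
    "gelman_rubin",
    "posterior_summary",
    "plot_matrix",
]

PARAM_NAMES = ("D", "r", "K", "sigma")

#: retained iterations per chain when summarizing a full-length run
DEFAULT_RETAIN = 5000

UM_TO_MM = 1e-3


@dataclass(frozen=True)
class PriorBox:
    """Per-parameter (lower, upper) bounds, uniform on log10 scale."""

    bounds: dict

    def __post_init__(self):
        for name in PARAM_NAMES:
            if name not in self.bounds:
                raise ValueError(f"missing prior bounds for {name}")
            lo, hi = self.bounds[name]
            if not (0 < lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def log_lower(self) -> np.ndarray:
        return np.array([math.log10(self.bounds[n][0]) for n in PARAM_NAMES])

    @property
    def log_upper(self) -> np.ndarray:
        return np.array([math.log10(self.bounds[n][1]) for n in PARAM_NAMES])

    def contains_log(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.log_lower) and np.all(x <= self.log_upper))

    def sample_log(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.uniform(self.log_lower, self.log_upper, size=(n, len(PARAM_NAMES)))


def default_priors(family: str) -> PriorBox:
    """Published log-uniform boxes, with two corrections.

    The published K box [1e3, 10^3.5] excludes the published estimates
    (~5113 and ~5319 cells mm^-2) and the porous-D bounds are printed
    reversed; the K box is widened to [1e3, 1e4] and the porous-D box set
    to [10^-2.5, 10^1.5] um^2 (cells h)^-1.
    """
    common = {"r": (10**-2.5, 10.0), "K": (1e3, 1e4), "sigma": (10.0, 10**3.5)}
    if family == "linear":
        return PriorBox({"D": (10**2.5, 10**4.5), **common})
    if family == "porous":
        return PriorBox({"D": (10**-2.5, 10**1.5), **common})
    raise ValueError(f"unknown family {family!r}")


class ExpansionLikelihood:
    """Maps theta = (D, r, K, sigma) to the log-likelihood of an
    observation set, given a known initial density profile.

    The forward model solves the chosen family from ``initial_state`` on
    that state's grid and voxel-averages the solution at the observation
    voxels (subsampled interpolation, matching the synthetic generator).
    Circular expansions should use a radial1d initial state: the physics is
    radially symmetric and the 1D solve is orders of magnitude cheaper.
    """

    def __init__(
        self,
        observations: ObservationSet,
        initial_state: MultiSpeciesState,
        family: str = "porous",
        m: float = 2.0,
        subsample: int = 4,
    ):
        if observations.n_obs == 0:
            raise ValueError("observation set is empty")
        self.observations = observations
        self.initial_state = initial_state
        self.family = family
        self.m = m
        self.times = list(observations.times)
        # precompute quadrature points of every voxel once
        v = observations.voxel * UM_TO_MM
        off = ((np.arange(subsample) + 0.5) / subsample - 0.5) * v
        ox, oy = np.meshgrid(off, off)
        pts = (
            observations.positions[:, None, :]
            + np.column_stack([ox.ravel(), oy.ravel()])[None, :, :]
        )
        self._nvox = len(observations.positions)
        self._nsub = subsample**2
        if initial_state.grid.mode == "radial1d":
            self._radii = np.hypot(pts[..., 0], pts[..., 1]).reshape(-1)
            self._centers = initial_state.grid.cell_centers()
        else:
            self._pts = pts.reshape(-1, 2)

    def predict(self, params: ModelParams) -> np.ndarray:
        """Voxel-averaged model densities, shape (n_times, n_voxels)."""
        traj = solve(self.initial_state, params, self.times)
        out = np.empty((len(self.times), self._nvox))
        for j, st in enumerate(traj):
            if st.grid.mode == "radial1d":
                vals = np.interp(
                    self._radii,
                    self._centers,
                    st.densities.sum(axis=0),
                    left=float(st.densities.sum(axis=0)[0]),
                    right=0.0,
                )
            else:
                from .solver import sample_field

                vals = sample_field(st.total(), self._pts)
            out[j] = vals.reshape(self._nvox, self._nsub).mean(axis=1)
        return out

    def loglike(self, theta: Sequence[float]) -> float:
        """l(theta); -inf when the solver fails or theta is inadmissible."""
        D, r, K, sigma = (float(v) for v in theta)
        if min(D, K, sigma) <= 0 or r < 0:
            return -math.inf
        try:
            params = ModelParams(self.family, D, r, K, m=self.m)
            pred = self.predict(params)
        except (ValueError, RuntimeError, FloatingPointError):
            return -math.inf
        resid = pred - self.observations.values
        n = resid.size
        return float(
            -0.5 * (n * math.log(2 * math.pi * sigma**2) + np.sum(resid**2) / sigma**2)
        )


def log_likelihood(
    theta: Sequence[float],
    observations: ObservationSet,
    initial_state: MultiSpeciesState,
    family: str = "porous",
    m: float = 2.0,
) -> float:
    """Functional wrapper over :class:`ExpansionLikelihood`."""
    return ExpansionLikelihood(observations, initial_state, family, m).loglike(theta)


@dataclass
class MLFit:
    """Best multistart optimum plus the full start table (sorted by l)."""

    theta: np.ndarray
    loglike: float
    table: pd.DataFrame

    def as_dict(self) -> dict:
        return dict(zip(PARAM_NAMES, self.theta))


def ml_fit(
    likelihood: ExpansionLikelihood | Callable[[np.ndarray], float],
    priors: PriorBox,
    n_starts: int = 20,
    seed: int = 0,
) -> MLFit:
    """Multistart maximum likelihood on log10 parameters.

    Starts are sampled uniformly on log scale inside the prior box; each is
    refined with bound-constrained L-BFGS-B. For an
    :class:`ExpansionLikelihood` the noise s.d. is profiled analytically:
    at fixed (D, r, K) the likelihood is maximized in closed form by
    sigma^2 = mean squared residual (clipped to the prior box), so the
    optimizer only works in the three mechanistic parameters and every
    evaluation costs a single forward solve. The argmax over the full
    theta = (D, r, K, sigma) is unchanged. Raises RuntimeError with
    per-start reasons when every start fails.
    """
    from scipy.optimize import minimize

    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    starts = priors.sample_log(rng, n_starts)
    lo, hi = priors.log_lower, priors.log_upper

    profiled = isinstance(likelihood, ExpansionLikelihood)
    if profiled:
        lik = likelihood
        obs_values = lik.observations.values
        n_obs = obs_values.size
        sig_lo, sig_hi = priors.bounds["sigma"]

        def negloglike(x3: np.ndarray) -> float:
            D, r, K = 10.0**x3
            try:
                pred = lik.predict(ModelParams(lik.family, D, r, K, m=lik.m))
            except (ValueError, RuntimeError, FloatingPointError):
                return math.inf
            ssq = float(np.sum((pred - obs_values) ** 2))
            sigma = min(max(math.sqrt(ssq / n_obs), sig_lo), sig_hi)
            return 0.5 * (n_obs * math.log(2 * math.pi * sigma**2) + ssq / sigma**2)

        def finish(x3: np.ndarray):
            D, r, K = 10.0**x3
            pred = lik.predict(ModelParams(lik.family, D, r, K, m=lik.m))
            ssq = float(np.sum((pred - obs_values) ** 2))
            sigma = min(max(math.sqrt(ssq / n_obs), sig_lo), sig_hi)
            return np.array([D, r, K, sigma])

        opt_lo, opt_hi = lo[:3], hi[:3]
    else:
        ll = likelihood

        def negloglike(x: np.ndarray) -> float:
            v = ll(10.0**x)
            return math.inf if not math.isfinite(v) else -v

        opt_lo, opt_hi = lo, hi

    rows, failures = [], []
    for s, x0 in enumerate(starts):
        try:
            res = minimize(
                negloglike,
                x0[: len(opt_lo)],
                method="L-BFGS-B",
                bounds=list(zip(opt_lo, opt_hi)),
                options={"maxiter": 100},
            )
            theta = finish(res.x) if profiled else 10.0**res.x
            rows.append(
                {
                    "start": s,
                    "loglike": -res.fun,
                    **dict(zip(PARAM_NAMES, theta)),
                    "converged": bool(res.success),
                }
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"start {s}: {exc}")
    if not rows:
        raise RuntimeError("all optimization starts failed: " + "; ".join(failures))
    table = pd.DataFrame(rows).sort_values("loglike", ascending=False).reset_index(drop=True)
    best = table.iloc[0]
    theta = np.array([best[n] for n in PARAM_NAMES])
    return MLFit(theta=theta, loglike=float(best["loglike"]), table=table)


@dataclass
class ChainSet:
    """MCMC draws from several chains (natural parameter units).

    samples : (n_chains, n_iter, 4); log_post : (n_chains, n_iter);
    accepted : (n_chains, n_iter) booleans; retain : burn-in convention,
    number of final iterations per chain pooled by summaries.
    """

    samples: np.ndarray
    log_post: np.ndarray
    accepted: np.ndarray
    retain: int = DEFAULT_RETAIN
    param_names: tuple = PARAM_NAMES

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_iter(self) -> int:
        return self.samples.shape[1]

    def acceptance_rate(self, warmup: int = 500) -> np.ndarray:
        return self.accepted[:, warmup:].mean(axis=1)

    def pooled(self, retain: int | None = None) -> np.ndarray:
        """Last ``retain`` iterations of each chain, stacked: (C*retain, 4)."""
        retain = self.retain if retain is None else retain
        if retain <= 0 or retain > self.n_iter:
            raise ValueError(
                f"retain={retain} incompatible with chain length {self.n_iter}"
            )
        return self.samples[:, -retain:, :].reshape(-1, self.samples.shape[2])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.samples[c], columns=list(self.param_names))
            df.insert(0, "iteration", np.arange(self.n_iter))
            df.insert(1, "chain", c)
            df["log_post"] = self.log_post[c]
            df["accepted"] = self.accepted[c].astype(int)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def mcmc_sample(
    likelihood: ExpansionLikelihood | Callable[[np.ndarray], float],
    priors: PriorBox,
    n_iter: int = 12000,
    n_chains: int = 3,
    seed: int = 0,
    start: Sequence[float] | None = None,
    retain: int | None = None,
    adapt_start: int = 500,
    adapt_interval: int = 50,
    init_step: float = 0.005,
) -> ChainSet:
    """Adaptive Metropolis-Hastings on log10 parameters.

    Each chain proposes Gaussian steps whose covariance is refreshed every
    ``adapt_interval`` iterations (after ``adapt_start``) from the running
    sample covariance, scaled by 2.38^2/d with a small diagonal jitter.
    Moves are accepted with probability min{1, posterior ratio}; proposals
    outside the prior box have zero prior density and are always rejected.
    Chain c uses the independent stream seeded by (seed, c); fixed inputs
    give identical chains.
    """
    ll = likelihood.loglike if isinstance(likelihood, ExpansionLikelihood) else likelihood
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    d = len(PARAM_NAMES)
    lo, hi = priors.log_lower, priors.log_upper
    scale = 2.38**2 / d
    jitter = 1e-10 * np.eye(d)
    if retain is None:
        retain = min(DEFAULT_RETAIN, max(1, n_iter // 2))

    samples = np.empty((n_chains, n_iter, d))
    log_post = np.empty((n_chains, n_iter))
    accepted = np.zeros((n_chains, n_iter), dtype=bool)

    for c in range(n_chains):
        rng = np.random.default_rng((int(seed), c))
        if start is not None:
            x = np.log10(np.asarray(start, float))
            if not priors.contains_log(x):
                raise ValueError("start lies outside the prior box")
            lp = ll(10.0**x)
            if not math.isfinite(lp):
                raise ValueError("start has zero posterior probability")
        else:
            for _ in range(100):
                x = priors.sample_log(rng, 1)[0]
                lp = ll(10.0**x)
                if math.isfinite(lp):
                    break
            else:
                raise RuntimeError("could not find a feasible starting point")
        chol = init_step * np.eye(d)
        hist = np.empty((n_iter, d))
        for it in range(n_iter):
            prop = x + chol @ rng.standard_normal(d)
            if priors.contains_log(prop):
                lp_prop = ll(10.0**prop)
            else:
                lp_prop = -math.inf
            if math.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted[c, it] = True
            hist[it] = x
            samples[c, it] = 10.0**x
            log_post[c, it] = lp
            if it + 1 >= adapt_start and (it + 1) % adapt_interval == 0:
                cov = np.cov(hist[: it + 1].T) * scale + jitter
                chol = np.linalg.cholesky(cov)
    return ChainSet(samples, log_post, accepted, retain=retain)


def gelman_rubin(chains, retain: int | None = None) -> dict:
    """Split-R-hat per parameter from between/within-chain variances.

    ``chains`` is a ChainSet or an array (n_chains, n_iter, n_params); each
    retained chain segment is split in half, and R-hat =
    sqrt(((n-1)/n W + B/n) / W) over the 2C half-sequences. Requires at
    least 2 chains.
    """
    if isinstance(chains, ChainSet):
        names = chains.param_names
        arr = chains.samples[:, -(retain or chains.retain):, :]
    else:
        arr = np.asarray(chains, float)
        names = PARAM_NAMES[: arr.shape[2]]
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    n_half = arr.shape[1] // 2
    halves = np.concatenate([arr[:, :n_half, :], arr[:, -n_half:, :]], axis=0)
    out = {}
    for p, name in enumerate(names):
        seqs = halves[:, :, p]
        n = seqs.shape[1]
        W = seqs.var(axis=1, ddof=1).mean()
        B_over_n = seqs.mean(axis=1).var(ddof=1)
        if W == 0:
            out[name] = 1.0
        else:
            var_plus = (n - 1) / n * W + B_over_n
            out[name] = float(math.sqrt(var_plus / W))
    return out


def posterior_summary(chains: ChainSet, retain: int | None = None) -> pd.DataFrame:
    """Mode, mean, s.d. and central 95% credible interval per parameter.

    Pools the last ``retain`` iterations of every chain (the stored
    convention by default). The univariate mode is the argmax of a
    Gaussian-kernel density estimate with Silverman bandwidth.
    """
    from scipy.stats import gaussian_kde

    pooled = chains.pooled(retain)
    rows = []
    for p, name in enumerate(chains.param_names):
        x = pooled[:, p]
        sd = float(x.std(ddof=1))
        if sd == 0 or np.ptp(x) == 0:
            mode = float(x[0])
        else:
            try:
                kde = gaussian_kde(x, bw_method="silverman")
                grid = np.linspace(x.min(), x.max(), 512)
                mode = float(grid[np.argmax(kde(grid))])
            except np.linalg.LinAlgError:  # degenerate draws
                mode = float(np.median(x))
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mode": mode,
                "mean": float(x.mean()),
                "sd": sd,
                "ci_2.5%": float(lo),
                "ci_97.5%": float(hi),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def plot_matrix(chains: ChainSet, retain: int | None = None, bins: int = 40):
    """Plot-matrix of marginal histograms (diagonal) and bivariate
    histograms (below diagonal) of the pooled retained draws."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pooled = chains.pooled(retain)
    names = chains.param_names
    d = len(names)
    fig, axes = plt.subplots(d, d, figsize=(2.2 * d, 2.2 * d))
    for i in range(d):
        for j in range(d):
            ax = axes[i, j]
            if j > i:
                ax.axis("off")
            elif i == j:
                ax.hist(pooled[:, i], bins=bins, color="steelblue")
                ax.set_yticks([])
            else:
                ax.hist2d(pooled[:, j], pooled[:, i], bins=bins, cmap="viridis")
            if i == d - 1:
                ax.set_xlabel(names[j])
            if j == 0 and i > 0:
                ax.set_ylabel(names[i])
    fig.tight_layout()
    return fig
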