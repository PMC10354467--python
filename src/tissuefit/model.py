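"""Model/Results interface for calibrating tissue expansions.

:class:`ExpansionModel` binds an observation set, a known initial density
profile and a model family; ``fit()`` runs multistart maximum likelihood
and ``fit_mcmc()`` the adaptive MCMC sampler. Both return results objects
carrying the estimates, their uncertainties, convergence diagnostics and a
``summary()`` table.

    >>> exp = expansion_protocol(params_true, sigma=400, seed=1)   # doctest: +SKIP
    >>> model = ExpansionModel(exp.observations, exp.initial_state,
    ...                        family="porous")                    # doctest: +SKIP
    >>> res = model.fit(n_starts=10, seed=0)                       # doctest: +SKIP
    >>> post = model.fit_mcmc(n_iter=3000, seed=0,
    ...                       start=res.params)                    # doctest: +SKIP
    >>> print(post.summary())                                      # doctest: +SKIP
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .grids import MultiSpeciesState
from .inference import (
    PARAM_NAMES,
    ChainSet,
    ExpansionLikelihood,
    MLFit,
    PriorBox,
    default_priors,
    gelman_rubin,
    mcmc_sample,
    ml_fit,
    plot_matrix,
    posterior_summary,
)
from .observations import ObservationSet, expansion_protocol
from .params import ModelParams, growth_summary

__all__ = ["ExpansionModel", "ExpansionMLResults", "ExpansionMCMCResults"]


class ExpansionModel:
    """Continuum growth model bound to voxel observations.

    Parameters
    ----------
    observations : ObservationSet
    initial_state : MultiSpeciesState
        Known density profile at the start of the fitting window (the
        protocol's burn-in profile), on the grid the forward solves use.
    family : {"porous", "linear"}
    m : pressure exponent (porous only)
    priors : PriorBox, default the published log-uniform boxes
    """

    def __init__(
        self,
        observations: ObservationSet,
        initial_state: MultiSpeciesState,
        family: str = "porous",
        m: float = 2.0,
        priors: PriorBox | None = None,
        subsample: int = 4,
    ):
        self.family = family
        self.m = m
        self.priors = priors if priors is not None else default_priors(family)
        self._lik = ExpansionLikelihood(observations, initial_state, family, m, subsample)
        self.observations = observations
        self.initial_state = initial_state
        self.params_true: ModelParams | None = None

    @classmethod
    def from_synthetic(
        cls,
        params_true: ModelParams,
        sigma: float,
        seed: int,
        family: str | None = None,
        priors: PriorBox | None = None,
        **protocol_kw,
    ) -> "ExpansionModel":
        """Generate a synthetic expansion experiment and bind a model to it.

        ``family`` defaults to the generating family (well-specified fit).
        """
        exp = expansion_protocol(params_true, sigma, seed, **protocol_kw)
        mdl = cls(
            exp.observations,
            exp.initial_state,
            family or params_true.family,
            m=params_true.m,
            priors=priors,
        )
        mdl.params_true = params_true
        return mdl

    def loglike(self, theta: Sequence[float]) -> float:
        """Log-likelihood at theta = (D, r, K, sigma)."""
        return self._lik.loglike(theta)

    def predict(self, theta: Sequence[float]) -> np.ndarray:
        """Voxel-averaged model densities at the observation voxels/times."""
        D, r, K, _ = theta if len(theta) == 4 else (*theta, None)
        return self._lik.predict(ModelParams(self.family, D, r, K, m=self.m))

    def fit(self, n_starts: int = 20, seed: int = 0) -> "ExpansionMLResults":
        """Multistart maximum likelihood."""
        res = ml_fit(self._lik, self.priors, n_starts=n_starts, seed=seed)
        return ExpansionMLResults(self, res)

    def fit_mcmc(
        self,
        n_iter: int = 12000,
        n_chains: int = 3,
        seed: int = 0,
        start: Sequence[float] | None = None,
        **kw,
    ) -> "ExpansionMCMCResults":
        """Adaptive Metropolis-Hastings posterior sampling."""
        chains = mcmc_sample(
            self._lik,
            self.priors,
            n_iter=n_iter,
            n_chains=n_chains,
            seed=seed,
            start=start,
            **kw,
        )
        return ExpansionMCMCResults(self, chains)


class ExpansionMLResults:
    """Maximum-likelihood estimates and the multistart table."""

    def __init__(self, model: ExpansionModel, fit: MLFit):
        self.model = model
        self.params = fit.theta
        self.llf = fit.loglike
        self.table = fit.table

    def __getattr__(self, name):
        if name in PARAM_NAMES:
            return float(self.params[PARAM_NAMES.index(name)])
        raise AttributeError(name)

    def as_params(self) -> ModelParams:
        D, r, K, _ = self.params
        return ModelParams(self.model.family, D, r, K, m=self.model.m)

    def derived(self, rho_bar: float = 3000.0):
        """Derived biology (cell radius, division time, ...) at rho_bar."""
        return growth_summary(self.as_params(), rho_bar)

    def summary(self) -> str:
        lines = [
            f"Expansion model: {self.model.family} (m={self.model.m:g})",
            f"log-likelihood at the optimum: {self.llf:.3f}",
            f"n observations: {self.model.observations.n_obs}",
            "",
            pd.Series(dict(zip(PARAM_NAMES, self.params))).to_string(),
            "",
            f"multistart table ({len(self.table)} starts, best first):",
            self.table.head(10).to_string(index=False),
        ]
        return "\n".join(lines)


class ExpansionMCMCResults:
    """Posterior draws with diagnostics and summaries."""

    def __init__(self, model: ExpansionModel, chains: ChainSet):
        self.model = model
        self.chains = chains

    def rhat(self, retain: int | None = None) -> dict:
        """Split Gelman-Rubin statistic per parameter."""
        return gelman_rubin(self.chains, retain=retain)

    def summary_frame(self, retain: int | None = None) -> pd.DataFrame:
        return posterior_summary(self.chains, retain=retain)

    def summary(self, retain: int | None = None) -> str:
        df = self.summary_frame(retain)
        rh = self.rhat(retain)
        df = df.assign(rhat=[rh[p] for p in df.index])
        acc = self.chains.acceptance_rate()
        lines = [
            f"Adaptive MCMC: {self.chains.n_chains} chains x {self.chains.n_iter} iterations"
            f" (last {retain or self.chains.retain} retained per chain)",
            f"acceptance rates: {np.round(acc, 3).tolist()}",
            "",
            df.to_string(),
        ]
        return "\n".join(lines)

    def credible_interval(self, retain: int | None = None) -> dict:
        df = self.summary_frame(retain)
        return {p: (df.loc[p, "ci_2.5%"], df.loc[p, "ci_97.5%"]) for p in df.index}

    def contains(self, theta: Sequence[float], retain: int | None = None) -> dict:
        """Whether each component of theta lies in its 95% credible interval."""
        ci = self.credible_interval(retain)
        return {
            p: bool(ci[p][0] <= v <= ci[p][1])
            for p, v in zip(self.chains.param_names, theta)
        }

    def plot_matrix(self, retain: int | None = None):
        return plot_matrix(self.chains, retain)
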