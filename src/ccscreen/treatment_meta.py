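"""Bayesian random-effects meta-analysis of pre-cancer treatment coverage.

Country-level counts of women treated among those reporting an abnormal,
non-cancer screening result are pooled with a logistic random-effects
model:

    k_c ~ Binomial(n_c, expit(mu + u_c)),   u_c ~ Normal(0, sigma^2)

with priors mu ~ Normal(0, 2.5^2) and sigma ~ half-Normal(0, 1)
(non-centered parameterization). The pooled summary is expit(mu), the
typical-country proportion; the population-average alternative
E[expit(mu + u)] is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import mcmc
from .io_core import TreatmentObservation
from .synthetic import expit


@dataclass
class TreatmentMcmcConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1500
    seed: int = 0


@dataclass
class TreatmentPosterior:
    countries: list[str]
    mu: np.ndarray            # (D,)
    sigma: np.ndarray         # (D,)
    u: np.ndarray             # (D, C)
    rhat: dict[str, float]
    converged: bool

    @property
    def p_country(self) -> np.ndarray:
        return expit(self.mu[:, None] + self.u)


def fit_treatment_meta(observations: Sequence[TreatmentObservation],
                       mcmc_config: TreatmentMcmcConfig | None = None,
                       sigma_fixed: float | None = None) -> TreatmentPosterior:
    """Fit the random-effects meta-analysis.

    ``sigma_fixed`` pins the between-country SD (``0`` collapses the model
    to a single common proportion — useful for conjugate checks).
    """
    if not observations:
        raise ValueError("empty treatment observation set")
    obs = sorted(observations, key=lambda o: o.country)
    countries = [o.country for o in obs]
    k = np.array([o.k_treated for o in obs], float)
    n = np.array([o.n_abnormal for o in obs], float)
    cfg = mcmc_config or TreatmentMcmcConfig()

    fixed_sd = sigma_fixed is not None
    degenerate = fixed_sd and sigma_fixed == 0.0
    blocks = {"mu": 1}
    if not degenerate:
        blocks["u"] = len(obs)
    if not fixed_sd:
        blocks["log_sigma"] = 1
    layout = mcmc.ParamLayout(blocks)

    def logp(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        b = layout.unpack(theta)
        mu = b["mu"][:, 0]
        eta = mu[:, None]
        lp = -0.5 * mu**2 / 2.5**2
        if not degenerate:
            u = b["u"]
            eta = eta + u
            if fixed_sd:
                lp = lp - 0.5 * (u**2).sum(axis=1) / sigma_fixed**2
            else:
                log_sigma = np.clip(b["log_sigma"][:, 0], -50.0, 50.0)
                sigma = np.exp(log_sigma)
                lp = lp + (-0.5 * (u**2).sum(axis=1) / sigma**2
                           - len(obs) * log_sigma
                           - 0.5 * sigma**2 + log_sigma)
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        ll = (k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=1)
        total = ll + lp
        return np.where(np.isfinite(total), total, -np.inf)

    map_fix = None
    hmc_mask = None
    gibbs = None
    prior_precision = None
    if not fixed_sd:
        map_fix = np.zeros(layout.ndim, dtype=bool)
        map_fix[layout.slices["log_sigma"]] = True
        hmc_mask = ~map_fix
        gibbs = mcmc.make_scale_gibbs(layout, [("u", "log_sigma", None)])
        n_sub = layout.slices["log_sigma"].start

        def prior_precision(theta: np.ndarray) -> np.ndarray:
            theta = np.atleast_2d(theta)
            out = np.full((theta.shape[0], n_sub), 1.0 / 2.5**2)
            sd = np.exp(theta[:, layout.slices["log_sigma"]])
            out[:, layout.slices["u"]] = 1.0 / np.maximum(sd**2, 1e-10)
            return out

    result = mcmc.run_hmc(mcmc.fd_value_and_grad(logp), layout,
                          seed=cfg.seed, n_chains=cfg.n_chains,
                          n_warmup=cfg.n_warmup, n_draws=cfg.n_draws,
                          map_fix=map_fix, hmc_mask=hmc_mask,
                          gibbs_update=gibbs,
                          prior_precision=prior_precision,
                          target_accept=0.9)
    converged = mcmc.check_convergence(result, context="treatment meta")
    D = result.draws.shape[0]
    sigma = (np.full(D, float(sigma_fixed)) if fixed_sd
             else np.exp(result.block("log_sigma")))
    u = (np.zeros((D, len(obs))) if degenerate
         else result.block("u").reshape(D, -1))
    return TreatmentPosterior(countries=countries, mu=result.block("mu"),
                              sigma=sigma, u=u,
                              rhat=result.rhat, converged=converged)


def pooled_estimate(posterior: TreatmentPosterior,
                    population_average: bool = False,
                    n_mc: int = 64) -> dict:
    """Median and 95% CrI of pooled treatment coverage.

    Default is the typical-country proportion expit(mu); with
    ``population_average`` the random-effect distribution is integrated out
    by Gauss-Hermite quadrature.
    """
    if population_average:
        nodes, w = np.polynomial.hermite_e.hermegauss(n_mc)
        w = w / w.sum()
        draws = (expit(posterior.mu[:, None]
                       + posterior.sigma[:, None] * nodes) * w).sum(axis=1)
    else:
        draws = expit(posterior.mu)
    out = {key: float(v) for key, v in mcmc.summarize(draws).items()}
    out["draws"] = draws
    return out


def country_estimates(posterior: TreatmentPosterior) -> pd.DataFrame:
    """Per-country shrunken treatment coverage: median and 95% CrI."""
    p = posterior.p_country
    s = mcmc.summarize(p, axis=0)
    return pd.DataFrame({
        "country": posterior.countries, "median": s["median"],
        "lo95": s["lo95"], "hi95": s["hi95"]})
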