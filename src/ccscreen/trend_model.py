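"""Four-level Bayesian multilevel binomial logistic regression of screening
coverage.

Lifetime and past-3-year screening reports are modeled jointly: each survey
stratum contributes a binomial likelihood ``k ~ Binomial(n, p)`` with

    logit p = beta0 + u_region + u_country + u_survey + alpha_age
              + (beta_year + v_region + v_country) * (year - 2010)/10
              + beta_recall * 1[recall = past3y]
              + (gamma + g_region + g_country) * 1[hiv = pos]

Random intercepts are nested survey < country < region < overall; year
slopes and the HIV log-odds-ratio carry country- and region-level
deviations. Strata that do not report HIV serostatus enter through the
marginalized mixture ``p_all = pi * p_pos + (1 - pi) * p_neg`` with ``pi``
the stratum's HIV prevalence from the auxiliary tables.

Priors are weakly informative: Normal(0, 2.5^2) on fixed effects (the
recall offset constrained non-positive, since past-3-year screeners are a
subset of lifetime screeners) and half-Normal(0, 1) on all standard
deviations. Random effects are stored centered; the sampling machinery
(scale-aware kinetic metric, exact conditional updates of the SDs, and
recentering translation moves) is described in :mod:`ccscreen.mcmc` and
docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mcmc
from .io_core import AGE_BANDS, AuxTables, StratumObservation, integerize_counts
from .synthetic import expit

SD_NAMES = ("sigma_survey", "sigma_country", "sigma_region",
            "tau_country", "tau_region", "omega_country", "omega_region")


@dataclass
class TrendMcmcConfig:
    """Sampler settings; defaults give desk-scale runtimes on the default
    synthetic world."""

    n_chains: int = 4
    n_warmup: int = 1500
    n_draws: int = 4000
    seed: int = 0


@dataclass
class PriorConfig:
    fixed_scale: float = 2.5
    sd_scale: float = 1.0


@dataclass
class TrendPosterior:
    """Posterior draws of all trend-model parameters.

    Draw arrays are pooled over walkers; shapes are ``(D,)`` for scalars and
    ``(D, n_groups)`` for random-effect blocks, with group order given by
    the label lists.
    """

    surveys: list[str]
    countries: list[str]
    regions: list[str]
    country_region_idx: np.ndarray          # country -> region index
    params: dict[str, np.ndarray]
    rhat: dict[str, float]
    ess_bulk: dict[str, float]
    converged: bool
    whs_fixed_effect: bool = False
    n_divergent: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.params["beta0"])

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def subsample(self, n: int) -> "TrendPosterior":
        """Deterministic, evenly spaced thinning to at most ``n`` draws."""
        if n >= self.n_draws:
            return self
        idx = np.linspace(0, self.n_draws - 1, n).astype(int)
        return TrendPosterior(
            surveys=self.surveys, countries=self.countries,
            regions=self.regions, country_region_idx=self.country_region_idx,
            params={k: v[idx] for k, v in self.params.items()},
            rhat=self.rhat, ess_bulk=self.ess_bulk, converged=self.converged,
            whs_fixed_effect=self.whs_fixed_effect,
            n_divergent=self.n_divergent)

    # -- persistence -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long format (draw, parameter, value) for CSV persistence."""
        rows = []
        for name, arr in self.params.items():
            if arr.ndim == 1:
                rows.append(pd.DataFrame(
                    {"draw": np.arange(len(arr)), "parameter": name,
                     "value": arr}))
            else:
                labels = {"u_survey": self.surveys,
                          "u_country": self.countries,
                          "v_country": self.countries,
                          "g_country": self.countries,
                          "u_region": self.regions,
                          "v_region": self.regions,
                          "g_region": self.regions,
                          "alpha": list(AGE_BANDS[1:])}[name]
                for j, lab in enumerate(labels):
                    rows.append(pd.DataFrame(
                        {"draw": np.arange(arr.shape[0]),
                         "parameter": f"{name}[{lab}]", "value": arr[:, j]}))
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrendPosterior":
        """Rebuild a posterior from the long-format draws CSV (diagnostics
        are not stored in the CSV; R-hat is set to the recorded flag only)."""
        from .regions import map_country_to_region
        long = pd.read_csv(path)
        wide = long.pivot(index="draw", columns="parameter", values="value")
        scalars = {"beta0", "beta_year", "beta_recall", "gamma", "beta_whs",
                   *SD_NAMES}
        params: dict[str, np.ndarray] = {}
        grouped: dict[str, list[tuple[str, str]]] = {}
        for col in wide.columns:
            if col in scalars:
                params[col] = wide[col].to_numpy()
            else:
                name, label = col[:-1].split("[", 1)
                grouped.setdefault(name, []).append((label, col))
        surveys = sorted(lab for lab, _ in grouped.get("u_survey", []))
        countries = sorted(lab for lab, _ in grouped.get("u_country", []))
        regions = sorted(lab for lab, _ in grouped.get("u_region", []))
        for name, pairs in grouped.items():
            if name == "alpha":
                order = list(AGE_BANDS[1:])
            elif name == "u_survey":
                order = surveys
            elif name.endswith("_country"):
                order = countries
            else:
                order = regions
            cols = dict(pairs)
            params[name] = np.column_stack(
                [wide[cols[lab]].to_numpy() for lab in order])
        cri = np.array([regions.index(map_country_to_region(c))
                        for c in countries])
        return cls(surveys=surveys, countries=countries, regions=regions,
                   country_region_idx=cri, params=params, rhat={"stored": 1.0},
                   ess_bulk={"stored": float("nan")}, converged=True,
                   whs_fixed_effect="beta_whs" in params)


@dataclass
class CoverageDraws:
    """Posterior coverage draws on a prediction grid.

    ``grid`` has columns country, year, age_group, hiv, recall; ``draws``
    has one row per grid point, one column per posterior draw.
    """

    grid: pd.DataFrame
    draws: np.ndarray

    def summary(self) -> pd.DataFrame:
        s = mcmc.summarize(self.draws, axis=1)
        out = self.grid.copy()
        out["median"], out["lo95"], out["hi95"] = s["median"], s["lo95"], s["hi95"]
        return out

    def write_csv(self, path: str | Path) -> None:
        long = self.grid.loc[self.grid.index.repeat(self.draws.shape[1])].copy()
        long["draw"] = np.tile(np.arange(self.draws.shape[1]), len(self.grid))
        long["p"] = self.draws.ravel()
        long.to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "CoverageDraws":
        long = pd.read_csv(path)
        keys = ["country", "year", "age_group", "hiv", "recall"]
        grid = long[keys].drop_duplicates().reset_index(drop=True)
        n_draws = long["draw"].nunique()
        draws = long["p"].to_numpy().reshape(len(grid), n_draws)
        return cls(grid=grid, draws=draws)


# ---------------------------------------------------------------------------
# Reference single-draw stratum probability
# ---------------------------------------------------------------------------

def stratum_probability(params: Mapping[str, float | Mapping[str, float]],
                        covariates: Mapping[str, object],
                        prevalence: float | None = None) -> float:
    """Success probability of one stratum under one parameter draw.

    ``params`` carries scalars ``beta0, beta_year, beta_recall, gamma`` and
    optional random-effect scalars (``u_survey, u_country, u_region,
    v_country, v_region, g_country, g_region``, default 0) plus an ``alpha``
    mapping age band -> effect (reference band 0). ``covariates`` names
    ``year, age_group, recall, hiv``. For ``hiv="all"`` the HIV prevalence
    ``pi`` must be supplied and the result is the exact mixture
    ``pi * p_pos + (1 - pi) * p_neg``.
    """
    g = lambda key: float(params.get(key, 0.0))
    alpha = params.get("alpha", {})
    x = (float(covariates["year"]) - 2010.0) / 10.0
    eta = (g("beta0") + g("u_region") + g("u_country") + g("u_survey")
           + float(alpha.get(str(covariates["age_group"]), 0.0))
           + (g("beta_year") + g("v_region") + g("v_country")) * x)
    if covariates["recall"] == "past3y":
        eta += g("beta_recall")
    gamma_tot = g("gamma") + g("g_region") + g("g_country")
    hiv = covariates["hiv"]
    if hiv == "neg":
        return float(expit(eta))
    if hiv == "pos":
        return float(expit(eta + gamma_tot))
    if hiv == "all":
        if prevalence is None:
            raise ValueError("hiv='all' stratum needs the HIV prevalence pi")
        pi = float(prevalence)
        return float(pi * expit(eta + gamma_tot) + (1.0 - pi) * expit(eta))
    raise ValueError(f"unknown hiv level {hiv!r}")


# ---------------------------------------------------------------------------
# Data assembly
# ---------------------------------------------------------------------------

@dataclass
class _Design:
    surveys: list[str]
    countries: list[str]
    regions: list[str]
    country_region_idx: np.ndarray
    iv: np.ndarray
    ic: np.ndarray
    ir: np.ndarray
    age_idx: np.ndarray
    x: np.ndarray
    rec: np.ndarray
    whs: np.ndarray
    hiv_code: np.ndarray    # 0 neg, 1 pos, 2 all
    pi: np.ndarray
    k: np.ndarray
    n: np.ndarray


def _assemble(observations: Sequence[StratumObservation],
              aux: AuxTables) -> _Design:
    if not observations:
        raise ValueError("empty observation set")
    surveys = sorted({o.survey_id for o in observations})
    countries = sorted({o.country for o in observations})
    regions = sorted({o.region for o in observations})
    s_idx = {s: i for i, s in enumerate(surveys)}
    c_idx = {c: i for i, c in enumerate(countries)}
    r_idx = {r: i for i, r in enumerate(regions)}
    country_region = np.array(
        [r_idx[next(o.region for o in observations if o.country == c)]
         for c in countries])
    band_idx = {b: i for i, b in enumerate(AGE_BANDS)}

    rows = dict(iv=[], ic=[], ir=[], age=[], x=[], rec=[], whs=[], hiv=[],
                pi=[], k=[], n=[])
    for o in observations:
        if o.age_group not in band_idx:
            raise ValueError(
                f"stratum {o.survey_id}/{o.age_group}: trend model expects "
                f"5-year bands {AGE_BANDS}")
        if o.recall not in ("lifetime", "past3y"):
            raise ValueError(
                f"stratum {o.survey_id}: recall {o.recall!r} not modeled "
                "(trend model uses lifetime and past3y)")
        k, n = integerize_counts(o.p_hat, o.n_eff)
        pi = 0.0
        if o.hiv == "all":
            pi = aux.prev(o.country, o.year, o.age_group)
        rows["iv"].append(s_idx[o.survey_id])
        rows["ic"].append(c_idx[o.country])
        rows["ir"].append(r_idx[o.region])
        rows["age"].append(band_idx[o.age_group])
        rows["x"].append((o.year - 2010.0) / 10.0)
        rows["rec"].append(1.0 if o.recall == "past3y" else 0.0)
        rows["whs"].append(1.0 if o.survey_type == "WHS" else 0.0)
        rows["hiv"].append({"neg": 0, "pos": 1, "all": 2}[o.hiv])
        rows["pi"].append(pi)
        rows["k"].append(k)
        rows["n"].append(n)
    arr = {k: np.asarray(v) for k, v in rows.items()}
    if not np.isfinite(arr["x"]).all():
        raise ValueError("non-finite year covariate in design")
    return _Design(surveys=surveys, countries=countries, regions=regions,
                   country_region_idx=country_region,
                   iv=arr["iv"], ic=arr["ic"], ir=arr["ir"],
                   age_idx=arr["age"], x=arr["x"].astype(float),
                   rec=arr["rec"], whs=arr["whs"], hiv_code=arr["hiv"],
                   pi=arr["pi"].astype(float),
                   k=arr["k"].astype(float), n=arr["n"].astype(float))


def _make_layout(d: _Design, whs: bool) -> mcmc.ParamLayout:
    # zeta_recall parameterizes the recall offset as beta_recall = -exp(zeta),
    # keeping the non-positivity constraint smooth for gradient-based MCMC.
    # Random effects are centered (sampled on their natural scale): the
    # effective sample sizes make group effects data-dominated, where the
    # centered parameterization avoids the funnel.
    blocks = {
        "beta0": 1, "beta_year": 1, "alpha": len(AGE_BANDS) - 1,
        "zeta_recall": 1, "gamma": 1,
    }
    if whs:
        blocks["beta_whs"] = 1
    blocks.update({
        "u_survey": len(d.surveys),
        "u_country": len(d.countries), "v_country": len(d.countries),
        "g_country": len(d.countries),
        "u_region": len(d.regions), "v_region": len(d.regions),
        "g_region": len(d.regions),
        "log_sd": len(SD_NAMES),
    })
    return mcmc.ParamLayout(blocks)


def _segment_sum(vals: np.ndarray, idx: np.ndarray, n_groups: int
                 ) -> np.ndarray:
    """Row-wise segment sums: (B, S) values grouped by idx -> (B, n_groups)."""
    B = vals.shape[0]
    flat_idx = (np.arange(B)[:, None] * n_groups + idx[None, :]).ravel()
    return np.bincount(flat_idx, weights=vals.ravel(),
                       minlength=B * n_groups).reshape(B, n_groups)


#: random-effect blocks sampled non-centered (z = effect / SD). Random
#: effects are stored centered by default: the SDs are excluded from the
#: Hamiltonian trajectory (interweaved slice updates instead) and the
#: kinetic metric tracks the prior precision 1/sd^2 as the scales move, so
#: the centered frame stays well-conditioned across the whole scale range.
NCP_BLOCKS: frozenset = frozenset()


def _model_fns(d: _Design, layout: mcmc.ParamLayout,
               priors: PriorConfig, whs: bool,
               ncp: frozenset = NCP_BLOCKS):
    """Vectorized log-posterior with analytic gradient.

    The binomial log-likelihood gradient flows through two channels per
    stratum: d loglik / d eta (the serostatus-negative linear predictor) and
    d loglik / d gamma_tot (the total HIV effect); serostatus-mixed strata
    weight the two component logistic densities by prevalence. Blocks in
    ``ncp`` are parameterized non-centered (parameter = effect / SD).

    The returned callable ``value_and_grad(theta, want_grad=True)`` also
    exposes ``forward_parts``, ``loglik_eta`` and ``block_meta`` attributes
    used by the interweaved scale updates to recompute the likelihood
    incrementally when a single block is rescaled.
    """
    neg_mask = d.hiv_code == 0
    pos_mask = d.hiv_code == 1
    fs2 = priors.fixed_scale**2
    ss2 = priors.sd_scale**2
    n_v, n_c, n_r = len(d.surveys), len(d.countries), len(d.regions)
    sl = layout.slices

    blocks_sd = (("u_survey", 0), ("u_country", 1), ("u_region", 2),
                 ("v_country", 3), ("v_region", 4), ("g_country", 5),
                 ("g_region", 6))
    # how each block enters the linear predictors: channel, stratum index,
    # per-stratum multiplier
    block_meta = {
        "u_survey": ("eta", d.iv, 1.0),
        "u_country": ("eta", d.ic, 1.0),
        "u_region": ("eta", d.ir, 1.0),
        "v_country": ("eta", d.ic, d.x),
        "v_region": ("eta", d.ir, d.x),
        "g_country": ("g", d.ic, 1.0),
        "g_region": ("g", d.ir, 1.0),
    }

    def unpack(theta):
        theta = np.atleast_2d(theta)
        b = layout.unpack(theta)
        sd = np.exp(b["log_sd"])
        beta_recall = -np.exp(b["zeta_recall"][:, 0])
        return theta, b, sd, beta_recall

    def forward_parts(theta):
        """Linear predictors eta (hiv-negative) and total HIV effect."""
        theta, b, sd, beta_recall = unpack(theta)
        B = theta.shape[0]
        eff = {name: (sd[:, j:j + 1] * b[name] if name in ncp else b[name])
               for name, j in blocks_sd}
        alpha_full = np.concatenate([np.zeros((B, 1)), b["alpha"]], axis=1)
        eta = (b["beta0"]
               + alpha_full[:, d.age_idx]
               + eff["u_region"][:, d.ir] + eff["u_country"][:, d.ic]
               + eff["u_survey"][:, d.iv]
               + (b["beta_year"] + eff["v_region"][:, d.ir]
                  + eff["v_country"][:, d.ic]) * d.x
               + beta_recall[:, None] * d.rec)
        if whs:
            eta = eta + b["beta_whs"] * d.whs
        g_tot = (b["gamma"] + eff["g_region"][:, d.ir]
                 + eff["g_country"][:, d.ic])
        return eta, g_tot

    def loglik_eta(eta, g_tot):
        """Binomial log likelihood given the linear predictors."""
        p_neg = expit(eta)
        p_pos = expit(eta + g_tot)
        p = np.where(neg_mask, p_neg,
                     np.where(pos_mask, p_pos,
                              d.pi * p_pos + (1.0 - d.pi) * p_neg))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        ll = (d.k * np.log(p) + (d.n - d.k) * np.log1p(-p)).sum(axis=1)
        return ll, p_neg, p_pos, p

    def logprior(b, sd, beta_recall, log_sd, zeta):
        prior_terms = 0.0
        for name, j in blocks_sd:
            raw = b[name]
            sq = (raw**2).sum(axis=1)
            if name in ncp:
                prior_terms = prior_terms - 0.5 * sq
            else:
                prior_terms = prior_terms + (-0.5 * sq / sd[:, j] ** 2
                                             - raw.shape[1] * log_sd[:, j])
        fixed_sq = (b["beta0"]**2 + b["beta_year"]**2
                    + b["gamma"]**2).sum(axis=1) + (b["alpha"]**2).sum(
                        axis=1) + beta_recall**2
        if whs:
            fixed_sq = fixed_sq + (b["beta_whs"]**2).sum(axis=1)
        return (-0.5 * fixed_sq / fs2 + zeta + prior_terms
                + (-0.5 * sd**2 / ss2 + log_sd).sum(axis=1))

    def value_and_grad(theta, want_grad: bool = True):
        theta, b, sd, beta_recall = unpack(theta)
        B = theta.shape[0]
        log_sd = b["log_sd"]
        zeta = b["zeta_recall"][:, 0]
        eta, g_tot = forward_parts(theta)
        loglik, p_neg, p_pos, p = loglik_eta(eta, g_tot)
        lp = loglik + logprior(b, sd, beta_recall, log_sd, zeta)
        if not want_grad:
            return lp, None

        q_neg = p_neg * (1.0 - p_neg)
        q_pos = p_pos * (1.0 - p_pos)
        # dloglik/deta (a) and dloglik/dg_tot (c) per stratum
        resid = d.k - d.n * p
        w = resid / (p * (1.0 - p))
        a = np.where(neg_mask, d.k - d.n * p_neg,
                     np.where(pos_mask, d.k - d.n * p_pos,
                              w * (d.pi * q_pos + (1.0 - d.pi) * q_neg)))
        c = np.where(neg_mask, 0.0,
                     np.where(pos_mask, d.k - d.n * p_pos, w * d.pi * q_pos))

        grad = np.empty_like(theta)
        grad[:, sl["beta0"]] = a.sum(axis=1, keepdims=True) - b["beta0"] / fs2
        ax = a * d.x
        grad[:, sl["beta_year"]] = (ax.sum(axis=1, keepdims=True)
                                    - b["beta_year"] / fs2)
        age_sums = _segment_sum(a, d.age_idx, len(AGE_BANDS))
        grad[:, sl["alpha"]] = age_sums[:, 1:] - b["alpha"] / fs2
        # d eta/d zeta = rec * d beta_recall/d zeta = rec * beta_recall
        grad[:, sl["zeta_recall"]] = (
            (a * d.rec).sum(axis=1) * beta_recall
            - beta_recall**2 / fs2 + 1.0)[:, None]
        grad[:, sl["gamma"]] = c.sum(axis=1, keepdims=True) - b["gamma"] / fs2
        if whs:
            grad[:, sl["beta_whs"]] = ((a * d.whs).sum(axis=1, keepdims=True)
                                       - b["beta_whs"] / fs2)

        sums = {
            "u_survey": _segment_sum(a, d.iv, n_v),
            "u_country": _segment_sum(a, d.ic, n_c),
            "u_region": _segment_sum(a, d.ir, n_r),
            "v_country": _segment_sum(ax, d.ic, n_c),
            "v_region": _segment_sum(ax, d.ir, n_r),
            "g_country": _segment_sum(c, d.ic, n_c),
            "g_region": _segment_sum(c, d.ir, n_r),
        }
        sd_grad = np.empty((B, 7))
        for name, j in blocks_sd:
            raw = b[name]
            n_g = raw.shape[1]
            sq = (raw**2).sum(axis=1)
            if name in ncp:
                # raw is z ~ N(0,1); effect = sd * z
                grad[:, sl[name]] = sd[:, j:j + 1] * sums[name] - raw
                sd_grad[:, j] = (raw * sums[name]).sum(axis=1) * sd[:, j]
            else:
                var = sd[:, j:j + 1] ** 2
                grad[:, sl[name]] = sums[name] - raw / var
                # d/d log_sd of [-sq/(2 sd^2) - n_g log_sd]
                sd_grad[:, j] = sq / var[:, 0] - n_g
        grad[:, sl["log_sd"]] = sd_grad - sd**2 / ss2 + 1.0
        return lp, grad

    value_and_grad.forward_parts = forward_parts
    value_and_grad.loglik_eta = lambda eta, g_tot: loglik_eta(eta, g_tot)[0]
    value_and_grad.block_meta = block_meta
    value_and_grad.ncp = ncp
    return value_and_grad


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _make_sd_gibbs(layout: mcmc.ParamLayout, sd_scale: float, fns,
                   n_sweeps: int = 1, include_ancillary: bool = True):
    """Interweaved slice update of the hierarchical SDs
    (ancillarity-sufficiency interweaving).

    Two 1-D slice moves per SD, alternated every iteration:

    1. Sufficient (centered) frame: holding the effects U = sigma * z
       fixed, the conditional of lam = log sigma has the closed form
       ``-SS e^{-2 lam}/2 - n lam - e^{2 lam}/(2 s^2) + lam``
       (generalized-inverse-Gaussian in sigma^2); afterwards z is rescaled
       to preserve U.
    2. Ancillary (non-centered) frame: holding z fixed, lam is updated
       against the full posterior (the likelihood moves through sigma * z).

    Interweaving the two frames mixes the scales efficiently whether a
    block is data-dominated or prior-dominated, without dragging the
    funnel geometry into the Hamiltonian trajectory.
    """
    sl_sd = layout.slices["log_sd"]
    block_names = ("u_survey", "u_country", "u_region", "v_country",
                   "v_region", "g_country", "g_region")

    def gibbs(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        for _ in range(n_sweeps):
            theta = _sweep(theta, rng)
        return theta

    def _sweep(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        theta = theta.copy()
        ss2 = sd_scale**2
        # sufficient-frame moves first: closed-form conditional given the
        # centered effects U, which stay untouched
        for j, name in enumerate(block_names):
            sl_b = layout.slices[name]
            col = sl_sd.start + j
            U = theta[:, sl_b]
            n_g = U.shape[1]
            ss = (U**2).sum(axis=1) + 1e-300

            def cond_centered(lam_vec):
                return (-0.5 * ss * np.exp(-2.0 * lam_vec)
                        - n_g * lam_vec
                        - 0.5 * np.exp(2.0 * lam_vec) / ss2 + lam_vec)

            theta[:, col] = mcmc.batched_slice_sample(
                cond_centered, theta[:, col], rng, width=0.8)

        if not include_ancillary:
            return theta
        # ancillary-frame moves: z = U / sd held fixed, the block rescales
        # with sd; likelihood recomputed incrementally from the block's
        # stratum contribution
        eta, g_tot = fns.forward_parts(theta)
        for j, name in enumerate(block_names):
            sl_b = layout.slices[name]
            col = sl_sd.start + j
            channel, idx, mult = fns.block_meta[name]
            lam1 = theta[:, col]
            z = theta[:, sl_b] * np.exp(-lam1)[:, None]
            contrib = z[:, idx] * mult                     # (B, S)
            scale1 = np.exp(lam1)[:, None]
            if channel == "eta":
                base = eta - scale1 * contrib

                def cond_ancillary(lam_vec):
                    e = base + np.exp(lam_vec)[:, None] * contrib
                    ll = fns.loglik_eta(e, g_tot)
                    return (ll - 0.5 * np.exp(2.0 * lam_vec) / ss2
                            + lam_vec)
            else:
                base = g_tot - scale1 * contrib

                def cond_ancillary(lam_vec):
                    g = base + np.exp(lam_vec)[:, None] * contrib
                    ll = fns.loglik_eta(eta, g)
                    return (ll - 0.5 * np.exp(2.0 * lam_vec) / ss2
                            + lam_vec)

            lam2 = mcmc.batched_slice_sample(cond_ancillary, lam1, rng,
                                             width=0.6)
            theta[:, col] = lam2
            theta[:, sl_b] = z * np.exp(lam2)[:, None]
            if channel == "eta":
                eta = base + np.exp(lam2)[:, None] * contrib
            else:
                g_tot = base + np.exp(lam2)[:, None] * contrib
        return theta

    return gibbs


def _make_translation_gibbs(layout: mcmc.ParamLayout, d: _Design,
                            priors: PriorConfig):
    """Exact Gaussian translation moves along likelihood-null directions.

    In the nested model the likelihood constrains only sums such as
    ``beta0 + u_region + u_country + u_survey``; the split between levels
    is prior-driven. Each move shifts one level by ``t`` and compensates
    the level below so every linear predictor is unchanged, with ``t``
    drawn from its exact Gaussian conditional (product of the Gaussian
    priors involved). These recentering sweeps decorrelate the levels and
    let the scale parameters mix quickly.
    """
    sl = layout.slices
    sd_pos = {name: layout.slices["log_sd"].start + j for name, j in
              (("sigma_survey", 0), ("sigma_country", 1),
               ("sigma_region", 2), ("tau_country", 3), ("tau_region", 4),
               ("omega_country", 5), ("omega_region", 6))}
    # survey -> (country index, year covariate); constant within survey
    n_v = len(d.surveys)
    surv_country = np.zeros(n_v, dtype=int)
    surv_x = np.zeros(n_v)
    for i in range(n_v):
        s = np.flatnonzero(d.iv == i)[0]
        surv_country[i] = d.ic[s]
        surv_x[i] = d.x[s]
    country_surveys = [np.flatnonzero(surv_country == c)
                       for c in range(len(d.countries))]
    region_countries = [np.flatnonzero(d.country_region_idx == r)
                        for r in range(len(d.regions))]
    fs2 = priors.fixed_scale**2

    def var_of(theta, name):
        return np.exp(2.0 * theta[:, sd_pos[name]])

    def draw_t(rng, prec, mean_num):
        m = mean_num / prec
        return m + rng.standard_normal(m.shape[0]) / np.sqrt(prec)

    def gibbs(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        theta = theta.copy()
        v_svy = var_of(theta, "sigma_survey")
        v_cty = var_of(theta, "sigma_country")
        v_rgn = var_of(theta, "sigma_region")
        v_tc = var_of(theta, "tau_country")
        v_tr = var_of(theta, "tau_region")
        v_oc = var_of(theta, "omega_country")
        v_or = var_of(theta, "omega_region")
        u_v = theta[:, sl["u_survey"]]
        u_c = theta[:, sl["u_country"]]
        u_r = theta[:, sl["u_region"]]
        v_c = theta[:, sl["v_country"]]
        v_r = theta[:, sl["v_region"]]
        g_c = theta[:, sl["g_country"]]
        g_r = theta[:, sl["g_region"]]

        for c, vs in enumerate(country_surveys):
            if vs.size == 0:
                continue
            # country intercept <-> its survey intercepts
            prec = 1.0 / v_cty + vs.size / v_svy
            num = -u_c[:, c] / v_cty + u_v[:, vs].sum(axis=1) / v_svy
            t = draw_t(rng, prec, num)
            u_c[:, c] += t
            u_v[:, vs] -= t[:, None]
            # country slope <-> survey intercepts (x constant per survey)
            xs = surv_x[vs]
            prec = 1.0 / v_tc + (xs**2).sum() / v_svy
            num = (-v_c[:, c] / v_tc
                   + (u_v[:, vs] * xs).sum(axis=1) / v_svy)
            t = draw_t(rng, prec, num)
            v_c[:, c] += t
            u_v[:, vs] -= t[:, None] * xs

        for r, cs in enumerate(region_countries):
            if cs.size == 0:
                continue
            for top, low, vt, vl in ((u_r, u_c, v_rgn, v_cty),
                                     (v_r, v_c, v_tr, v_tc),
                                     (g_r, g_c, v_or, v_oc)):
                prec = 1.0 / vt + cs.size / vl
                num = -top[:, r] / vt + low[:, cs].sum(axis=1) / vl
                t = draw_t(rng, prec, num)
                top[:, r] += t
                low[:, cs] -= t[:, None]

        n_r = u_r.shape[1]
        for glob, top, vt in ((sl["beta0"], u_r, v_rgn),
                              (sl["beta_year"], v_r, v_tr),
                              (sl["gamma"], g_r, v_or)):
            prec = 1.0 / fs2 + n_r / vt
            num = -theta[:, glob.start] / fs2 + top.sum(axis=1) / vt
            t = draw_t(rng, prec, num)
            theta[:, glob.start] += t
            top -= t[:, None]
        return theta

    return gibbs


def fit_trend_model(observations: Sequence[StratumObservation],
                    aux: AuxTables,
                    mcmc_config: TrendMcmcConfig | None = None,
                    priors: PriorConfig | None = None,
                    year_min: float | None = None,
                    whs_fixed_effect: bool = False) -> TrendPosterior:
    """Fit the four-level trend model and return posterior draws.

    ``year_min`` restricts the fit to surveys at or after that year (the
    2010-onward sensitivity analysis); ``whs_fixed_effect`` adds a fixed
    effect for WHS-type surveys. Counts are integerized on entry. The fit
    warns loudly (and flags the posterior) when any split-chain R-hat
    exceeds 1.05 rather than returning silently.
    """
    cfg = mcmc_config or TrendMcmcConfig()
    priors = priors or PriorConfig()
    obs = list(observations)
    if year_min is not None:
        obs = [o for o in obs if o.year >= year_min]
    d = _assemble(obs, aux)
    layout = _make_layout(d, whs_fixed_effect)
    value_and_grad = _model_fns(d, layout, priors, whs_fixed_effect)

    init = np.zeros(layout.ndim)
    init[layout.slices["log_sd"]] = np.log(0.3)
    init[layout.slices["zeta_recall"]] = np.log(0.1)
    # the joint mode over (effects, SDs) is degenerate in the centered
    # parameterization, so the MAP initialization holds the SDs fixed;
    # the SDs themselves are Gibbs-sampled from their exact conditionals
    # rather than moved by the trajectory
    map_fix = np.zeros(layout.ndim, dtype=bool)
    map_fix[layout.slices["log_sd"]] = True

    sd_col = {"u_survey": 0, "u_country": 1, "u_region": 2, "v_country": 3,
              "v_region": 4, "g_country": 5, "g_region": 6}
    n_sub = layout.slices["log_sd"].start          # log_sd is the last block

    def prior_precision(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        out = np.full((theta.shape[0], n_sub), 1.0 / priors.fixed_scale**2)
        sd = np.exp(theta[:, layout.slices["log_sd"]])
        for name, j in sd_col.items():
            out[:, layout.slices[name]] = 1.0 / np.maximum(
                sd[:, j:j + 1] ** 2, 1e-10)
        return out

    sd_gibbs = _make_sd_gibbs(layout, priors.sd_scale, value_and_grad)
    sd_sufficient = _make_sd_gibbs(layout, priors.sd_scale, value_and_grad,
                                   include_ancillary=False)
    trans_gibbs = _make_translation_gibbs(layout, d, priors)

    def gibbs_update(theta, rng):
        # extra cheap sweeps of the closed-form moves decorrelate the
        # (scale, effect-spread) pair; one full interweaved sweep follows
        for _ in range(3):
            theta = sd_sufficient(trans_gibbs(theta, rng), rng)
        return sd_gibbs(trans_gibbs(theta, rng), rng)

    result = mcmc.run_hmc(
        value_and_grad, layout, seed=cfg.seed, n_chains=cfg.n_chains,
        n_warmup=cfg.n_warmup, n_draws=cfg.n_draws, init=init,
        map_fix=map_fix, hmc_mask=~map_fix,
        gibbs_update=gibbs_update,
        prior_precision=prior_precision)
    converged = mcmc.check_convergence(result, warn_at=1.05,
                                       context="trend model")

    D = result.draws.shape[0]
    sd = np.exp(result.block("log_sd"))
    params: dict[str, np.ndarray] = {
        "beta0": result.block("beta0"),
        "beta_year": result.block("beta_year"),
        "alpha": result.block("alpha"),
        "beta_recall": -np.exp(result.block("zeta_recall")),
        "gamma": result.block("gamma"),
    }
    sd_col = {"u_survey": 0, "u_country": 1, "u_region": 2, "v_country": 3,
              "v_region": 4, "g_country": 5, "g_region": 6}
    for name, j in sd_col.items():
        raw = result.block(name).reshape(D, -1)
        params[name] = sd[:, j:j + 1] * raw if name in NCP_BLOCKS else raw
    for j, name in enumerate(SD_NAMES):
        params[name] = sd[:, j]
    if whs_fixed_effect:
        params["beta_whs"] = result.block("beta_whs")

    return TrendPosterior(
        surveys=d.surveys, countries=d.countries, regions=d.regions,
        country_region_idx=d.country_region_idx, params=params,
        rhat=result.rhat, ess_bulk=result.ess_bulk, converged=converged,
        whs_fixed_effect=whs_fixed_effect, n_divergent=result.n_divergent)


# ---------------------------------------------------------------------------
# Prediction, odds ratios, PPC
# ---------------------------------------------------------------------------

def make_grid(countries: Sequence[str], years: Sequence[float],
              age_groups: Sequence[str] = AGE_BANDS,
              hiv: Sequence[str] = ("neg", "pos"),
              recall: Sequence[str] = ("lifetime", "past3y")) -> pd.DataFrame:
    idx = pd.MultiIndex.from_product(
        [countries, years, age_groups, hiv, recall],
        names=["country", "year", "age_group", "hiv", "recall"])
    return idx.to_frame(index=False)


def _predict_eta(posterior: TrendPosterior, grid: pd.DataFrame,
                 u_c: np.ndarray | None = None, v_c: np.ndarray | None = None,
                 g_c: np.ndarray | None = None,
                 region_override: str | None = None) -> np.ndarray:
    """Logit-scale draws (n_grid, D) for the hiv=neg stratum, and the total
    HIV effect as second return. Country effects can be overridden (used by
    imputation)."""
    p = posterior.params
    D = posterior.n_draws
    band_idx = {b: i for i, b in enumerate(AGE_BANDS)}
    alpha_full = np.concatenate([np.zeros((D, 1)), p["alpha"]], axis=1)

    etas = np.empty((len(grid), D))
    gtots = np.empty((len(grid), D))
    c_idx = {c: i for i, c in enumerate(posterior.countries)}
    r_idx = {r: i for i, r in enumerate(posterior.regions)}
    for row_i, row in enumerate(grid.itertuples(index=False)):
        if region_override is not None:
            ir = r_idx[region_override]
            uc = u_c[:, 0] if u_c is not None else 0.0
            vc = v_c[:, 0] if v_c is not None else 0.0
            gc = g_c[:, 0] if g_c is not None else 0.0
        else:
            if row.country not in c_idx:
                raise KeyError(
                    f"country {row.country!r} was not observed; use "
                    "poststrat.impute_country for countries without surveys")
            ic = c_idx[row.country]
            ir = posterior.country_region_idx[ic]
            uc, vc, gc = (p["u_country"][:, ic], p["v_country"][:, ic],
                          p["g_country"][:, ic])
        x = (row.year - 2010.0) / 10.0
        eta = (p["beta0"] + p["u_region"][:, ir] + uc
               + alpha_full[:, band_idx[str(row.age_group)]]
               + (p["beta_year"] + p["v_region"][:, ir] + vc) * x)
        if row.recall == "past3y":
            eta = eta + p["beta_recall"]
        elif row.recall != "lifetime":
            raise ValueError(f"unknown recall {row.recall!r}")
        etas[row_i] = eta
        gtots[row_i] = p["gamma"] + p["g_region"][:, ir] + gc
    return etas, gtots


def predict_coverage(posterior: TrendPosterior, grid: pd.DataFrame,
                     max_draws: int = 4000) -> CoverageDraws:
    """Coverage draws on a (country, year, age_group, hiv, recall) grid.

    Population-level prediction: survey intercepts are excluded. The
    past-3-year <= lifetime ordering holds draw-wise because the recall
    offset is non-positive in every draw.
    """
    post = posterior.subsample(max_draws)
    grid = grid.reset_index(drop=True)
    etas, gtots = _predict_eta(post, grid)
    hiv = grid["hiv"].to_numpy()
    draws = np.where((hiv == "pos")[:, None], expit(etas + gtots), expit(etas))
    bad = ~np.isin(hiv, ("pos", "neg"))
    if bad.any():
        raise ValueError("prediction grid hiv must be 'pos' or 'neg'; "
                         "serostatus-combined aggregates come from poststrat")
    return CoverageDraws(grid=grid, draws=draws)


def hiv_odds_ratio(posterior: TrendPosterior, country: str | None = None,
                   region: str | None = None) -> dict:
    """Draws and summary of the adjusted HIV odds ratio exp(gamma + g_r + g_c).

    With ``country`` the country-level OR; with only ``region`` the
    region-level OR; with neither the overall OR exp(gamma).
    """
    p = posterior.params
    log_or = p["gamma"].copy()
    if country is not None:
        ic = posterior.countries.index(country)
        ir = posterior.country_region_idx[ic]
        log_or = log_or + p["g_region"][:, ir] + p["g_country"][:, ic]
    elif region is not None:
        ir = posterior.regions.index(region)
        log_or = log_or + p["g_region"][:, ir]
    draws = np.exp(log_or)
    out = {k: float(v) for k, v in mcmc.summarize(draws).items()}
    out["draws"] = draws
    return out


def posterior_predictive_check(posterior: TrendPosterior,
                               observations: Sequence[StratumObservation],
                               aux: AuxTables, seed: int = 0,
                               max_draws: int = 1000) -> pd.DataFrame:
    """In-sample posterior predictive check.

    For every stratum, replicate counts ``k_rep ~ Binomial(n, p_draw)`` are
    simulated across draws (including the stratum's fitted survey
    intercept); the report gives each stratum's central 95% predictive
    interval, whether the observed count falls inside, and its standardized
    residual. The attribute ``frac_inside`` on the returned frame summarizes
    calibration.
    """
    post = posterior.subsample(max_draws)
    D = post.n_draws
    rng = np.random.default_rng(seed)
    p = post.params
    s_idx = {s: i for i, s in enumerate(post.surveys)}
    band_idx = {b: i for i, b in enumerate(AGE_BANDS)}
    alpha_full = np.concatenate([np.zeros((D, 1)), p["alpha"]], axis=1)
    c_idx = {c: i for i, c in enumerate(post.countries)}

    rows = []
    for o in observations:
        k, n = integerize_counts(o.p_hat, o.n_eff)
        ic = c_idx[o.country]
        ir = post.country_region_idx[ic]
        x = (o.year - 2010.0) / 10.0
        eta = (p["beta0"] + p["u_region"][:, ir] + p["u_country"][:, ic]
               + p["u_survey"][:, s_idx[o.survey_id]]
               + alpha_full[:, band_idx[o.age_group]]
               + (p["beta_year"] + p["v_region"][:, ir]
                  + p["v_country"][:, ic]) * x)
        if o.recall == "past3y":
            eta = eta + p["beta_recall"]
        gtot = p["gamma"] + p["g_region"][:, ir] + p["g_country"][:, ic]
        if o.hiv == "neg":
            prob = expit(eta)
        elif o.hiv == "pos":
            prob = expit(eta + gtot)
        else:
            pi = aux.prev(o.country, o.year, o.age_group)
            prob = pi * expit(eta + gtot) + (1.0 - pi) * expit(eta)
        k_rep = rng.binomial(n, prob)
        lo, hi = np.percentile(k_rep, [2.5, 97.5])
        mean, sd = k_rep.mean(), max(k_rep.std(), 1e-9)
        rows.append({
            "survey_id": o.survey_id, "country": o.country, "year": o.year,
            "age_group": o.age_group, "recall": o.recall, "hiv": o.hiv,
            "k": k, "n": n, "pred_lo95": lo, "pred_hi95": hi,
            "inside": bool(lo <= k <= hi),
            "std_residual": (k - mean) / sd,
        })
    report = pd.DataFrame(rows)
    report.attrs["frac_inside"] = float(report["inside"].mean())
    return report
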