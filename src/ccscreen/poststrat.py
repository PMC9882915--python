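"""Post-stratification of coverage draws and imputation for countries
without surveys.

Stratum-level coverage draws (country x year x 5-year age band x HIV
serostatus) are pooled into broader aggregates — wider age ranges, combined
serostatus, countries, regions, all of sub-Saharan Africa — with weights
proportional to female population counts split by HIV prevalence:
``pop * prev`` for the HIV-positive stratum and ``pop * (1 - prev)`` for
the HIV-negative stratum, normalized within each (aggregate, year).
Aggregation is a draw-wise convex combination, so credible intervals
propagate coherently.

Countries lacking surveys are imputed from the regional average by drawing
fresh country-level random effects from their posterior hierarchical
distribution, which widens the imputed intervals relative to observed
countries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import mcmc
from .io_core import AGE_BANDS, AuxTables
from .trend_model import CoverageDraws, TrendPosterior, _predict_eta, make_grid
from .synthetic import expit


@dataclass
class StratumWeights:
    """Normalized post-stratification weights for one aggregate.

    ``table`` has columns country, year, age_group, hiv, weight; weights sum
    to 1 within each year (the normalization domain).
    """

    name: str
    table: pd.DataFrame

    def __post_init__(self):
        sums = self.table.groupby("year")["weight"].sum()
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError(
                f"weights for aggregate {self.name!r} do not normalize: {sums}")


def build_weights(aux: AuxTables, name: str, countries: Sequence[str],
                  years: Sequence[float],
                  age_groups: Sequence[str] = AGE_BANDS,
                  hiv: Sequence[str] = ("neg", "pos")) -> StratumWeights:
    """Population x prevalence-share weights, normalized within each year.

    ``hiv`` restricts the serostatus scope (e.g. ``("pos",)`` for a WLHIV
    aggregate). Raises a KeyError naming the missing cell if the auxiliary
    tables do not cover the aggregate.
    """
    rows = []
    for year in years:
        for c in countries:
            for a in age_groups:
                pop = aux.pop_f(c, year, a)
                prev = aux.prev(c, year, a)
                if "pos" in hiv:
                    rows.append((c, year, a, "pos", pop * prev))
                if "neg" in hiv:
                    rows.append((c, year, a, "neg", pop * (1.0 - prev)))
    table = pd.DataFrame(rows, columns=["country", "year", "age_group",
                                        "hiv", "weight"])
    totals = table.groupby("year")["weight"].transform("sum")
    if (totals <= 0).any():
        raise ValueError(f"aggregate {name!r} has zero total weight")
    table["weight"] = table["weight"] / totals
    return StratumWeights(name=name, table=table)


def aggregate_draws(coverage: CoverageDraws, weights: StratumWeights,
                    recall: str = "lifetime") -> tuple[pd.DataFrame, np.ndarray]:
    """Draw-wise weighted aggregate coverage per year.

    Returns (summary frame with columns year/median/lo95/hi95, draws array
    of shape (n_years, D)). Every weighted stratum must be present in the
    coverage grid.
    """
    grid = coverage.grid.reset_index(drop=True)
    sub = grid[grid["recall"] == recall]
    key = ["country", "year", "age_group", "hiv"]
    lookup = {tuple(row): i for i, row in zip(sub.index, sub[key].to_numpy())}
    years = sorted(weights.table["year"].unique())
    out_draws = np.zeros((len(years), coverage.draws.shape[1]))
    for yi, year in enumerate(years):
        wt = weights.table[weights.table["year"] == year]
        for row in wt.itertuples(index=False):
            k = (row.country, row.year, row.age_group, row.hiv)
            if k not in lookup:
                raise KeyError(f"aggregate {weights.name!r}: stratum {k} "
                               "missing from coverage draws")
            out_draws[yi] += row.weight * coverage.draws[lookup[k]]
    s = mcmc.summarize(out_draws, axis=1)
    summary = pd.DataFrame({
        "aggregate": weights.name, "year": years, "median": s["median"],
        "lo95": s["lo95"], "hi95": s["hi95"]})
    return summary, out_draws


def compose_weights(parts: Sequence[StratumWeights], shares: Sequence[float],
                    name: str) -> StratumWeights:
    """Combine sub-aggregate weights with outer shares (e.g. country weights
    within a region): the two-step aggregate equals the direct aggregate
    with composed weights."""
    shares = np.asarray(shares, float)
    if not np.isclose(shares.sum(), 1.0):
        raise ValueError("outer shares must sum to 1")
    tables = []
    for w, s in zip(parts, shares):
        t = w.table.copy()
        t["weight"] = t["weight"] * s
        tables.append(t)
    return StratumWeights(name=name, table=pd.concat(tables, ignore_index=True))


def country_data_tier(observations) -> dict[str, str]:
    """Label each observed country by how much survey data supports it.

    Tiers mirror reporting practice: country-level estimates are surfaced
    by default only for countries with at least two surveys; single-survey
    countries are flagged, and countries absent entirely are imputed.
    """
    surveys: dict[str, set] = {}
    for o in observations:
        surveys.setdefault(o.country, set()).add(o.survey_id)
    return {c: (">=2 surveys" if len(s) >= 2 else "1 survey")
            for c, s in surveys.items()}


@dataclass
class AggregateSpec:
    """Declarative description of one reported aggregate."""

    name: str
    countries: list[str]
    years: list[float]
    age_groups: list[str] = field(default_factory=lambda: list(AGE_BANDS))
    hiv: list[str] = field(default_factory=lambda: ["neg", "pos"])
    recall: str = "lifetime"


def impute_country(posterior: TrendPosterior, region: str, seed: int,
                   years: Sequence[float],
                   age_groups: Sequence[str] = AGE_BANDS,
                   country_label: str = "IMPUTED",
                   max_draws: int = 4000) -> CoverageDraws:
    """Coverage draws for a country without surveys.

    Per posterior draw d, fresh country-level effects are sampled from the
    fitted hierarchy — ``u* ~ N(0, sigma_country_d^2)``, ``v* ~ N(0,
    tau_country_d^2)``, ``g* ~ N(0, omega_country_d^2)`` — and combined with
    the regional prediction, propagating both regional uncertainty and
    between-country heterogeneity. Deterministic given (posterior, seed).
    """
    if region not in posterior.regions:
        raise KeyError(f"region {region!r} not in the fitted posterior")
    post = posterior.subsample(max_draws)
    rng = np.random.default_rng(seed)
    D = post.n_draws
    u_star = post.params["sigma_country"] * rng.standard_normal(D)
    v_star = post.params["tau_country"] * rng.standard_normal(D)
    g_star = post.params["omega_country"] * rng.standard_normal(D)

    grid = make_grid([country_label], years, age_groups)
    etas, gtots = _predict_eta(
        post, grid, u_c=u_star[:, None], v_c=v_star[:, None],
        g_c=g_star[:, None], region_override=region)
    hiv = grid["hiv"].to_numpy()
    draws = np.where((hiv == "pos")[:, None], expit(etas + gtots), expit(etas))
    return CoverageDraws(grid=grid, draws=draws)


def region_prediction(posterior: TrendPosterior, region: str,
                      years: Sequence[float],
                      age_groups: Sequence[str] = AGE_BANDS,
                      max_draws: int = 4000) -> CoverageDraws:
    """Region-level prediction (country effects set to zero): the regional
    average an unobserved country is imputed around."""
    post = posterior.subsample(max_draws)
    D = post.n_draws
    zeros = np.zeros((D, 1))
    grid = make_grid([region], years, age_groups)
    etas, gtots = _predict_eta(post, grid, u_c=zeros, v_c=zeros, g_c=zeros,
                               region_override=region)
    hiv = grid["hiv"].to_numpy()
    draws = np.where((hiv == "pos")[:, None], expit(etas + gtots), expit(etas))
    return CoverageDraws(grid=grid, draws=draws)
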