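"""Synthetic-data generator with known ground truth.

Generates every input the pipeline consumes — a "true world" logit-linear
coverage surface with nested country/region heterogeneity, stratified survey
tabulations (including serostatus-mixed strata and design-effect-deflated
sample sizes), auxiliary population / HIV-prevalence tables, individual
screening histories with distinct first- and re-screening hazards, and
treatment tabulations — so every downstream stage can be tested against a
known truth without any external download.

True coverage on the logit scale is

    logit p = beta0 + u_r + u_c + alpha_age
              + (beta_year + v_r + v_c) * (year - 2010)/10
              + beta_recall * 1[recall = past3y]
              + (gamma + g_r + g_c) * 1[hiv = pos]

with all random effects drawn from zero-mean normals with configured SDs.
The year covariate is centered at 2010 and scaled per decade. Serostatus-
unknown survey strata are generated from the exact prevalence-weighted
mixture of the serostatus-specific probabilities, matching the estimation
model's marginalization assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .io_core import AGE_BANDS, AuxTables, StratumObservation, TreatmentObservation
from .regions import map_country_to_region, normalize_country

WCE_GROUP = "Western/Central/Eastern Africa"
SOUTHERN_GROUP = "Southern Africa"

#: region-group used for the re-screening rate ratio (data scarcity pools
#: Western/Central with Eastern; Southern stands alone)
def rate_ratio_group(country: str) -> str:
    region = map_country_to_region(country)
    return SOUTHERN_GROUP if region == "Southern Africa" else WCE_GROUP


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def logit(p):
    p = np.asarray(p, float)
    return np.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class WorldConfig:
    """Parameters of the true coverage surface and screening-rate process."""

    regions: dict[str, list[str]]
    beta0: float = -1.9924301646902063          # logit(0.12)
    beta_year: float = 0.5                      # per decade, logit scale
    beta_recall: float = -0.7                   # past3y vs lifetime, <= 0
    gamma: float = 0.6931471805599453           # ln 2: HIV log-OR
    alpha: dict[str, float] = field(default_factory=lambda: {
        "25-29": 0.0, "30-34": 0.25, "35-39": 0.40, "40-44": 0.50,
        "45-49": 0.55})
    sigma_survey: float = 0.15
    sigma_country: float = 0.30
    sigma_region: float = 0.30
    tau_country: float = 0.15
    tau_region: float = 0.15
    omega_country: float = 0.20
    omega_region: float = 0.20
    #: women's HIV prevalence per country (held flat over year/age bands)
    prevalence: dict[str, float] = field(default_factory=dict)
    #: female population per 5-year band per country
    population: dict[str, float] = field(default_factory=dict)
    #: re-screening:first-screening rate ratio per region-group
    rate_ratio: dict[str, float] = field(default_factory=lambda: {
        WCE_GROUP: 30.0, SOUTHERN_GROUP: 20.0})
    #: first-screening hazard per year (stationary default)
    r1_base: float = 0.02
    #: multiplicative log-trend in r1 per calendar year (period effect)
    r1_log_trend: float = 0.0

    def __post_init__(self):
        self.regions = {r: [normalize_country(c) for c in cs]
                        for r, cs in self.regions.items()}
        for r, cs in self.regions.items():
            for c in cs:
                if map_country_to_region(c) != r:
                    raise ValueError(
                        f"{c} is in region {map_country_to_region(c)!r}, "
                        f"not {r!r}")
        if self.beta_recall > 0:
            raise ValueError("beta_recall must be <= 0 (past-3-year screeners "
                             "are a subset of lifetime screeners)")
        for name in ("sigma_survey", "sigma_country", "sigma_region",
                     "tau_country", "tau_region", "omega_country",
                     "omega_region"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for g, rr in self.rate_ratio.items():
            if rr <= 0:
                raise ValueError(f"rate ratio for {g} must be > 0")
        if not self.prevalence:
            self.prevalence = {c: 0.10 for cs in self.regions.values() for c in cs}
        if not self.population:
            self.population = {c: 5e5 for cs in self.regions.values() for c in cs}

    @property
    def countries(self) -> list[str]:
        return [c for cs in self.regions.values() for c in cs]

    def r1(self, country: str, year: float, age: float | None = None) -> float:
        """First-screening hazard per year; log-linear period trend."""
        return self.r1_base * np.exp(self.r1_log_trend * (year - 2010.0))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def default_world_config() -> WorldConfig:
    """Default synthetic scale: 3 regions x 6 countries x 2 surveys each.

    Prevalence and population magnitudes are loosely patterned on women's
    HIV prevalence and female population sizes in the chosen countries.
    """
    return WorldConfig(
        regions={
            "Western/Central Africa": ["GHA", "SEN"],
            "Eastern Africa": ["KEN", "TZA"],
            "Southern Africa": ["ZAF", "NAM"],
        },
        prevalence={"GHA": 0.03, "SEN": 0.01, "KEN": 0.07, "TZA": 0.06,
                    "ZAF": 0.25, "NAM": 0.14},
        population={"GHA": 1.0e6, "SEN": 5.5e5, "KEN": 1.6e6, "TZA": 1.8e6,
                    "ZAF": 2.3e6, "NAM": 9.0e4},
    )


@dataclass(frozen=True)
class SurveyDesign:
    """Design of one simulated survey."""

    survey_id: str
    country: str
    year: float
    survey_type: str = "DHS"
    recalls: tuple[str, ...] = ("lifetime", "past3y")
    serostatus_reported: bool = False
    n_nominal: tuple[float, float] = (500.0, 2000.0)  # per-stratum range
    design_effect: float = 1.0


def default_survey_designs(config: WorldConfig) -> list[SurveyDesign]:
    """Two surveys per country: an early DHS-style survey without serostatus
    and a later PHIA-style survey reporting serostatus-split strata."""
    designs = []
    for c in config.countries:
        designs.append(SurveyDesign(f"{c}-DHS-2008", c, 2008.0, "DHS",
                                    serostatus_reported=False))
        designs.append(SurveyDesign(f"{c}-PHIA-2016", c, 2016.0, "PHIA",
                                    serostatus_reported=True))
    return designs


# ---------------------------------------------------------------------------
# True world
# ---------------------------------------------------------------------------

@dataclass
class TrueWorld:
    """A realized world: config plus drawn country/region random effects."""

    config: WorldConfig
    u_region: dict[str, float]
    v_region: dict[str, float]
    g_region: dict[str, float]
    u_country: dict[str, float]
    v_country: dict[str, float]
    g_country: dict[str, float]

    @property
    def countries(self) -> list[str]:
        return self.config.countries

    def region_of(self, country: str) -> str:
        return map_country_to_region(country)

    def linear_predictor(self, country: str, year: float, age_group: str,
                         recall: str) -> float:
        """Logit coverage for the HIV-negative stratum."""
        cfg = self.config
        if country not in self.u_country:
            raise KeyError(f"country {country!r} not on the world's grid")
        if age_group not in cfg.alpha:
            raise KeyError(f"age group {age_group!r} not on the world's grid")
        r = self.region_of(country)
        x = (year - 2010.0) / 10.0
        eta = (cfg.beta0 + self.u_region[r] + self.u_country[country]
               + cfg.alpha[age_group]
               + (cfg.beta_year + self.v_region[r] + self.v_country[country]) * x)
        if recall == "past3y":
            eta += cfg.beta_recall
        elif recall != "lifetime":
            raise KeyError(f"recall {recall!r} not on the world's grid")
        return float(eta)

    def hiv_log_or(self, country: str) -> float:
        r = self.region_of(country)
        return float(self.config.gamma + self.g_region[r] + self.g_country[country])


def make_world(config: WorldConfig, seed: int) -> TrueWorld:
    """Draw all nested random effects; deterministic given (config, seed)."""
    rng = np.random.default_rng(seed)
    regions = list(config.regions)
    countries = config.countries
    draw = lambda sd, labels: {
        lab: float(sd * z) for lab, z in zip(labels, rng.standard_normal(len(labels)))}
    return TrueWorld(
        config=config,
        u_region=draw(config.sigma_region, regions),
        v_region=draw(config.tau_region, regions),
        g_region=draw(config.omega_region, regions),
        u_country=draw(config.sigma_country, countries),
        v_country=draw(config.tau_country, countries),
        g_country=draw(config.omega_country, countries),
    )


def true_coverage(world: TrueWorld, country: str, year: float,
                  age_group: str, hiv: str = "neg",
                  recall: str = "lifetime") -> float:
    """True coverage proportion at one grid point.

    ``hiv="all"`` returns the prevalence-weighted mixture using the world's
    configured prevalence for the country.
    """
    eta = world.linear_predictor(country, year, age_group, recall)
    if hiv == "neg":
        return float(expit(eta))
    if hiv == "pos":
        return float(expit(eta + world.hiv_log_or(country)))
    if hiv == "all":
        pi = world.config.prevalence[country]
        return float(pi * expit(eta + world.hiv_log_or(country))
                     + (1.0 - pi) * expit(eta))
    raise KeyError(f"unknown hiv level {hiv!r}")


# ---------------------------------------------------------------------------
# Survey simulation
# ---------------------------------------------------------------------------

def simulate_surveys(world: TrueWorld, designs: Sequence[SurveyDesign],
                     seed: int) -> list[StratumObservation]:
    """Simulate stratified survey tabulations from the true world.

    Each stratum's effective denominator is the nominal size deflated by the
    design effect; counts are Binomial at the true stratum probability
    (which includes a survey-level intercept drawn from ``sigma_survey``).
    Surveys not reporting serostatus emit ``hiv="all"`` rows whose success
    probability is the exact prevalence-weighted mixture.
    """
    rng = np.random.default_rng(seed)
    cfg = world.config
    out: list[StratumObservation] = []
    for d in designs:
        if d.country not in world.u_country:
            raise KeyError(f"survey {d.survey_id}: country {d.country!r} "
                           "absent from world")
        u_v = float(cfg.sigma_survey * rng.standard_normal())
        for age in AGE_BANDS:
            for recall in d.recalls:
                eta = world.linear_predictor(d.country, d.year, age, recall) + u_v
                p_neg = float(expit(eta))
                p_pos = float(expit(eta + world.hiv_log_or(d.country)))
                if d.serostatus_reported:
                    cells = [("neg", p_neg), ("pos", p_pos)]
                else:
                    pi = cfg.prevalence[d.country]
                    cells = [("all", pi * p_pos + (1.0 - pi) * p_neg)]
                for hiv, p in cells:
                    n_nom = rng.uniform(*d.n_nominal)
                    n_eff = max(1, int(round(n_nom / d.design_effect)))
                    k = int(rng.binomial(n_eff, p))
                    out.append(StratumObservation(
                        survey_id=d.survey_id, country=d.country,
                        survey_type=d.survey_type, year=d.year,
                        age_group=age, recall=recall, hiv=hiv,
                        k_eff=float(k), n_eff=float(n_eff)))
    return out


def simulate_aux_tables(world: TrueWorld, seed: int = 0,
                        years: Iterable[int] = range(2000, 2021),
                        age_bands: Sequence[str] = AGE_BANDS) -> AuxTables:
    """Emit population / prevalence tables on the full grid the pipeline
    queries. Counts and prevalences come straight from the config (the
    emulated UN population and UNAIDS prevalence products are treated as
    known inputs, not as noisy data)."""
    cfg = world.config
    aux = AuxTables()
    # mild age taper so age bands are not exactly exchangeable
    taper = {a: 1.0 - 0.06 * i for i, a in enumerate(age_bands)}
    for c in world.countries:
        for y in years:
            for a in age_bands:
                aux.population[(c, int(y), a)] = cfg.population[c] * taper[a]
                aux.prevalence[(c, int(y), a)] = cfg.prevalence[c]
    return aux


def simulate_treatment(probs: dict[str, float], denominators: dict[str, int],
                       seed: int) -> list[TreatmentObservation]:
    """Country-level treated counts: k ~ Binomial(n_c, p_c)."""
    rng = np.random.default_rng(seed)
    out = []
    for c in probs:
        p, n = probs[c], int(denominators[c])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"treatment probability for {c} outside [0,1]")
        out.append(TreatmentObservation(
            country=normalize_country(c), k_treated=int(rng.binomial(n, p)),
            n_abnormal=n))
    return out


# ---------------------------------------------------------------------------
# Individual screening histories
# ---------------------------------------------------------------------------

@dataclass
class ScreeningHistories:
    """Ragged collection of per-woman screening event times.

    Event times are measured in years since screening eligibility (the
    sexual-debut age floor, ``debut_age``); a woman's decimal age at event
    ``t`` is ``debut_age + t``. Times are strictly increasing per woman.
    """

    times: np.ndarray       # flat event times (years since debut)
    offsets: np.ndarray     # (n_women + 1,), int
    horizon: float
    debut_age: float = 15.0
    hiv: np.ndarray | None = None

    @property
    def n_women(self) -> int:
        return len(self.offsets) - 1

    def events(self, i: int) -> np.ndarray:
        return self.times[self.offsets[i]:self.offsets[i + 1]]

    def event_ages(self, i: int) -> np.ndarray:
        return self.debut_age + self.events(i)

    def n_events_by(self, t: float) -> np.ndarray:
        """Number of events per woman at or before time t."""
        cs = np.concatenate(([0], np.cumsum(self.times <= t)))
        return cs[self.offsets[1:]] - cs[self.offsets[:-1]]

    def last_event_time(self) -> np.ndarray:
        """Per-woman time of the latest event (-inf if never screened)."""
        last = np.full(self.n_women, -np.inf)
        nonempty = self.offsets[1:] > self.offsets[:-1]
        last[nonempty] = self.times[self.offsets[1:][nonempty] - 1]
        return last

    def occupancy(self, cycles: int, cycle_length: float = 1.0,
                  one_advance_per_cycle: bool = True) -> np.ndarray:
        """Never/once/twice+ occupancy at the end of each cycle.

        With ``one_advance_per_cycle`` (default) a woman's state advances at
        most one step per cycle — the same bookkeeping as the life table, so
        the two are directly comparable: the first cycle containing an event
        moves never -> once, and each later cycle containing an event moves
        once -> twice+. Returns an array of shape (cycles + 1, 3) whose row
        ``t`` is the occupancy at time ``t * cycle_length`` (row 0 = start).
        """
        occ = np.zeros((cycles + 1, 3))
        occ[0] = (1.0, 0.0, 0.0)
        n = self.n_women
        state = np.zeros(n, dtype=np.int8)
        prev_counts = np.zeros(n, dtype=int)
        for t in range(1, cycles + 1):
            counts = self.n_events_by(t * cycle_length)
            if one_advance_per_cycle:
                advanced = counts > prev_counts
                state = np.minimum(state + advanced, 2)
            else:
                state = np.minimum(counts, 2)
            prev_counts = counts
            occ[t] = np.bincount(state, minlength=3) / n
        return occ


def simulate_histories(r1: float | Sequence[float], rr: float, n: int,
                       horizon: float, seed: int,
                       debut_age: float = 15.0) -> ScreeningHistories:
    """Simulate individual screening histories.

    Time to first screen is Exponential with hazard ``r1``; inter-screen
    gaps thereafter are Exponential with hazard ``rr * r1``; everything is
    truncated at ``horizon`` years. ``r1`` may be a sequence of per-year
    hazards (piecewise-constant period effect); re-screening then uses
    ``rr`` times the hazard prevailing at calendar time.
    """
    if rr <= 0:
        raise ValueError("rate ratio must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rates = np.atleast_1d(np.asarray(r1, float))
    if (rates < 0).any():
        raise ValueError("first-screening hazard must be >= 0")
    stationary = rates.size == 1

    events: list[np.ndarray] = []
    if stationary:
        base = float(rates[0])
        if base == 0.0:
            times = np.empty(0)
            offsets = np.zeros(n + 1, dtype=int)
            return ScreeningHistories(times, offsets, horizon, debut_age)
        t = rng.exponential(1.0 / base, size=n)
        cols = [np.where(t < horizon, t, np.inf)]
        active = cols[0] < np.inf
        r2 = rr * base
        while active.any():
            nxt = np.full(n, np.inf)
            nxt[active] = cols[-1][active] + rng.exponential(1.0 / r2,
                                                            size=int(active.sum()))
            nxt[nxt >= horizon] = np.inf
            if not np.isfinite(nxt).any():
                break
            cols.append(nxt)
            active = np.isfinite(nxt)
        mat = np.stack(cols, axis=1)            # times increase left to right
        finite = np.isfinite(mat)
        offsets = np.zeros(n + 1, dtype=int)
        offsets[1:] = np.cumsum(finite.sum(axis=1))
        return ScreeningHistories(mat[finite], offsets, float(horizon),
                                  debut_age)
    else:
        # piecewise-constant hazards: sequential inverse-CDF per woman
        n_years = len(rates)
        for i in range(n):
            t, evs, screened = 0.0, [], False
            while t < horizon:
                yr = min(int(t), n_years - 1)
                rate = rates[yr] * (rr if screened else 1.0)
                if rate <= 0:
                    t = float(yr + 1)
                    if t >= n_years and not screened:
                        t = horizon
                    continue
                gap = rng.exponential(1.0 / rate)
                boundary = min(float(yr + 1), horizon)
                if t + gap < boundary:
                    t = t + gap
                    evs.append(t)
                    screened = True
                else:
                    t = boundary
            events.append(np.asarray(evs))

    offsets = np.zeros(n + 1, dtype=int)
    offsets[1:] = np.cumsum([len(e) for e in events])
    times = np.concatenate(events) if events else np.empty(0)
    return ScreeningHistories(times, offsets, float(horizon), debut_age)


def cross_section_strata(r1: float | Sequence[float], rr: float,
                         ages: Sequence[int], n_per_age: int, seed: int,
                         survey_id: str, country: str, year: float,
                         survey_type: str = "OTHER",
                         debut_age: float = 15.0) -> list[StratumObservation]:
    """Tabulate a cross-sectional survey from simulated histories.

    For each single-year age ``a``, simulates ``n_per_age`` women with
    ``a - debut_age`` years of exposure and emits a lifetime row (ever
    screened) and a past-year row (any screen in the last year).
    """
    rng = np.random.default_rng(seed)
    out = []
    for a in ages:
        exposure = float(a) - debut_age
        if exposure <= 0:
            raise ValueError(f"age {a} at or below debut age {debut_age}")
        h = simulate_histories(r1, rr, n_per_age, exposure,
                               seed=int(rng.integers(2**31 - 1)),
                               debut_age=debut_age)
        ever = int((h.n_events_by(exposure) > 0).sum())
        past1y = int((h.last_event_time() > exposure - 1.0).sum())
        for recall, k in (("lifetime", ever), ("past1y", past1y)):
            out.append(StratumObservation(
                survey_id=survey_id, country=country, survey_type=survey_type,
                year=year, age_group=str(int(a)), recall=recall, hiv="all",
                k_eff=float(k), n_eff=float(n_per_age)))
    return out
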