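"""Tabular I/O, validation, and effective-sample-size computation.

Survey tabulations arrive as one row per stratum: a survey x country x
5-year age group x recall period x HIV-serostatus cell with an *effective*
screened count and denominator, i.e. nominal counts already deflated by the
survey design effect. When only a weighted proportion with a survey-adjusted
confidence interval is available, :func:`effective_sample_size` inverts the
normal approximation to recover the effective denominator.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import map_country_to_region, normalize_country

AGE_BANDS = ("25-29", "30-34", "35-39", "40-44", "45-49")
RECALLS = ("lifetime", "past3y", "past1y")
HIV_LEVELS = ("pos", "neg", "all")
SURVEY_TYPES = ("DHS", "PHIA", "STEPS", "SAGE", "WHS", "KAIS", "SABSSM", "OTHER")

STRATA_COLUMNS = [
    "survey_id", "country", "region", "survey_type", "year",
    "age_group", "recall", "hiv", "k_eff", "n_eff",
]


class ValidationError(ValueError):
    """Input table violates an invariant; message lists offending rows."""


@dataclass(frozen=True)
class StratumObservation:
    """One survey stratum with effective binomial counts.

    ``age_group`` is either a 5-year band label (``"25-29"`` ... ``"45-49"``)
    or a single-year label (``"18"`` ... ``"49"``) for the rate-ratio inputs.
    ``hiv="all"`` marks a serostatus-mixed stratum whose likelihood is the
    prevalence-weighted mixture of the serostatus-specific probabilities.
    """

    survey_id: str
    country: str
    survey_type: str
    year: float
    age_group: str
    recall: str
    hiv: str
    k_eff: float
    n_eff: float
    region: str = ""

    def __post_init__(self):
        if not self.region:
            object.__setattr__(self, "region", map_country_to_region(self.country))

    @property
    def p_hat(self) -> float:
        return self.k_eff / self.n_eff

    def validate(self) -> list[str]:
        """Return a list of human-readable invariant violations (empty if ok)."""
        problems = []
        if self.survey_type not in SURVEY_TYPES:
            problems.append(f"unknown survey_type {self.survey_type!r}")
        if not (2000.0 <= self.year <= 2020.0):
            problems.append(f"year {self.year} outside [2000, 2020]")
        if self.recall not in RECALLS:
            problems.append(f"unknown recall {self.recall!r}")
        if self.hiv not in HIV_LEVELS:
            problems.append(f"unknown hiv level {self.hiv!r}")
        if not (self.n_eff > 0):
            problems.append(f"n_eff {self.n_eff} must be positive")
        elif not (0 <= self.k_eff <= self.n_eff):
            problems.append(f"k_eff {self.k_eff} outside [0, n_eff={self.n_eff}]")
        if not _valid_age_label(self.age_group):
            problems.append(f"unrecognized age_group {self.age_group!r}")
        return problems


def _valid_age_label(label: str) -> bool:
    if label in AGE_BANDS:
        return True
    try:
        age = int(label)
    except ValueError:
        return False
    return 15 <= age <= 49


@dataclass
class AuxTables:
    """Auxiliary population and HIV-prevalence tables.

    ``population`` maps ``(country, year, age_group)`` to female population
    counts (persons); ``prevalence`` maps the same key to HIV prevalence
    among women (proportion in [0, 1]). Survey midpoints carry decimal
    years; lookups round to the nearest tabulated integer year.
    """

    population: dict[tuple[str, int, str], float] = field(default_factory=dict)
    prevalence: dict[tuple[str, int, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(country: str, year: float, age_group: str) -> tuple[str, int, str]:
        return (normalize_country(country), int(round(year)), age_group)

    def pop_f(self, country: str, year: float, age_group: str) -> float:
        key = self._key(country, year, age_group)
        if key not in self.population:
            raise KeyError(f"population table has no entry for {key}")
        return self.population[key]

    def prev(self, country: str, year: float, age_group: str) -> float:
        key = self._key(country, year, age_group)
        if key not in self.prevalence:
            raise KeyError(f"prevalence table has no entry for {key}")
        return self.prevalence[key]

    def has_prev(self, country: str, year: float, age_group: str) -> bool:
        return self._key(country, year, age_group) in self.prevalence

    # -- CSV round trips -------------------------------------------------
    def write(self, pop_path: str | Path, prev_path: str | Path) -> None:
        pop = pd.DataFrame(
            [(c, y, a, v) for (c, y, a), v in sorted(self.population.items())],
            columns=["country", "year", "age_group", "pop_f"],
        )
        prev = pd.DataFrame(
            [(c, y, a, v) for (c, y, a), v in sorted(self.prevalence.items())],
            columns=["country", "year", "age_group", "prev"],
        )
        pop.to_csv(pop_path, index=False, float_format="%.17g")
        prev.to_csv(prev_path, index=False, float_format="%.17g")

    @classmethod
    def read(cls, pop_path: str | Path, prev_path: str | Path) -> "AuxTables":
        pop = pd.read_csv(pop_path)
        prev = pd.read_csv(prev_path)
        aux = cls()
        for row in pop.itertuples(index=False):
            if row.pop_f < 0:
                raise ValidationError(f"negative population count for {row}")
            aux.population[(normalize_country(row.country), int(row.year),
                            str(row.age_group))] = float(row.pop_f)
        for row in prev.itertuples(index=False):
            if not 0.0 <= row.prev <= 1.0:
                raise ValidationError(f"prevalence outside [0,1] for {row}")
            aux.prevalence[(normalize_country(row.country), int(row.year),
                            str(row.age_group))] = float(row.prev)
        return aux


@dataclass(frozen=True)
class TreatmentObservation:
    """Country-level pre-cancer treatment counts: treated / abnormal-screen."""

    country: str
    k_treated: int
    n_abnormal: int

    def validate(self) -> list[str]:
        problems = []
        if self.n_abnormal < 1:
            problems.append(f"n_abnormal {self.n_abnormal} must be >= 1")
        if not 0 <= self.k_treated <= self.n_abnormal:
            problems.append(
                f"k_treated {self.k_treated} outside [0, n_abnormal={self.n_abnormal}]")
        return problems


# ---------------------------------------------------------------------------
# Effective sample size
# ---------------------------------------------------------------------------

def effective_sample_size(
    p_hat: float,
    se: float | None = None,
    ci: tuple[float, float, float] | None = None,
) -> float:
    """Effective sample size implied by a design-adjusted proportion.

    Either the standard error ``se`` of the weighted proportion or a
    symmetric normal-approximation confidence interval
    ``ci = (lower, upper, level)`` must be supplied; with a CI,
    ``se = (upper - lower) / (2 z)`` with ``z`` the exact standard-normal
    quantile for ``level``. Returns ``n_eff = p_hat (1 - p_hat) / se**2``.
    """
    if not 0.0 < p_hat < 1.0:
        raise ValueError(
            "p_hat must lie strictly in (0, 1); for boundary proportions apply "
            "the continuity adjustment (k + 0.5)/(n + 1) first "
            "(see continuity_adjusted_proportion)")
    if (se is None) == (ci is None):
        raise ValueError("provide exactly one of se or ci")
    if ci is not None:
        lower, upper, level = ci
        if not (0.0 < level < 1.0):
            raise ValueError(f"CI level {level} must be in (0, 1)")
        if upper <= lower:
            raise ValueError(f"inverted confidence interval ({lower}, {upper})")
        if not (lower <= p_hat <= upper):
            raise ValueError(f"CI ({lower}, {upper}) does not bracket p_hat={p_hat}")
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = (upper - lower) / (2.0 * z)
    if not se > 0:
        raise ValueError(f"se must be positive, got {se}")
    return p_hat * (1.0 - p_hat) / se**2


def continuity_adjusted_proportion(k: float, n: float) -> float:
    """Continuity adjustment (k + 0.5)/(n + 1) for boundary proportions."""
    if n <= 0:
        raise ValueError("n must be positive")
    return (k + 0.5) / (n + 1.0)


def integerize_counts(p_hat: float, n_eff: float) -> tuple[int, int]:
    """Round effective counts to an exact binomial pair (k, n).

    ``n`` is the nearest integer to ``n_eff`` (at least 1) and ``k`` the
    nearest integer to ``p_hat * n`` clamped to [0, n]; the observed
    proportion and design-adjusted information are preserved to rounding.
    """
    n = max(1, int(round(n_eff)))
    k = int(round(p_hat * n))
    return min(max(k, 0), n), n


# ---------------------------------------------------------------------------
# Strata CSV round trip
# ---------------------------------------------------------------------------

def write_table(records: Iterable[StratumObservation], path: str | Path) -> None:
    """Write strata to CSV; counts serialized with 12 significant digits."""
    rows = [
        {
            "survey_id": r.survey_id, "country": r.country, "region": r.region,
            "survey_type": r.survey_type, "year": r.year,
            "age_group": r.age_group, "recall": r.recall, "hiv": r.hiv,
            "k_eff": r.k_eff, "n_eff": r.n_eff,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=STRATA_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def load_strata(
    path: str | Path, aux: AuxTables | None = None
) -> list[StratumObservation]:
    """Load and validate a strata CSV.

    Every row is checked against the type invariants; if ``aux`` is given,
    serostatus-mixed rows (``hiv="all"``) must have a resolvable prevalence
    entry, and no survey may contribute both split (pos/neg) and mixed rows
    for the same (age, recall) cell. All violations are collected and raised
    together with their row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in STRATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"strata file {path} missing columns: {missing}")

    records: list[StratumObservation] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            k_eff, n_eff = float(row.k_eff), float(row.n_eff)
        except (TypeError, ValueError):
            problems.append(f"line {i}: non-numeric counts ({row.k_eff!r}, {row.n_eff!r})")
            continue
        try:
            rec = StratumObservation(
                survey_id=str(row.survey_id),
                country=normalize_country(str(row.country)),
                survey_type=str(row.survey_type), year=float(row.year),
                age_group=str(row.age_group), recall=str(row.recall),
                hiv=str(row.hiv), k_eff=k_eff, n_eff=n_eff,
            )
        except KeyError as exc:
            problems.append(f"line {i}: {exc.args[0]}")
            continue
        for msg in rec.validate():
            problems.append(f"line {i}: {msg}")
        if aux is not None and rec.hiv == "all" and not aux.has_prev(
                rec.country, rec.year, rec.age_group):
            problems.append(
                f"line {i}: hiv='all' stratum but prevalence table has no entry "
                f"for {AuxTables._key(rec.country, rec.year, rec.age_group)}")
        records.append(rec)

    if aux is not None:
        _check_no_double_counting(records, problems)
    if problems:
        raise ValidationError(
            f"strata file {path} failed validation:\n  " + "\n  ".join(problems))
    return records


def _check_no_double_counting(records: Sequence[StratumObservation],
                              problems: list[str]) -> None:
    """A survey contributes either split (pos/neg) or mixed rows per cell."""
    seen: dict[tuple[str, str, str], set[str]] = {}
    for r in records:
        seen.setdefault((r.survey_id, r.age_group, r.recall), set()).add(r.hiv)
    for (survey, age, recall), levels in seen.items():
        if "all" in levels and levels & {"pos", "neg"}:
            problems.append(
                f"survey {survey} cell (age={age}, recall={recall}) mixes "
                f"hiv='all' with serostatus-split rows (double counting)")


# ---------------------------------------------------------------------------
# Treatment CSV
# ---------------------------------------------------------------------------

def load_treatment(path: str | Path) -> list[TreatmentObservation]:
    df = pd.read_csv(path)
    missing = [c for c in ("country", "k_treated", "n_abnormal") if c not in df.columns]
    if missing:
        raise ValidationError(f"treatment file {path} missing columns: {missing}")
    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = TreatmentObservation(
            country=normalize_country(str(row.country)),
            k_treated=int(row.k_treated), n_abnormal=int(row.n_abnormal))
        for msg in rec.validate():
            problems.append(f"line {i}: {msg}")
        records.append(rec)
    if problems:
        raise ValidationError(
            f"treatment file {path} failed validation:\n  " + "\n  ".join(problems))
    return records


def write_treatment(records: Iterable[TreatmentObservation], path: str | Path) -> None:
    pd.DataFrame(
        [(r.country, r.k_treated, r.n_abnormal) for r in records],
        columns=["country", "k_treated", "n_abnormal"],
    ).to_csv(path, index=False)
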