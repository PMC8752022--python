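"""Synthetic mental-health care ecosystems.

One *catchment area* is the decision-making unit of the analysis: a
geographic territory served by a community mental-health centre, described by
its adult population, outpatient utilization (frequentation), inpatient
activity (days of stay, discharges, readmissions), outpatient service
availability, and workforce rates.

The generator emulates the dependency structure the downstream analysis
assumes: workforce headcount grows exponentially with population, outpatient
frequentation grows exponentially with a population x workforce composite,
inpatient days of stay follow the same composite, discharges follow a power
law of frequentation x workforce, and readmissions are an overdispersed count
with no systematic link to outpatient provision. Multiplicative lognormal
noise keeps every generated quantity positive and matches the log scale on
which the structural fits are performed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scenarios import ScenarioSet, default_scenarios

__all__ = [
    "AreaRecord",
    "EcosystemTable",
    "GeneratorParams",
    "GIPUZKOA_AREA_NAMES",
    "COLUMNS",
    "generate_ecosystem",
    "table_summary",
    "default_scenarios",
]

#: Canonical column order of the area table (CSV header).
COLUMNS: tuple[str, ...] = (
    "area_id",
    "population_adults",
    "frequentation_visits",
    "stay_days",
    "discharges",
    "readmissions",
    "availability_per_100k",
    "psychiatrists_per_100k",
    "psychologists_per_100k",
    "nurses_per_100k",
    "total_professionals_per_100k",
    "total_professionals_fte",
)

#: The 13 catchment areas of the Gipuzkoa mental-health ecosystem.
GIPUZKOA_AREA_NAMES: tuple[str, ...] = (
    "Alto Deba-Arrasate",
    "Amara",
    "Andoain",
    "Azpeitia",
    "Beasain",
    "Eguia",
    "Eibar",
    "Irun",
    "Ondarreta",
    "Renteria",
    "Tolosa",
    "Zarautz",
    "Zumarraga",
)

_RELTOL = 1e-9


@dataclass
class AreaRecord:
    """Care-provision variables for one catchment area.

    Rates are full-time-equivalent (FTE) professionals per 100,000 adults;
    ``total_professionals_fte`` is the absolute per-area headcount.
    """

    area_id: str
    population_adults: float
    frequentation_visits: float
    stay_days: float
    discharges: float
    readmissions: float
    availability_per_100k: float
    psychiatrists_per_100k: float
    psychologists_per_100k: float
    nurses_per_100k: float
    total_professionals_per_100k: float
    total_professionals_fte: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.population_adults <= 0:
            raise ValueError(f"area {self.area_id!r}: population_adults must be > 0")
        for name in COLUMNS[1:]:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"area {self.area_id!r}: {name} must be finite and >= 0")
        if self.readmissions > self.discharges * (1 + _RELTOL):
            raise ValueError(
                f"area {self.area_id!r}: readmissions ({self.readmissions}) exceed "
                f"discharges ({self.discharges})"
            )
        implied = self.total_professionals_per_100k * self.population_adults / 1e5
        if self.total_professionals_fte > 0 or implied > 0:
            denom = max(abs(self.total_professionals_fte), abs(implied), 1e-300)
            if abs(self.total_professionals_fte - implied) / denom > 1e-6:
                raise ValueError(
                    f"area {self.area_id!r}: total_professionals_fte "
                    f"({self.total_professionals_fte}) inconsistent with rate x population "
                    f"({implied})"
                )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EcosystemTable:
    """Ordered collection of catchment-area records (one DEA instance source)."""

    areas: list[AreaRecord]
    label: str = "pre"

    def __post_init__(self) -> None:
        if len(self.areas) < 2:
            raise ValueError("an ecosystem needs at least 2 areas (DEA comparators)")
        ids = [a.area_id for a in self.areas]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate area_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.areas)

    @property
    def area_ids(self) -> list[str]:
        return [a.area_id for a in self.areas]

    def area(self, area_id: str) -> AreaRecord:
        for a in self.areas:
            if a.area_id == area_id:
                return a
        raise KeyError(f"unknown area_id {area_id!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([a.as_dict() for a in self.areas], columns=list(COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "pre") -> "EcosystemTable":
        missing = set(COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        records = [
            AreaRecord(**{c: (str(row[c]) if c == "area_id" else float(row[c])) for c in COLUMNS})
            for _, row in frame.iterrows()
        ]
        return cls(records, label=label)

    def replace_values(self, values: pd.DataFrame, label: str | None = None) -> "EcosystemTable":
        """Return a new table with numeric columns taken from ``values``.

        ``values`` is indexed by area_id with a subset of numeric columns;
        unlisted columns keep their current values. Cross-field count
        invariants are re-enforced by clipping readmissions at discharges.
        """
        frame = self.to_frame().set_index("area_id")
        for col in values.columns:
            frame[col] = values[col]
        frame["readmissions"] = np.minimum(frame["readmissions"], frame["discharges"])
        frame = frame.reset_index()
        return EcosystemTable.from_frame(frame, label=label or self.label)


# --- generator -----------------------------------------------------------

#: Proportions of the total workforce rate by profession (share of the
#: printed per-100k averages: 5.93, 2.11 and 3.93 of a 13.89 total).
_PROFESSION_SHARES = {
    "psychiatrists_per_100k": 5.93 / 13.89,
    "psychologists_per_100k": 2.11 / 13.89,
    "nurses_per_100k": 3.93 / 13.89,
}


@dataclass
class GeneratorParams:
    """Configuration of the synthetic ecosystem generator.

    Structural coefficients default to the fitted values of the reference
    ecosystem (13 catchment areas of Gipuzkoa): an exponential
    population->workforce law, an exponential composite->frequentation law,
    an exponential composite->stay law and a power-law
    (frequentation x workforce)->discharges relationship. ``noise_sigma`` is
    the standard deviation of multiplicative lognormal noise applied to every
    modelled variable on the log scale.
    """

    n_areas: int = 13
    population_range: tuple[float, float] = (21_593, 78_400)
    availability_range: tuple[float, float] = (1.25, 4.53)
    # workforce = alpha * exp(beta * population/1000)
    alpha_professionals: float = 2.381
    beta_professionals: float = 0.0196
    # frequentation (thousands of visits) = alpha * exp(beta * composite)
    alpha_frequentation: float = 5.7767
    beta_frequentation: float = 0.0196
    # stay (days) = alpha * exp(beta * composite)
    alpha_stay: float = 433.39
    beta_stay: float = 0.0204
    # discharges = alpha * (frequentation_visits * workforce / 1000) ** beta
    alpha_discharges: float = 5.372
    beta_discharges: float = 0.5697
    #: composite regressor = (population / composite_pop_divisor) * workforce FTE
    composite_pop_divisor: float = 10_000.0
    noise_sigma: float = 0.12
    readmission_rate: float = 0.083
    readmission_dispersion: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("population_range", "availability_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
        if self.population_range[0] <= 0:
            raise ValueError("population_range: lower bound must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_areas < 2:
            raise ValueError("n_areas must be >= 2")
        if self.readmission_rate < 0:
            raise ValueError("readmission_rate must be >= 0")

    # -- structural formulas (exact, noise-free) --
    def professionals_formula(self, population: np.ndarray) -> np.ndarray:
        return self.alpha_professionals * np.exp(self.beta_professionals * population / 1000.0)

    def composite(self, population: np.ndarray, workforce: np.ndarray) -> np.ndarray:
        return population / self.composite_pop_divisor * workforce

    def frequentation_formula(self, population: np.ndarray, workforce: np.ndarray) -> np.ndarray:
        """Annual outpatient visits (raw count, not thousands)."""
        z = self.composite(population, workforce)
        return 1000.0 * self.alpha_frequentation * np.exp(self.beta_frequentation * z)

    def stay_formula(self, population: np.ndarray, workforce: np.ndarray) -> np.ndarray:
        z = self.composite(population, workforce)
        return self.alpha_stay * np.exp(self.beta_stay * z)

    def discharges_formula(self, frequentation: np.ndarray, workforce: np.ndarray) -> np.ndarray:
        return self.alpha_discharges * (frequentation * workforce / 1000.0) ** self.beta_discharges

    # -- (de)serialization --
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorParams":
        raw = json.loads(Path(path).read_text())
        for key in ("population_range", "availability_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def generate_ecosystem(params: GeneratorParams, label: str = "pre") -> EcosystemTable:
    """Draw a synthetic ecosystem table, reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_areas

    lo, hi = params.population_range
    population = rng.integers(int(lo), int(hi) + 1, size=n).astype(float)

    def noise() -> np.ndarray:
        if params.noise_sigma == 0:
            return np.ones(n)
        return np.exp(rng.normal(0.0, params.noise_sigma, size=n))

    workforce = params.professionals_formula(population) * noise()
    frequentation = params.frequentation_formula(population, workforce) * noise()
    stay = params.stay_formula(population, workforce) * noise()
    discharges = params.discharges_formula(frequentation, workforce) * noise()

    availability = rng.uniform(*params.availability_range, size=n)

    mu = params.readmission_rate * discharges
    k = params.readmission_dispersion
    if params.readmission_rate == 0:
        readmissions = np.zeros(n)
    else:
        readmissions = rng.negative_binomial(k, k / (k + mu), size=n).astype(float)
    readmissions = np.minimum(readmissions, np.floor(discharges))

    total_rate = workforce * 1e5 / population
    if n == 13:
        ids = list(GIPUZKOA_AREA_NAMES)
    else:
        ids = [f"area_{i + 1:02d}" for i in range(n)]

    records = []
    for i in range(n):
        records.append(
            AreaRecord(
                area_id=ids[i],
                population_adults=population[i],
                frequentation_visits=frequentation[i],
                stay_days=stay[i],
                discharges=discharges[i],
                readmissions=readmissions[i],
                availability_per_100k=availability[i],
                psychiatrists_per_100k=total_rate[i] * _PROFESSION_SHARES["psychiatrists_per_100k"],
                psychologists_per_100k=total_rate[i] * _PROFESSION_SHARES["psychologists_per_100k"],
                nurses_per_100k=total_rate[i] * _PROFESSION_SHARES["nurses_per_100k"],
                total_professionals_per_100k=total_rate[i],
                total_professionals_fte=workforce[i],
            )
        )
    return EcosystemTable(records, label=label)


def table_summary(table: EcosystemTable) -> pd.DataFrame:
    """Per-variable mean, sd (n-1 denominator), cv%, min and max.

    ``cv_pct`` is NaN (undefined-cv flag) when the variable mean is zero.
    """
    frame = table.to_frame().drop(columns="area_id")
    mean = frame.mean()
    sd = frame.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    cv[mean == 0] = np.nan
    out = pd.DataFrame(
        {"mean": mean, "sd": sd, "cv_pct": cv, "min": frame.min(), "max": frame.max()}
    )
    out.index.name = "variable"
    return out
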