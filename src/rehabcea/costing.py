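"""Micro-costing of the course and per-patient cost aggregation.

The intervention is costed bottom-up: each staff role's formal hours are
multiplied by a load factor (to cover non-productive paid time) and by the
role's hourly wage; the expert patient's (lay educator's) hours are valued
unloaded at a flat pensioner net wage; a hospital overhead rate is applied
to the sum of the role subtotals; and the per-course total is divided by
the average number of patients per course.

Patient-level costs over follow-up are then assembled per category —
intervention, primary care, prescribed medicine, secondary care,
productivity loss, informal (patient) time, patient transport — and summed
under either a societal or a healthcare perspective.

Full precision is kept internally; amounts are rounded to whole DKK only at
reported lines (half-up, matching the printed course-cost table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .catalogue import CatalogueError, CostCatalogue, CourseSpec, SalaryTable, lookup_salary

__all__ = [
    "PERSPECTIVES",
    "CATEGORY_COLUMNS",
    "HEALTHCARE_CATEGORIES",
    "SOCIETAL_EXTRA_CATEGORIES",
    "PENSION_AGE",
    "WORK_HOURS_PER_WEEK",
    "SESSION_HOURS",
    "INTERVIEW_HOURS",
    "CourseCostBreakdown",
    "Transport",
    "round_dkk",
    "apply_load",
    "course_cost",
    "informal_time_cost",
    "transport_cost",
    "productivity_loss_cost",
    "adjust_price_year",
    "cost_components",
    "aggregate",
    "total_costs",
]

PERSPECTIVES = ("societal", "healthcare")
PENSION_AGE = 67          # productivity losses are counted below this age
WORK_HOURS_PER_WEEK = 37  # standard Danish full-time week
SESSION_HOURS = 1.5       # planned duration of one training/education session
INTERVIEW_HOURS = 1.0     # planned duration of one clarifying interview

# per-category cost columns produced by cost_components()
CATEGORY_COLUMNS = (
    "intervention",
    "intervention_healthcare",
    "primary_care",
    "prescribed_medicine",
    "secondary_care",
    "secondary_care_post_followup",
    "productivity_loss",
    "informal_time",
    "patient_transport",
)
HEALTHCARE_CATEGORIES = ("primary_care", "prescribed_medicine", "secondary_care")
SOCIETAL_EXTRA_CATEGORIES = ("productivity_loss", "informal_time", "patient_transport")

KNOWN_EXCLUSIONS = ("patient_time", "post_followup_admissions")


def round_dkk(amount) -> int | np.ndarray:
    """Round to whole DKK, half away from zero (reported lines only)."""
    if np.isscalar(amount):
        return int(math.floor(amount + 0.5)) if amount >= 0 else -int(math.floor(-amount + 0.5))
    amount = np.asarray(amount, dtype=float)
    return np.where(amount >= 0, np.floor(amount + 0.5), -np.floor(-amount + 0.5)).astype(int)


def apply_load(formal_hours: float, load_factor: float) -> float:
    """Loaded (paid) hours: formal hours scaled up for non-productive time.

    The excess ``(load_factor - 1) * formal_hours`` is the "load for
    unproductive time" line of the course-cost breakdown.
    """
    if formal_hours < 0:
        raise ValueError(f"formal_hours must be >= 0, got {formal_hours}")
    if load_factor < 1:
        raise ValueError(f"load_factor must be >= 1, got {load_factor}")
    return formal_hours * load_factor


@dataclass(frozen=True)
class CourseCostBreakdown:
    """Whole-DKK course-cost table for one arm, plus perspective shares.

    ``informal_per_course`` is the expert patient's time cost (a volunteer's
    informal time); everything else — staff time, hospital-paid expert
    transport, overhead — is formal healthcare spending.
    """

    arm: str
    patients_per_course: int
    nurse_formal_h: float
    nurse_loaded_h: float
    nurse_total: int
    physio_formal_h: float
    physio_loaded_h: float
    physio_total: int
    expert_time_h: float
    expert_time_cost: int
    expert_transport_cost: int
    expert_total: int
    overhead: int
    total_per_course: int
    cost_per_patient: int

    @property
    def informal_per_course(self) -> int:
        return self.expert_time_cost

    @property
    def healthcare_per_course(self) -> int:
        return self.total_per_course - self.expert_time_cost

    @property
    def cost_per_patient_healthcare(self) -> float:
        return self.healthcare_per_course / self.patients_per_course

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "arm", "patients_per_course", "nurse_formal_h", "nurse_loaded_h", "nurse_total",
            "physio_formal_h", "physio_loaded_h", "physio_total", "expert_time_h",
            "expert_time_cost", "expert_transport_cost", "expert_total", "overhead",
            "total_per_course", "cost_per_patient")}


def course_cost(spec: CourseSpec, catalogue: CostCatalogue) -> CourseCostBreakdown:
    """Micro-cost one course: loaded staff hours x wages + expert patient + overhead."""
    load = catalogue.load_factor
    nurse_h = spec.nurse.total
    physio_h = spec.physiotherapist.total
    nurse_loaded = apply_load(nurse_h, load)
    physio_loaded = apply_load(physio_h, load)
    nurse_total = nurse_loaded * catalogue["nurse_hourly"]
    physio_total = physio_loaded * catalogue["physiotherapist_hourly"]

    expert_h = spec.expert.total + spec.expert_transport_time_h  # unloaded volunteer hours
    expert_time_cost = expert_h * catalogue["expert_patient_hourly"]
    expert_total = expert_time_cost + spec.expert_transport_cost_total

    overhead = catalogue.overhead_rate * (nurse_total + physio_total + expert_total)
    total = nurse_total + physio_total + expert_total + round_dkk(overhead)
    return CourseCostBreakdown(
        arm=spec.arm,
        patients_per_course=spec.patients_per_course,
        nurse_formal_h=nurse_h,
        nurse_loaded_h=nurse_loaded,
        nurse_total=round_dkk(nurse_total),
        physio_formal_h=physio_h,
        physio_loaded_h=physio_loaded,
        physio_total=round_dkk(physio_total),
        expert_time_h=expert_h,
        expert_time_cost=round_dkk(expert_time_cost),
        expert_transport_cost=round_dkk(spec.expert_transport_cost_total),
        expert_total=round_dkk(expert_total),
        overhead=round_dkk(overhead),
        total_per_course=round_dkk(total),
        cost_per_patient=round_dkk(total / spec.patients_per_course),
    )


def informal_time_cost(hours: float, gender: str, age: float, time_type: str,
                       table: SalaryTable) -> float:
    """Opportunity cost of a person's time: hours x age/gender-matched wage."""
    if hours < 0:
        raise ValueError(f"hours must be >= 0, got {hours}")
    return hours * lookup_salary(table, gender, age, time_type)


class Transport(NamedTuple):
    cost: float     # DKK
    time_h: float   # accompanying travel time, hours


def transport_cost(n_contacts: float, km_per_way: float, tariff: float,
                   minutes_per_way: float = 20.0) -> Transport:
    """Round-trip transport cost and time for a number of attended contacts."""
    if min(n_contacts, km_per_way, tariff, minutes_per_way) < 0:
        raise ValueError("transport inputs must be >= 0")
    ways = 2.0 * n_contacts
    return Transport(cost=ways * km_per_way * tariff, time_h=ways * minutes_per_way / 60.0)


def productivity_loss_cost(weeks_by_type: Mapping[str, float] | float, gender: str,
                           age: float, table: SalaryTable,
                           pension_age: float = PENSION_AGE,
                           hours_per_week: float = WORK_HOURS_PER_WEEK) -> float:
    """Value weeks of inability to work at the gross weekly wage.

    Zero for anyone at or above the pension age at the end of follow-up:
    pensioners forgo no production.
    """
    weeks = sum(weeks_by_type.values()) if isinstance(weeks_by_type, Mapping) else float(weeks_by_type)
    if weeks < 0:
        raise ValueError(f"weeks must be >= 0, got {weeks}")
    if age >= pension_age:
        return 0.0
    return weeks * hours_per_week * lookup_salary(table, gender, age, "productive")


def adjust_price_year(amount: float, from_year: int, cpi_index: Mapping[int, float],
                      target_year: int = 2013) -> float:
    """Inflate an amount to the target price year using a CPI index."""
    for year in (from_year, target_year):
        if year not in cpi_index:
            raise KeyError(f"year {year} not in CPI index (have {sorted(cpi_index)})")
    return amount * cpi_index[target_year] / cpi_index[from_year]


# ---------------------------------------------------------------------------
# Patient-level aggregation

_PRIMARY_COLS = ("cost_general_practice", "cost_specialist", "cost_physiotherapist",
                 "cost_dentist", "cost_primary_other")
_WEEK_COLS = ("weeks_reschooling", "weeks_disability", "weeks_sick")


def cost_components(records: pd.DataFrame, catalogue: CostCatalogue, salaries: SalaryTable,
                    courses: Mapping[str, CourseCostBreakdown],
                    pension_age: float = PENSION_AGE) -> pd.DataFrame:
    """Per-patient cost components (DKK, full precision), one column per category.

    ``records`` is the patient-level trial table (see the column dictionary in
    the package docs); ``courses`` maps arm label -> costed course breakdown.
    Registry-style categories (primary care, medicine, secondary care) are
    pre-tariffed amounts in the input; intervention, informal time, transport
    and productivity loss are derived from attendance, wages and tariffs.
    """
    n = len(records)
    arm = records["arm"].astype(str)
    for label in arm.unique():
        if label not in courses:
            raise KeyError(f"no course breakdown for arm {label!r}")

    out = pd.DataFrame(index=records.index)
    out["intervention"] = arm.map({a: c.cost_per_patient for a, c in courses.items()}).astype(float)
    out["intervention_healthcare"] = arm.map(
        {a: c.cost_per_patient_healthcare for a, c in courses.items()}).astype(float)
    out["primary_care"] = records[list(_PRIMARY_COLS)].sum(axis=1).astype(float)
    out["prescribed_medicine"] = records["cost_medicine"].astype(float)
    out["secondary_care"] = (records["cost_outpatient"] + records["cost_admissions"]).astype(float)
    out["secondary_care_post_followup"] = records.get(
        "cost_admissions_post_followup", pd.Series(0.0, index=records.index)).astype(float)

    contacts = (records["training_attended"] + records["education_attended"]
                + records.get("interviews_attended", pd.Series(0, index=records.index)))
    km_per_way = catalogue["km_per_way"]
    minutes = catalogue["transport_minutes_per_way"]
    transport_dkk = 2.0 * contacts * km_per_way * catalogue["patient_transport_per_km"]
    transport_h = 2.0 * contacts * minutes / 60.0

    course_h = (SESSION_HOURS * (records["training_attended"] + records["education_attended"])
                + INTERVIEW_HOURS * records.get("interviews_attended", pd.Series(0, index=records.index)))

    # time of patients below pension age is productive (gross wage), at/above: leisure (net)
    wage = np.empty(n)
    ages = records["age"].to_numpy()
    genders = records["gender"].to_numpy()
    for i in range(n):
        kind = "productive" if ages[i] < pension_age else "leisure"
        wage[i] = lookup_salary(salaries, genders[i], ages[i], kind)
    out["informal_time"] = (course_h + transport_h).to_numpy() * wage
    out["patient_transport"] = transport_dkk.astype(float)

    weeks = records[list(_WEEK_COLS)].sum(axis=1).to_numpy()
    gross = np.array([lookup_salary(salaries, g, a, "productive") for g, a in zip(genders, ages)])
    out["productivity_loss"] = np.where(ages >= pension_age, 0.0,
                                        weeks * WORK_HOURS_PER_WEEK * gross)
    return out


def total_costs(components: pd.DataFrame, perspective: str,
                exclusions: Iterable[str] = ()) -> pd.Series:
    """Per-patient total cost under a perspective, with optional exclusions.

    Healthcare counts the formal-care share of the intervention plus primary
    care, medicine and secondary care; societal adds the full intervention,
    productivity loss, informal time and patient transport. Exclusions:
    ``patient_time`` drops informal time; ``post_followup_admissions`` drops
    admission costs accruing after the end of follow-up.
    """
    if perspective not in PERSPECTIVES:
        raise CatalogueError("perspective", f"must be one of {PERSPECTIVES}, got {perspective!r}")
    exclusions = tuple(exclusions)
    for exc in exclusions:
        if exc not in KNOWN_EXCLUSIONS:
            raise CatalogueError("exclusions", f"unknown exclusion {exc!r}; known: {KNOWN_EXCLUSIONS}")

    secondary = components["secondary_care"].copy()
    if "post_followup_admissions" in exclusions:
        secondary = secondary - components["secondary_care_post_followup"]

    base = components["primary_care"] + components["prescribed_medicine"] + secondary
    if perspective == "healthcare":
        return base + components["intervention_healthcare"]
    total = base + components["intervention"] + components["productivity_loss"] + components["patient_transport"]
    if "patient_time" not in exclusions:
        total = total + components["informal_time"]
    return total


def aggregate(components_row: Mapping[str, float], perspective: str,
              exclusions: Iterable[str] = ()) -> float:
    """Single-patient perspective total (scalar convenience over total_costs)."""
    df = pd.DataFrame([dict(components_row)])
    return float(total_costs(df, perspective, exclusions).iloc[0])
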