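"""Unit-cost catalogues, salary tables and course specifications.

The costing of a group-based rehabilitation course needs three structured
inputs:

* a :class:`CostCatalogue` of unit costs (staff wages per hour, transport
  tariffs per km or per way), together with the load factor applied to staff
  formal hours and the overhead rate applied to course subtotals;
* a :class:`SalaryTable` of national-average gross/net hourly wages by gender
  and 5-year age band, used to value patient and volunteer time by the
  opportunity-cost method (gross wage for productive time, net wage for
  leisure time);
* a :class:`CourseSpec` listing the per-role hours that one course consumes.

All three round-trip losslessly through small YAML documents; shipped
fixtures live under :mod:`rehabcea.data`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = [
    "CatalogueError",
    "CostCatalogue",
    "SalaryTable",
    "RoleHours",
    "CourseSpec",
    "load_catalogue",
    "load_salary_table",
    "load_course_spec",
    "lookup_salary",
    "data_path",
]


class CatalogueError(ValueError):
    """Validation failure in a catalogue/salary/course document.

    Carries the offending field name so callers (and error messages) can
    point at the exact key that failed.
    """

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def data_path(name: str) -> Path:
    """Return the path of a shipped data fixture (e.g. ``item_costs_2013.yaml``)."""
    return Path(str(resources.files("rehabcea").joinpath("data", name)))


# ---------------------------------------------------------------------------
# CostCatalogue


@dataclass(frozen=True)
class CostCatalogue:
    """Named unit costs plus the load factor and overhead rate.

    ``items`` maps item name -> unit cost in DKK (per hour, per way or per
    km depending on the item). ``load_factor`` multiplies staff formal hours
    to cover non-productive time (1.0 = no loading); ``overhead_rate`` is the
    fraction added for capital/indirect costs; ``price_year`` is the common
    price year of all entries.
    """

    items: Mapping[str, float]
    load_factor: float = 1.0
    overhead_rate: float = 0.0
    price_year: int = 2013

    def __post_init__(self):
        for name, cost in self.items.items():
            if not isinstance(cost, (int, float)) or not cost >= 0:  # also rejects NaN
                raise CatalogueError(f"items.{name}", f"unit cost must be >= 0, got {cost!r}")
        if self.load_factor < 1:
            raise CatalogueError("load_factor", f"must be >= 1, got {self.load_factor}")
        if not 0 <= self.overhead_rate <= 1:
            raise CatalogueError("overhead_rate", f"must be in [0, 1], got {self.overhead_rate}")

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.items[name])
        except KeyError:
            raise CatalogueError(f"items.{name}", "unknown catalogue item") from None

    def replace(self, **overrides) -> "CostCatalogue":
        """Return a copy with item and/or attribute overrides applied.

        Keys that match an item name override that unit cost; ``load_factor``,
        ``overhead_rate`` and ``price_year`` override the attributes. Unknown
        keys raise :class:`CatalogueError` before any computation.
        """
        items = dict(self.items)
        attrs = {"load_factor": self.load_factor, "overhead_rate": self.overhead_rate,
                 "price_year": self.price_year}
        for key, value in overrides.items():
            if key in attrs:
                attrs[key] = value
            elif key in items:
                items[key] = value
            else:
                raise CatalogueError(key, "unknown override key")
        return CostCatalogue(items=items, **attrs)

    def to_dict(self) -> dict:
        return {"items": dict(self.items), "load_factor": self.load_factor,
                "overhead_rate": self.overhead_rate, "price_year": self.price_year}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_catalogue(path: str | Path) -> CostCatalogue:
    """Load and validate a :class:`CostCatalogue` from a YAML document."""
    doc = _load_yaml_mapping(path)
    for key in ("items", "load_factor", "overhead_rate", "price_year"):
        if key not in doc:
            raise CatalogueError(key, "missing required key")
    if not isinstance(doc["items"], dict):
        raise CatalogueError("items", "must be a mapping of item name -> unit cost")
    return CostCatalogue(
        items={str(k): float(v) for k, v in doc["items"].items()},
        load_factor=float(doc["load_factor"]),
        overhead_rate=float(doc["overhead_rate"]),
        price_year=int(doc["price_year"]),
    )


# ---------------------------------------------------------------------------
# SalaryTable

_BAND_WIDTH = 5


@dataclass(frozen=True)
class SalaryTable:
    """Gross/net hourly wages by (gender, 5-year age band).

    ``entries[gender][band_start]`` is ``{"gross": DKK/h, "net": DKK/h}``
    with ``band_start`` the lower edge of a 5-year band (60 covers ages
    60-64). Ages above the top band clamp to the top band; ages below the
    bottom band are a lookup error.
    """

    entries: Mapping[str, Mapping[int, Mapping[str, float]]]

    def __post_init__(self):
        for gender, bands in self.entries.items():
            if not bands:
                raise CatalogueError(f"entries.{gender}", "no age bands")
            starts = sorted(bands)
            for lo, hi in zip(starts, starts[1:]):
                if hi - lo != _BAND_WIDTH:
                    raise CatalogueError(
                        f"entries.{gender}", f"age bands must be contiguous 5-year bands, gap at {lo}-{hi}")
            for start, wages in bands.items():
                if wages["net"] > wages["gross"]:
                    raise CatalogueError(
                        f"entries.{gender}.{start}", f"net wage {wages['net']} exceeds gross {wages['gross']}")
                if wages["gross"] < 0 or wages["net"] < 0:
                    raise CatalogueError(f"entries.{gender}.{start}", "wages must be >= 0")

    def band_for(self, gender: str, age: int | float) -> int:
        if gender not in self.entries:
            raise CatalogueError("gender", f"unknown gender {gender!r}; have {sorted(self.entries)}")
        starts = sorted(self.entries[gender])
        if age < starts[0]:
            raise CatalogueError("age", f"age {age} below supported range (min {starts[0]})")
        band = starts[0] + _BAND_WIDTH * int((age - starts[0]) // _BAND_WIDTH)
        return min(band, starts[-1])  # clamp above the top band

    def wage(self, gender: str, age: int | float, kind: str) -> float:
        band = self.band_for(gender, age)  # validates gender and age range
        return float(self.entries[gender][band][kind])

    def iter_entries(self) -> Iterator[tuple[str, int, float, float]]:
        for gender, bands in self.entries.items():
            for start, wages in sorted(bands.items()):
                yield gender, start, float(wages["gross"]), float(wages["net"])

    def to_dict(self) -> dict:
        return {"entries": {g: {int(s): {"gross": float(w["gross"]), "net": float(w["net"])}
                                for s, w in bands.items()}
                            for g, bands in self.entries.items()}}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_salary_table(path: str | Path) -> SalaryTable:
    doc = _load_yaml_mapping(path)
    if "entries" not in doc:
        raise CatalogueError("entries", "missing required key")
    entries = {str(g): {int(s): {"gross": float(w["gross"]), "net": float(w["net"])}
                        for s, w in bands.items()}
               for g, bands in doc["entries"].items()}
    return SalaryTable(entries=entries)


def lookup_salary(table: SalaryTable, gender: str, age: int | float, time_type: str) -> float:
    """Hourly value of a person's time under the opportunity-cost method.

    Productive time is valued at the gross wage, leisure time at the net
    wage, matched on gender and 5-year age band.
    """
    if time_type not in ("leisure", "productive"):
        raise CatalogueError("time_type", f"must be 'leisure' or 'productive', got {time_type!r}")
    return table.wage(gender, age, "net" if time_type == "leisure" else "gross")


# ---------------------------------------------------------------------------
# CourseSpec


@dataclass(frozen=True)
class RoleHours:
    """Formal hours one course consumes for a single staff role."""

    training_h: float = 0.0
    education_h: float = 0.0
    interview_h: float = 0.0
    team_eval_h: float = 0.0

    def __post_init__(self):
        for name, value in asdict(self).items():
            if value < 0:
                raise CatalogueError(name, f"hours must be >= 0, got {value}")

    @property
    def total(self) -> float:
        return self.training_h + self.education_h + self.interview_h + self.team_eval_h


@dataclass(frozen=True)
class CourseSpec:
    """Resource profile of one rehabilitation course for one trial arm.

    The expert patient is a former patient acting as lay educator: their
    hours are valued (unloaded) at a flat pensioner net wage, and the
    hospital pays their transport, carried here as a per-course total.
    """

    arm: str
    nurse: RoleHours = field(default_factory=RoleHours)
    physiotherapist: RoleHours = field(default_factory=RoleHours)
    expert: RoleHours = field(default_factory=RoleHours)
    expert_transport_time_h: float = 0.0
    expert_transport_cost_total: float = 0.0
    patients_per_course: int = 10

    def __post_init__(self):
        if self.patients_per_course < 1:
            raise CatalogueError("patients_per_course", f"must be >= 1, got {self.patients_per_course}")
        if self.expert_transport_time_h < 0 or self.expert_transport_cost_total < 0:
            raise CatalogueError("expert_transport", "must be >= 0")

    def replace(self, **overrides) -> "CourseSpec":
        known = {"patients_per_course", "expert_transport_cost_total", "expert_transport_time_h"}
        bad = set(overrides) - known
        if bad:
            raise CatalogueError(sorted(bad)[0], "unknown course-spec override")
        kwargs = dict(arm=self.arm, nurse=self.nurse, physiotherapist=self.physiotherapist,
                      expert=self.expert, expert_transport_time_h=self.expert_transport_time_h,
                      expert_transport_cost_total=self.expert_transport_cost_total,
                      patients_per_course=self.patients_per_course)
        kwargs.update(overrides)
        return CourseSpec(**kwargs)

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "nurse": asdict(self.nurse),
            "physiotherapist": asdict(self.physiotherapist),
            "expert": asdict(self.expert),
            "expert_transport_time_h": self.expert_transport_time_h,
            "expert_transport_cost_total": self.expert_transport_cost_total,
            "patients_per_course": self.patients_per_course,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_course_spec(path: str | Path) -> CourseSpec:
    doc = _load_yaml_mapping(path)
    for key in ("arm", "nurse", "physiotherapist"):
        if key not in doc:
            raise CatalogueError(key, "missing required key")

    def role(key: str) -> RoleHours:
        raw = doc.get(key, {}) or {}
        return RoleHours(**{k: float(v) for k, v in raw.items()})

    return CourseSpec(
        arm=str(doc["arm"]),
        nurse=role("nurse"),
        physiotherapist=role("physiotherapist"),
        expert=role("expert"),
        expert_transport_time_h=float(doc.get("expert_transport_time_h", 0.0)),
        expert_transport_cost_total=float(doc.get("expert_transport_cost_total", 0.0)),
        patients_per_course=int(doc.get("patients_per_course", 10)),
    )


def _load_yaml_mapping(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise CatalogueError(str(path), f"malformed YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise CatalogueError(str(path), "document must be a mapping")
    return doc
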