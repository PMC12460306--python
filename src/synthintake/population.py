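"""Population-statistics configuration: validated categorical and conditional
distributions that ground all demographic sampling.

The configuration is a single JSON document (see ``assets/population_config.json``
for the packaged fixture and its schema). It holds census-style tables for an
adult catchment population: ethnicity, five age groups with numeric bracket
bounds, sex, relationship status conditional on (age bracket, sex), parental
status and disability prevalence by (age bracket, sex), type shares over ten
disability categories, locale weights for name assignment, and a catalog of
clinical attributes (psychiatric conditions with commonly prescribed
medications, unconstrained lists, and comorbidity-count weights).

Probabilities are absolute fractions that must sum to 1 within 1e-9; a
distribution may set ``"normalize": true`` to request explicit renormalisation
(census-derived percents rarely sum exactly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np

__all__ = [
    "CategoricalDist",
    "ConditionalTable",
    "AttributeCatalog",
    "PopulationConfig",
    "PopulationConfigError",
    "load_population_config",
    "sample_categorical",
    "packaged_config_path",
]

PROB_TOL = 1e-9


class PopulationConfigError(ValueError):
    """Raised when a population configuration violates its schema or invariants."""


@dataclass(frozen=True)
class CategoricalDist:
    """A named discrete distribution over ordered category labels."""

    labels: tuple[str, ...]
    probs: tuple[float, ...]
    name: str = ""

    @classmethod
    def from_spec(cls, spec: Mapping[str, Any], name: str = "") -> "CategoricalDist":
        """Build from a JSON table, honoring the optional ``normalize`` flag."""
        probs = [float(p) for p in spec["probs"]]
        if spec.get("normalize"):
            total = sum(probs)
            if total <= 0:
                raise PopulationConfigError(
                    f"distribution {name or '?'}: cannot normalize, total {total}"
                )
            probs = [p / total for p in probs]
        return cls(labels=tuple(spec["labels"]), probs=tuple(probs), name=name)

    def __post_init__(self) -> None:
        label = self.name or "categorical distribution"
        if not self.labels:
            raise PopulationConfigError(f"{label}: no categories")
        if len(self.labels) != len(self.probs):
            raise PopulationConfigError(
                f"{label}: {len(self.labels)} labels but {len(self.probs)} probabilities"
            )
        if any(not l for l in self.labels):
            raise PopulationConfigError(f"{label}: empty category label")
        if len(set(self.labels)) != len(self.labels):
            raise PopulationConfigError(f"{label}: duplicate category labels")
        if any(p < 0 for p in self.probs):
            raise PopulationConfigError(f"{label}: negative probability")
        total = float(sum(self.probs))
        if abs(total - 1.0) > PROB_TOL:
            raise PopulationConfigError(
                f"normalization error in {label!r}: probabilities sum to {total!r}, not 1"
            )

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.probs)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.probs))


@dataclass(frozen=True)
class ConditionalTable:
    """A CategoricalDist per (age bracket, sex) cell, with full grid coverage."""

    brackets: tuple[str, ...]
    sexes: tuple[str, ...]
    categories: tuple[str, ...]
    rows: dict[str, CategoricalDist]  # key "bracket|sex"
    name: str = ""

    @staticmethod
    def key(bracket: str, sex: str) -> str:
        return f"{bracket}|{sex}"

    def __post_init__(self) -> None:
        label = self.name or "conditional table"
        for bracket in self.brackets:
            for sex in self.sexes:
                key = self.key(bracket, sex)
                if key not in self.rows:
                    raise PopulationConfigError(
                        f"consistency error in {label!r}: missing row for cell ({bracket}, {sex})"
                    )
        for key, dist in self.rows.items():
            if dist.labels != self.categories:
                raise PopulationConfigError(
                    f"consistency error in {label!r}, row {key!r}: categories "
                    f"{list(dist.labels)} do not match configured {list(self.categories)}"
                )

    def dist(self, bracket: str, sex: str) -> CategoricalDist:
        return self.rows[self.key(bracket, sex)]


@dataclass(frozen=True)
class AttributeCatalog:
    """Clinical attribute lists: condition→medication map, unconstrained lists,
    and comorbidity-count weights over one to three conditions."""

    condition_to_meds: dict[str, tuple[str, ...]]
    unconstrained_lists: dict[str, tuple[str, ...]]
    prob_any: float
    count_weights: dict[int, float]

    def __post_init__(self) -> None:
        if not self.condition_to_meds:
            raise PopulationConfigError("catalog: condition_to_meds is empty")
        for cond, meds in self.condition_to_meds.items():
            if not meds:
                raise PopulationConfigError(
                    f"catalog: medication list for condition {cond!r} is empty"
                )
        if not 0.0 <= self.prob_any <= 1.0:
            raise PopulationConfigError(f"catalog: prob_any {self.prob_any} outside [0, 1]")
        if set(self.count_weights) - {1, 2, 3}:
            raise PopulationConfigError(
                f"catalog: count_weights keys {sorted(self.count_weights)} not within {{1,2,3}}"
            )
        total = sum(self.count_weights.values())
        if abs(total - 1.0) > PROB_TOL:
            raise PopulationConfigError(
                f"normalization error in 'count_weights': weights sum to {total!r}, not 1"
            )


@dataclass(frozen=True)
class PopulationConfig:
    """Fully validated population statistics for demographic sampling."""

    ethnicity: CategoricalDist
    age_groups: CategoricalDist
    age_bounds: tuple[tuple[int, int], ...]
    sex: CategoricalDist
    relationship_by_age_sex: ConditionalTable
    parental_by_age_sex: dict[str, float]
    disability_any_by_age_sex: dict[str, float]
    disability_type_shares: CategoricalDist
    name_locale_weights: CategoricalDist
    catalog: AttributeCatalog
    reference_date: str = "2025-01-01"
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.age_bounds) != len(self.age_groups.labels):
            raise PopulationConfigError(
                "age_groups: bracket bounds count does not match label count"
            )
        prev_hi = None
        for (lo, hi), label in zip(self.age_bounds, self.age_groups.labels):
            if lo > hi:
                raise PopulationConfigError(f"age_groups: bracket {label!r} bounds reversed")
            if prev_hi is not None and lo != prev_hi + 1:
                raise PopulationConfigError(
                    f"age_groups: bracket {label!r} does not abut the previous bracket "
                    f"(gap or overlap at {lo})"
                )
            prev_hi = hi
        for field in ("parental_by_age_sex", "disability_any_by_age_sex"):
            table: dict[str, float] = getattr(self, field)
            for bracket in self.age_groups.labels:
                for sex in self.sex.labels:
                    key = ConditionalTable.key(bracket, sex)
                    if key not in table:
                        raise PopulationConfigError(
                            f"consistency error in {field!r}: missing cell ({bracket}, {sex})"
                        )
                    p = table[key]
                    if not 0.0 <= p <= 1.0:
                        raise PopulationConfigError(
                            f"{field}: probability {p} for cell {key!r} outside [0, 1]"
                        )
        if len(self.disability_type_shares.labels) != 10:
            raise PopulationConfigError(
                "disability_type_shares: expected the 10 configured disability types, "
                f"got {len(self.disability_type_shares.labels)}"
            )

    def bracket_bounds(self, bracket: str) -> tuple[int, int]:
        idx = self.age_groups.labels.index(bracket)
        return self.age_bounds[idx]

    # -- serialization -------------------------------------------------------

    def to_json_dict(self) -> dict[str, Any]:
        """Re-emit the documented JSON schema (inverse of :func:`load_population_config`)."""
        return {
            "schema_version": 1,
            "description": self.description,
            "reference_date": self.reference_date,
            "ethnicity": {"labels": list(self.ethnicity.labels), "probs": list(self.ethnicity.probs)},
            "age_groups": {
                "labels": list(self.age_groups.labels),
                "probs": list(self.age_groups.probs),
                "bounds": [list(b) for b in self.age_bounds],
            },
            "sex": {"labels": list(self.sex.labels), "probs": list(self.sex.probs)},
            "relationship_categories": list(self.relationship_by_age_sex.categories),
            "relationship_by_age_sex": {
                key: list(dist.probs) for key, dist in self.relationship_by_age_sex.rows.items()
            },
            "parental_by_age_sex": dict(self.parental_by_age_sex),
            "disability_any_by_age_sex": dict(self.disability_any_by_age_sex),
            "disability_type_shares": {
                "labels": list(self.disability_type_shares.labels),
                "probs": list(self.disability_type_shares.probs),
            },
            "name_locale_weights": {
                "labels": list(self.name_locale_weights.labels),
                "probs": list(self.name_locale_weights.probs),
            },
            "catalog": {
                "condition_to_meds": {
                    c: list(m) for c, m in self.catalog.condition_to_meds.items()
                },
                "unconstrained_lists": {
                    k: list(v) for k, v in self.catalog.unconstrained_lists.items()
                },
                "comorbidity": {
                    "prob_any": self.catalog.prob_any,
                    "count_weights": {str(k): v for k, v in self.catalog.count_weights.items()},
                },
            },
        }

    def dump_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")


def _require(doc: Mapping[str, Any], field: str) -> Any:
    if field not in doc:
        raise PopulationConfigError(f"schema error: missing required table {field!r}")
    return doc[field]


def _dist(doc: Mapping[str, Any], field_name: str) -> CategoricalDist:
    return CategoricalDist.from_spec(_require(doc, field_name), name=field_name)


def parse_population_config(doc: Mapping[str, Any]) -> PopulationConfig:
    """Build a validated :class:`PopulationConfig` from a parsed JSON document."""
    ethnicity = _dist(doc, "ethnicity")
    age_groups = _dist(doc, "age_groups")
    sex = _dist(doc, "sex")
    bounds = tuple(
        (int(lo), int(hi)) for lo, hi in _require(doc, "age_groups").get("bounds", ())
    )
    if not bounds:
        raise PopulationConfigError("schema error: age_groups.bounds is required")

    categories = tuple(_require(doc, "relationship_categories"))
    rel_raw = _require(doc, "relationship_by_age_sex")
    rows = {}
    for key, probs in rel_raw.items():
        rows[key] = CategoricalDist(
            labels=categories,
            probs=tuple(float(p) for p in probs),
            name=f"relationship_by_age_sex[{key}]",
        )
    relationship = ConditionalTable(
        brackets=age_groups.labels,
        sexes=sex.labels,
        categories=categories,
        rows=rows,
        name="relationship_by_age_sex",
    )

    cat_raw = _require(doc, "catalog")
    comorbidity = _require(cat_raw, "comorbidity")
    catalog = AttributeCatalog(
        condition_to_meds={c: tuple(m) for c, m in _require(cat_raw, "condition_to_meds").items()},
        unconstrained_lists={
            k: tuple(v) for k, v in _require(cat_raw, "unconstrained_lists").items()
        },
        prob_any=float(comorbidity["prob_any"]),
        count_weights={int(k): float(v) for k, v in comorbidity["count_weights"].items()},
    )

    return PopulationConfig(
        ethnicity=ethnicity,
        age_groups=age_groups,
        age_bounds=bounds,
        sex=sex,
        relationship_by_age_sex=relationship,
        parental_by_age_sex={k: float(v) for k, v in _require(doc, "parental_by_age_sex").items()},
        disability_any_by_age_sex={
            k: float(v) for k, v in _require(doc, "disability_any_by_age_sex").items()
        },
        disability_type_shares=_dist(doc, "disability_type_shares"),
        name_locale_weights=_dist(doc, "name_locale_weights"),
        catalog=catalog,
        reference_date=str(doc.get("reference_date", "2025-01-01")),
        description=str(doc.get("description", "")),
    )


def load_population_config(path: str | Path) -> PopulationConfig:
    """Load and validate a population configuration from a JSON file.

    This is the single entry point used by all sampling modules. Validation
    failures raise :class:`PopulationConfigError` naming the offending field
    (and, for conditional tables, the offending row key).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PopulationConfigError(f"schema error: {path} is not valid JSON: {exc}") from exc
    return parse_population_config(doc)


def packaged_config_path() -> Path:
    """Path of the packaged fixture configuration."""
    return Path(__file__).parent / "assets" / "population_config.json"


def sample_categorical(dist: CategoricalDist, rng: np.random.Generator) -> str:
    """Draw one label from ``dist`` using the provided generator.

    Repeated calls with an identically seeded generator reproduce the same
    label sequence exactly.
    """
    u = rng.random()
    idx = int(np.searchsorted(dist.cumulative(), u, side="right"))
    return dist.labels[min(idx, len(dist.labels) - 1)]
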