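"""Synthetic patient profiles: template construction, demographic sampling
from the population configuration, conditional attribute assignment,
identity generation from weighted locale name tables, and narrative
enrichment through the chat-backend contract.

Seeding model: a cohort is generated from one master seed, with patient
``i``'s random stream derived as ``default_rng([master_seed, i])``. Streams
are therefore independent of batch composition — patient ``i`` is identical
whether generated alone or inside a cohort.
"""

from __future__ import annotations

import json
import re
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .backends import ChatBackend, InferenceOptions, Message, RESPONSE_PREFIX
from .population import (
    AttributeCatalog,
    CategoricalDist,
    ConditionalTable,
    PopulationConfig,
    sample_categorical,
)
from .questionbank import QuestionBank

__all__ = [
    "FieldSpec",
    "ProfileTemplate",
    "Demographics",
    "Identity",
    "PatientProfile",
    "ProfileError",
    "generate_profile_template",
    "canonical_template",
    "sample_demographics",
    "assign_disability",
    "assign_conditions",
    "assign_identity",
    "enrich_narrative",
    "generate_patient",
    "generate_cohort",
    "write_profiles",
    "read_profiles",
    "load_name_table",
    "NARRATIVE_FIELDS",
]

_ASSETS = Path(__file__).parent / "assets"

# Narrative profile fields and the question-bank section each one feeds.
# ``children_details`` is backend-filled only for patients with children.
NARRATIVE_FIELDS: dict[str, str] = {
    "family_social_history": "Family History",
    "health_injury_history": "Medical History",
    "interests": "Personal History",
    "daily_lifestyle": "Personal History",
}
CONDITIONAL_NARRATIVE_FIELDS: dict[str, str] = {
    "children_details": "General Information",
}


class ProfileError(ValueError):
    """Raised on template-coverage or profile-construction failures."""


class FieldSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    field_id: str
    section: str
    kind: str  # fixed | narrative
    prompt_hint: str

    @model_validator(mode="after")
    def _check(self) -> "FieldSpec":
        if self.kind not in ("fixed", "narrative"):
            raise ProfileError(f"field {self.field_id!r}: unknown kind {self.kind!r}")
        return self


class ProfileTemplate(BaseModel):
    """Ordered field specifications covering every question-bank section."""

    model_config = ConfigDict(frozen=True)

    fields: tuple[FieldSpec, ...]

    @model_validator(mode="after")
    def _check(self) -> "ProfileTemplate":
        ids = [f.field_id for f in self.fields]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ProfileError(f"duplicate template field ids: {dupes}")
        return self

    @property
    def sections(self) -> tuple[str, ...]:
        seen: list[str] = []
        for f in self.fields:
            if f.section not in seen:
                seen.append(f.section)
        return tuple(seen)

    def hints_for_section(self, section: str, kind: str | None = None) -> tuple[str, ...]:
        return tuple(
            f.prompt_hint
            for f in self.fields
            if f.section == section and (kind is None or f.kind == kind)
        )


def generate_profile_template(bank: QuestionBank, backend: ChatBackend) -> ProfileTemplate:
    """Ask the backend for a profile template that strictly adheres to the
    bank's structure, then validate section coverage.

    With the scripted mock this reproduces the packaged canonical template
    deterministically (one field per question point).
    """
    if not bank.sections:
        raise ProfileError("cannot build a template from an empty question bank")
    prompt = (_ASSETS / "prompts" / "template_prompt.txt").read_text().replace(
        "{bank}", bank.serialize()
    )
    completion = backend.chat(
        [Message(role="system", content=prompt),
         Message(role="user", content="Please produce the profile template now.")],
        InferenceOptions(),
    )
    text = completion.strip()
    if text.startswith(RESPONSE_PREFIX):
        text = text[len(RESPONSE_PREFIX):].strip()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ProfileError(f"backend returned non-JSON template: {exc}") from exc
    template = ProfileTemplate(
        fields=tuple(FieldSpec(**spec) for spec in doc.get("fields", []))
    )
    missing = set(bank.titles) - set(template.sections)
    if missing:
        raise ProfileError(
            f"template-coverage error: backend template omits bank sections {sorted(missing)}"
        )
    return template


def canonical_template() -> ProfileTemplate:
    """The packaged canonical template for the packaged question bank
    (the reviewed reference the mock-backend path is validated against)."""
    doc = json.loads((_ASSETS / "profile_template.json").read_text())
    return ProfileTemplate(fields=tuple(FieldSpec(**spec) for spec in doc["fields"]))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


class Demographics(BaseModel):
    model_config = ConfigDict(frozen=True)

    ethnicity: str
    age_bracket: str
    age: int
    sex: str
    relationship_status: str
    has_children: bool


class Identity(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    given_name: str
    surname: str
    date_of_birth: str  # ISO date
    address: str
    occupation: str
    locale: str


class PatientProfile(BaseModel):
    """A complete synthetic patient: sampler-filled structured attributes plus
    backend-filled narrative fields."""

    model_config = ConfigDict(frozen=True)

    patient_id: int
    master_seed: int
    reference_date: str
    identity: Identity
    demographics: Demographics
    relationship_status: str
    has_children: bool
    disabilities: tuple[str, ...]
    conditions: tuple[dict[str, str], ...]
    attributes: dict[str, str]
    narrative: dict[str, dict[str, str]]  # field -> {text, filled_by}

    @model_validator(mode="after")
    def _check(self) -> "PatientProfile":
        if not 0 <= len(self.conditions) <= 3:
            raise ProfileError(
                f"patient {self.patient_id}: {len(self.conditions)} conditions (allowed 0-3)"
            )
        for entry in self.conditions:
            if not entry.get("condition") or not entry.get("medication"):
                raise ProfileError(
                    f"patient {self.patient_id}: condition entry missing fields: {entry}"
                )
        ref = date.fromisoformat(self.reference_date)
        dob = date.fromisoformat(self.identity.date_of_birth)
        if _age_at(dob, ref) != self.demographics.age:
            raise ProfileError(
                f"patient {self.patient_id}: date of birth {dob} implies age "
                f"{_age_at(dob, ref)} at {ref}, profile says {self.demographics.age}"
            )
        return self

    def fixed_dump(self) -> dict:
        """The sampler-filled portion, used for narrative prompts and diffing."""
        return {
            "patient_id": self.patient_id,
            "identity": self.identity.model_dump(),
            "demographics": self.demographics.model_dump(),
            "relationship_status": self.relationship_status,
            "has_children": self.has_children,
            "disabilities": list(self.disabilities),
            "conditions": [dict(c) for c in self.conditions],
            "attributes": dict(self.attributes),
        }

    def to_json_dict(self) -> dict:
        doc = self.fixed_dump()
        doc["master_seed"] = self.master_seed
        doc["reference_date"] = self.reference_date
        doc["narrative"] = {k: dict(v) for k, v in self.narrative.items()}
        return doc


def _age_at(dob: date, ref: date) -> int:
    years = ref.year - dob.year
    if (ref.month, ref.day) < (dob.month, dob.day):
        years -= 1
    return years


def sample_demographics(cfg: PopulationConfig, rng: np.random.Generator) -> Demographics:
    """Draw one demographic bundle: ethnicity, age bracket and exact age, sex,
    relationship status and parental status from their conditional tables."""
    ethnicity = sample_categorical(cfg.ethnicity, rng)
    bracket = sample_categorical(cfg.age_groups, rng)
    lo, hi = cfg.bracket_bounds(bracket)
    age = int(rng.integers(lo, hi + 1))
    sex = sample_categorical(cfg.sex, rng)
    relationship = sample_categorical(cfg.relationship_by_age_sex.dist(bracket, sex), rng)
    p_child = cfg.parental_by_age_sex[ConditionalTable.key(bracket, sex)]
    has_children = bool(rng.random() < p_child)
    return Demographics(
        ethnicity=ethnicity,
        age_bracket=bracket,
        age=age,
        sex=sex,
        relationship_status=relationship,
        has_children=has_children,
    )


def assign_disability(
    bundle: Demographics, cfg: PopulationConfig, rng: np.random.Generator
) -> tuple[str, ...]:
    """With the cell's prevalence probability, assign exactly one disability
    type drawn from the configured type shares; otherwise none."""
    key = ConditionalTable.key(bundle.age_bracket, bundle.sex)
    prevalence = cfg.disability_any_by_age_sex[key]
    if rng.random() < prevalence:
        return (sample_categorical(cfg.disability_type_shares, rng),)
    return ()


def assign_conditions(
    catalog: AttributeCatalog, rng: np.random.Generator
) -> tuple[dict[str, str], ...]:
    """With probability ``prob_any``, draw a comorbidity count from the 1-3
    weights, then that many distinct conditions (without replacement), each
    paired with one medication from its list."""
    if rng.random() >= catalog.prob_any:
        return ()
    counts = sorted(catalog.count_weights)
    weights = np.array([catalog.count_weights[c] for c in counts])
    u = rng.random()
    count = counts[int(np.searchsorted(np.cumsum(weights), u, side="right").clip(max=len(counts) - 1))]
    conditions = sorted(catalog.condition_to_meds)
    if count > len(conditions):
        raise ProfileError(
            f"comorbidity count {count} exceeds the {len(conditions)} cataloged conditions"
        )
    chosen_idx = rng.choice(len(conditions), size=count, replace=False)
    out = []
    for idx in sorted(int(i) for i in chosen_idx):
        condition = conditions[idx]
        meds = catalog.condition_to_meds[condition]
        medication = meds[int(rng.integers(0, len(meds)))]
        out.append({"condition": condition, "medication": medication})
    return tuple(out)


def load_name_table() -> dict:
    return json.loads((_ASSETS / "names.json").read_text())


def assign_identity(
    bundle: Demographics,
    cfg: PopulationConfig,
    name_table: Mapping,
    rng: np.random.Generator,
) -> Identity:
    """Draw a name locale from the census-weighted locale distribution, a name
    from that locale's table, a date of birth uniform within the bracket and
    consistent with the exact age at the reference date, and an address and
    occupation from the packaged identity lists."""
    locale = sample_categorical(cfg.name_locale_weights, rng)
    locales = name_table["locales"]
    if locale not in locales:
        raise ProfileError(f"name locale {locale!r} missing from the name table")
    entry = locales[locale]
    given_key = f"given_{bundle.sex}" if f"given_{bundle.sex}" in entry else "given_female"
    given = entry[given_key][int(rng.integers(0, len(entry[given_key])))]
    surname = entry["surnames"][int(rng.integers(0, len(entry["surnames"])))]

    ref = date.fromisoformat(cfg.reference_date)
    latest = _shift_years(ref, -bundle.age)  # turned `age` exactly today
    earliest = _shift_years(ref, -(bundle.age + 1)) + timedelta(days=1)
    span = (latest - earliest).days
    dob = earliest + timedelta(days=int(rng.integers(0, span + 1)))

    number = int(rng.integers(100, 9999))
    street = name_table["street_names"][int(rng.integers(0, len(name_table["street_names"])))]
    city = name_table["cities"][int(rng.integers(0, len(name_table["cities"])))]
    occupation = name_table["occupations"][int(rng.integers(0, len(name_table["occupations"])))]
    return Identity(
        name=f"{given} {surname}",
        given_name=given,
        surname=surname,
        date_of_birth=dob.isoformat(),
        address=f"{number} {street}, {city}",
        occupation=occupation,
        locale=locale,
    )


def _shift_years(d: date, years: int) -> date:
    try:
        return d.replace(year=d.year + years)
    except ValueError:  # Feb 29
        return d.replace(year=d.year + years, day=28)


def _sample_attributes(catalog: AttributeCatalog, rng: np.random.Generator) -> dict[str, str]:
    out = {}
    for field, key in (
        ("allergies", "allergies"),
        ("supplements", "supplements"),
        ("recreational_drugs", "recreational_drugs"),
        ("visit_reason", "visit_reasons"),
    ):
        values = catalog.unconstrained_lists[key]
        out[field] = values[int(rng.integers(0, len(values)))]
    return out


# ---------------------------------------------------------------------------
# narrative enrichment and assembly
# ---------------------------------------------------------------------------


def enrich_narrative(
    profile: PatientProfile,
    template: ProfileTemplate,
    backend: ChatBackend,
) -> PatientProfile:
    """Fill every narrative field through the backend; fixed fields are left
    byte-identical. Backend failures and empty completions are raised with the
    offending field id."""
    prompt_template = (_ASSETS / "prompts" / "narrative_prompt.txt").read_text()
    fields = dict(NARRATIVE_FIELDS)
    if profile.has_children:
        fields.update(CONDITIONAL_NARRATIVE_FIELDS)
    fixed = profile.fixed_dump()
    narrative: dict[str, dict[str, str]] = {}
    for field_id, section in fields.items():
        hints = template.hints_for_section(section, kind="narrative") or template.hints_for_section(section)
        prompt = (
            prompt_template
            .replace("{field_id}", field_id)
            .replace("{hint}", "; ".join(hints[:3]))
            .replace("{profile}", json.dumps({**fixed, "narrative": narrative}, sort_keys=True))
        )
        try:
            text = backend.chat(
                [Message(role="system", content=prompt),
                 Message(role="user", content="Write this field now.")],
                InferenceOptions(),
            )
        except Exception as exc:
            raise ProfileError(f"narrative enrichment failed for field {field_id!r}: {exc}") from exc
        text = text.strip()
        if text.startswith(RESPONSE_PREFIX):
            text = text[len(RESPONSE_PREFIX):].strip()
        if not text:
            raise ProfileError(f"enrichment error: backend returned empty text for field {field_id!r}")
        narrative[field_id] = {"text": text, "filled_by": "backend"}
    return profile.model_copy(update={"narrative": narrative})


def generate_patient(
    cfg: PopulationConfig,
    template: ProfileTemplate,
    backend: ChatBackend,
    master_seed: int,
    index: int,
    name_table: Mapping | None = None,
) -> PatientProfile:
    """Generate patient ``index`` of a cohort keyed by ``master_seed``."""
    rng = np.random.default_rng([int(master_seed), int(index)])
    name_table = name_table or load_name_table()
    bundle = sample_demographics(cfg, rng)
    disabilities = assign_disability(bundle, cfg, rng)
    conditions = assign_conditions(cfg.catalog, rng)
    attributes = _sample_attributes(cfg.catalog, rng)
    identity = assign_identity(bundle, cfg, name_table, rng)
    profile = PatientProfile(
        patient_id=index,
        master_seed=int(master_seed),
        reference_date=cfg.reference_date,
        identity=identity,
        demographics=bundle,
        relationship_status=bundle.relationship_status,
        has_children=bundle.has_children,
        disabilities=disabilities,
        conditions=conditions,
        attributes=attributes,
        narrative={},
    )
    return enrich_narrative(profile, template, backend)


def generate_cohort(
    cfg: PopulationConfig,
    template: ProfileTemplate,
    backend: ChatBackend,
    n: int,
    master_seed: int,
) -> list[PatientProfile]:
    name_table = load_name_table()
    return [
        generate_patient(cfg, template, backend, master_seed, i, name_table=name_table)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# persistence (JSON lines, one profile per line)
# ---------------------------------------------------------------------------


def write_profiles(cohort: Sequence[PatientProfile], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for profile in cohort:
            fh.write(json.dumps(profile.to_json_dict(), ensure_ascii=False) + "\n")


def read_profiles(path: str | Path) -> list[PatientProfile]:
    out: list[PatientProfile] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                doc = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ProfileError(f"malformed profile at line {lineno}: {exc}") from exc
            out.append(profile_from_dict(doc))
    return out


def profile_from_dict(doc: Mapping) -> PatientProfile:
    return PatientProfile(
        patient_id=int(doc["patient_id"]),
        master_seed=int(doc.get("master_seed", 0)),
        reference_date=str(doc["reference_date"]),
        identity=Identity(**doc["identity"]),
        demographics=Demographics(**doc["demographics"]),
        relationship_status=str(doc["relationship_status"]),
        has_children=bool(doc["has_children"]),
        disabilities=tuple(doc.get("disabilities", ())),
        conditions=tuple(dict(c) for c in doc.get("conditions", ())),
        attributes=dict(doc.get("attributes", {})),
        narrative={k: dict(v) for k, v in doc.get("narrative", {}).items()},
    )
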