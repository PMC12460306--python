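"""Patient generation: template coverage, demographic sampling against
binomial/multinomial oracles, conditional assignment, identity consistency,
narrative enrichment, and cohort persistence."""

import json
from collections import Counter
from datetime import date

import numpy as np
import pytest

from synthintake.backends import BackendError, ChatBackend, ScriptedMockBackend
from synthintake.patients import (
    ProfileError,
    assign_conditions,
    assign_disability,
    assign_identity,
    canonical_template,
    enrich_narrative,
    generate_patient,
    generate_profile_template,
    load_name_table,
    read_profiles,
    sample_demographics,
    write_profiles,
)
from synthintake.population import AttributeCatalog, parse_population_config
from synthintake.questionbank import QuestionBank, parse_question_bank


class TestTemplate:
    def test_mock_template_covers_bank_sections(self, bank, mock_backend):
        template = generate_profile_template(bank, mock_backend())
        assert set(template.sections) == set(bank.titles)

    def test_mock_path_reproduces_canonical_template(self, bank, mock_backend):
        assert generate_profile_template(bank, mock_backend()) == canonical_template()

    def test_toy_single_section_bank(self, mock_backend):
        toy = parse_question_bank("## Only\n1. first point\n2. second point\n")
        template = generate_profile_template(toy, mock_backend())
        assert len(template.fields) >= 2
        assert all(f.section == "Only" for f in template.fields)

    def test_empty_bank_is_error(self, mock_backend):
        empty = QuestionBank(sections=())
        with pytest.raises(ProfileError, match="empty"):
            generate_profile_template(empty, mock_backend())

    def test_backend_omitting_a_section_is_coverage_error(self, bank):
        class Partial(ChatBackend):
            deterministic = True

            def chat(self, messages, options):
                return json.dumps(
                    {"fields": [{"field_id": "f", "section": bank.titles[0],
                                 "kind": "fixed", "prompt_hint": "x"}]}
                )

        with pytest.raises(ProfileError, match="template-coverage"):
            generate_profile_template(bank, Partial())


class TestDemographics:
    def test_deterministic_under_same_seed(self, cfg):
        b1 = sample_demographics(cfg, np.random.default_rng(42))
        b2 = sample_demographics(cfg, np.random.default_rng(42))
        assert b1 == b2

    def test_age_within_bracket(self, cfg):
        rng = np.random.default_rng(0)
        for _ in range(500):
            b = sample_demographics(cfg, rng)
            lo, hi = cfg.bracket_bounds(b.age_bracket)
            assert lo <= b.age <= hi

    def test_zero_parental_probability_cell(self, cfg):
        doc = cfg.to_json_dict()
        for key in doc["parental_by_age_sex"]:
            doc["parental_by_age_sex"][key] = 0.0
        cfg0 = parse_population_config(doc)
        rng = np.random.default_rng(1)
        assert not any(sample_demographics(cfg0, rng).has_children for _ in range(300))

    def test_relationship_frequencies_match_conditional_rows(self, cfg):
        """Per-cell relationship frequencies in a sampled cohort sit within 3
        binomial standard deviations of the configured conditional row."""
        rng = np.random.default_rng(3)
        bundles = [sample_demographics(cfg, rng) for _ in range(8000)]
        for bracket in cfg.age_groups.labels:
            for sex in cfg.sex.labels:
                cell = [b for b in bundles if b.age_bracket == bracket and b.sex == sex]
                if len(cell) < 50:
                    continue
                dist = cfg.relationship_by_age_sex.dist(bracket, sex)
                counts = Counter(b.relationship_status for b in cell)
                n = len(cell)
                for label, prob in zip(dist.labels, dist.probs):
                    sd = np.sqrt(n * prob * (1 - prob))
                    assert abs(counts[label] - n * prob) <= 3 * sd + 1, (bracket, sex, label)


class TestDisability:
    def _bundle(self, cfg, seed=0):
        return sample_demographics(cfg, np.random.default_rng(seed))

    def test_zero_prevalence_never_assigns(self, cfg):
        doc = cfg.to_json_dict()
        for key in doc["disability_any_by_age_sex"]:
            doc["disability_any_by_age_sex"][key] = 0.0
        cfg0 = parse_population_config(doc)
        rng = np.random.default_rng(5)
        bundle = self._bundle(cfg0)
        assert all(assign_disability(bundle, cfg0, rng) == () for _ in range(200))

    def test_certain_prevalence_single_share(self, cfg):
        doc = cfg.to_json_dict()
        for key in doc["disability_any_by_age_sex"]:
            doc["disability_any_by_age_sex"][key] = 1.0
        doc["disability_type_shares"]["probs"] = [0, 0, 0, 0, 0, 0, 0, 1.0, 0, 0]  # Hearing
        cfg1 = parse_population_config(doc)
        rng = np.random.default_rng(6)
        bundle = self._bundle(cfg1)
        assert all(assign_disability(bundle, cfg1, rng) == ("Hearing",) for _ in range(200))

    def test_product_probability_oracle(self, cfg):
        """P(type) = prevalence x share: at prevalence 0.3 and share 0.5 the
        joint rate must sit within 3 SDs of 0.15 over 1e5 draws."""
        doc = cfg.to_json_dict()
        for key in doc["disability_any_by_age_sex"]:
            doc["disability_any_by_age_sex"][key] = 0.3
        doc["disability_type_shares"]["probs"] = [0, 0.5, 0.5, 0, 0, 0, 0, 0, 0, 0]
        cfg2 = parse_population_config(doc)
        bundle = self._bundle(cfg2)
        rng = np.random.default_rng(7)
        n = 100_000
        hits = sum(assign_disability(bundle, cfg2, rng) == ("Pain-related",) for _ in range(n))
        sd = np.sqrt(n * 0.15 * 0.85)
        assert abs(hits - n * 0.15) <= 3 * sd


class TestConditions:
    def test_prob_any_zero_gives_empty(self, cfg):
        catalog = AttributeCatalog(
            condition_to_meds=dict(cfg.catalog.condition_to_meds),
            unconstrained_lists=dict(cfg.catalog.unconstrained_lists),
            prob_any=0.0,
            count_weights={1: 1.0},
        )
        rng = np.random.default_rng(0)
        assert all(assign_conditions(catalog, rng) == () for _ in range(200))

    def test_degenerate_catalog_single_condition(self):
        catalog = AttributeCatalog(
            condition_to_meds={"MDD": ("sertraline 50 mg",)},
            unconstrained_lists={"allergies": ("none",), "supplements": ("none",),
                                 "recreational_drugs": ("none",), "visit_reasons": ("checkup",)},
            prob_any=1.0,
            count_weights={1: 1.0},
        )
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert assign_conditions(catalog, rng) == (
                {"condition": "MDD", "medication": "sertraline 50 mg"},
            )

    def test_count_exceeding_catalog_is_error(self):
        catalog = AttributeCatalog(
            condition_to_meds={"A": ("x",), "B": ("y",)},
            unconstrained_lists={"allergies": ("none",), "supplements": ("none",),
                                 "recreational_drugs": ("none",), "visit_reasons": ("v",)},
            prob_any=1.0,
            count_weights={3: 1.0},
        )
        with pytest.raises(ProfileError, match="exceeds"):
            assign_conditions(catalog, np.random.default_rng(2))

    def test_multinomial_count_oracle_and_uniqueness(self, cfg):
        catalog = AttributeCatalog(
            condition_to_meds=dict(cfg.catalog.condition_to_meds),
            unconstrained_lists=dict(cfg.catalog.unconstrained_lists),
            prob_any=1.0,
            count_weights={1: 0.5, 2: 0.3, 3: 0.2},
        )
        rng = np.random.default_rng(3)
        n = 100_000
        counts = Counter()
        for _ in range(n):
            drawn = assign_conditions(catalog, rng)
            counts[len(drawn)] += 1
            names = [d["condition"] for d in drawn]
            assert len(set(names)) == len(names)
        for k, w in ((1, 0.5), (2, 0.3), (3, 0.2)):
            sd = np.sqrt(n * w * (1 - w))
            assert abs(counts[k] - n * w) <= 3 * sd


class TestIdentity:
    def test_dob_consistent_with_age_at_reference_date(self, cfg):
        rng = np.random.default_rng(0)
        table = load_name_table()
        ref = date.fromisoformat(cfg.reference_date)
        for _ in range(300):
            bundle = sample_demographics(cfg, rng)
            identity = assign_identity(bundle, cfg, table, rng)
            dob = date.fromisoformat(identity.date_of_birth)
            years = ref.year - dob.year - ((ref.month, ref.day) < (dob.month, dob.day))
            assert years == bundle.age
            lo, hi = cfg.bracket_bounds(bundle.age_bracket)
            assert lo <= years <= hi

    def test_single_locale_weights(self, cfg):
        doc = cfg.to_json_dict()
        doc["name_locale_weights"] = {"labels": ["en_CA"], "probs": [1.0]}
        cfg1 = parse_population_config(doc)
        rng = np.random.default_rng(1)
        table = load_name_table()
        bundle = sample_demographics(cfg1, rng)
        assert all(
            assign_identity(bundle, cfg1, table, rng).locale == "en_CA" for _ in range(50)
        )

    def test_locale_frequencies_match_weights(self, cfg):
        doc = cfg.to_json_dict()
        doc["name_locale_weights"] = {"labels": ["en_CA", "zh"], "probs": [0.7, 0.3]}
        cfg2 = parse_population_config(doc)
        rng = np.random.default_rng(2)
        table = load_name_table()
        bundle = sample_demographics(cfg2, rng)
        n = 10_000
        hits = sum(assign_identity(bundle, cfg2, table, rng).locale == "en_CA" for _ in range(n))
        sd = np.sqrt(n * 0.7 * 0.3)
        assert abs(hits - n * 0.7) <= 3 * sd

    def test_missing_locale_is_error(self, cfg, rng):
        bundle = sample_demographics(cfg, rng)
        with pytest.raises(ProfileError, match="missing"):
            assign_identity(bundle, cfg, {"locales": {}}, rng)


class TestNarrative:
    def test_all_fields_nonempty_and_fixed_fields_untouched(self, patient):
        assert patient.narrative
        for field_name, entry in patient.narrative.items():
            assert entry["text"].strip(), field_name
            assert entry["filled_by"] == "backend"

    def test_reproducible_under_same_seed(self, cfg, template, mock_backend):
        p1 = generate_patient(cfg, template, mock_backend(11), master_seed=11, index=0)
        p2 = generate_patient(cfg, template, mock_backend(11), master_seed=11, index=0)
        assert p1 == p2

    def test_name_only_difference_changes_only_name_interpolations(self, patient, template, mock_backend):
        other = patient.model_copy(
            update={
                "identity": patient.identity.model_copy(
                    update={"name": "Zoe Quill", "given_name": "Zoe", "surname": "Quill"}
                ),
                "narrative": {},
            }
        )
        base = patient.model_copy(update={"narrative": {}})
        e1 = enrich_narrative(base, template, mock_backend(4))
        e2 = enrich_narrative(other, template, mock_backend(4))
        first1 = patient.identity.given_name
        for field_name in e1.narrative:
            t1 = e1.narrative[field_name]["text"]
            t2 = e2.narrative[field_name]["text"]
            assert t1.replace(first1, "Zoe") == t2, field_name

    def test_empty_backend_output_names_field(self, patient, template):
        class Empty(ChatBackend):
            deterministic = True

            def chat(self, messages, options):
                return ""

        bare = patient.model_copy(update={"narrative": {}})
        with pytest.raises(ProfileError, match="family_social_history"):
            enrich_narrative(bare, template, Empty())

    def test_backend_failure_carries_field_context(self, patient, template):
        class Failing(ChatBackend):
            deterministic = True

            def chat(self, messages, options):
                raise BackendError("boom")

        bare = patient.model_copy(update={"narrative": {}})
        with pytest.raises(ProfileError, match="family_social_history"):
            enrich_narrative(bare, template, Failing())


class TestCohortPersistence:
    def test_roundtrip_three_profiles(self, cfg, template, mock_backend, tmp_path):
        cohort = [
            generate_patient(cfg, template, mock_backend(9), master_seed=9, index=i)
            for i in range(3)
        ]
        path = tmp_path / "cohort.jsonl"
        write_profiles(cohort, path)
        assert len(path.read_text().splitlines()) == 3
        assert read_profiles(path) == cohort

    def test_empty_cohort_roundtrip(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        write_profiles([], path)
        assert read_profiles(path) == []

    def test_truncated_line_cites_line_number(self, cfg, template, mock_backend, tmp_path):
        cohort = [
            generate_patient(cfg, template, mock_backend(9), master_seed=9, index=i)
            for i in range(2)
        ]
        path = tmp_path / "broken.jsonl"
        write_profiles(cohort, path)
        lines = path.read_text().splitlines()
        lines[1] = lines[1][: len(lines[1]) // 2]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ProfileError, match="line 2"):
            read_profiles(path)

    def test_patient_order_independence(self, cfg, template, mock_backend):
        """Patient i is identical whether generated alone or within a batch."""
        alone = generate_patient(cfg, template, mock_backend(21), master_seed=21, index=5)
        batch = [
            generate_patient(cfg, template, mock_backend(21), master_seed=21, index=i)
            for i in range(8)
        ]
        assert batch[5] == alone


class TestProfileInvariants:
    def test_property_sweep_over_generated_patients(self, cfg, template, mock_backend):
        """Structural invariants hold across a seeded sweep: 0-3 conditions
        with catalog medications, disabilities among the 10 configured types,
        age/DOB/bracket consistency (enforced at construction), narrative
        fields non-empty."""
        backend = mock_backend(31)
        types = set(cfg.disability_type_shares.labels)
        for i in range(120):
            p = generate_patient(cfg, template, backend, master_seed=31, index=i)
            assert 0 <= len(p.conditions) <= 3
            for entry in p.conditions:
                assert entry["medication"] in cfg.catalog.condition_to_meds[entry["condition"]]
            assert set(p.disabilities) <= types
            assert len(p.disabilities) <= 1
            assert all(v["text"] for v in p.narrative.values())
            assert ("children_details" in p.narrative) == p.has_children
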