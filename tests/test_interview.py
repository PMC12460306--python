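"""Dialogue engine: protocol parsing, role relabeling, chunked delivery with
context dumping, failure classification, summaries, and transcript export."""

import json

import pytest

from synthintake.backends import (
    ProtocolError,
    RESPONSE_PREFIX,
    STOP_TOKEN,
    ScriptedMockBackend,
)
from synthintake.interview import (
    Limits,
    Note,
    Turn,
    classify_session,
    compose_summary,
    export_transcript,
    parse_model_output,
    read_transcript,
    relabel_history,
    run_interview,
)
from synthintake.questionbank import parse_question_bank


class TestParseModelOutput:
    def test_note_and_payload_extraction(self):
        raw = "Note: poor sleep, 3 months <END_NOTE>\nRESPONSE: Thank you. How is your appetite?"
        parsed = parse_model_output(raw, "interviewer")
        assert parsed.note == "poor sleep, 3 months"
        assert parsed.payload == "Thank you. How is your appetite?"
        assert not parsed.leaked_cot and not parsed.is_stop

    def test_stop_token_detection(self):
        parsed = parse_model_output("RESPONSE: <STOP>", "interviewer")
        assert parsed.is_stop and parsed.payload == STOP_TOKEN

    def test_leaked_reasoning_before_prefix(self):
        raw = "Step 1: the previous question was... RESPONSE: I take sertraline."
        parsed = parse_model_output(raw, "patient")
        assert parsed.leaked_cot
        assert parsed.payload == "I take sertraline."

    def test_missing_prefix_falls_back_to_full_raw(self):
        parsed = parse_model_output("I just answered directly.", "patient")
        assert parsed.leaked_cot
        assert parsed.payload == "I just answered directly."

    def test_double_prefix_flags_leak_and_uses_last(self):
        raw = "RESPONSE: draft one\nRESPONSE: final answer"
        parsed = parse_model_output(raw, "patient")
        assert parsed.leaked_cot
        assert parsed.payload == "final answer"

    def test_embedded_stop_in_longer_text_is_not_stop(self):
        parsed = parse_model_output("RESPONSE: We are done now <STOP>", "interviewer")
        assert not parsed.is_stop


class TestRelabelHistory:
    def _turns(self, n):
        out = []
        for i in range(n):
            speaker = "patient" if i % 2 == 0 else "interviewer"
            out.append(Turn(index=i, speaker=speaker, text=f"t{i}", raw=f"t{i}"))
        return out

    def test_patient_perspective_shape(self):
        msgs = relabel_history(self._turns(3), "patient", system_prompt="P", opener="Q0")
        assert [m.role for m in msgs] == ["system", "user", "assistant", "user", "assistant"]
        assert msgs[1].content == "Q0"

    def test_perspectives_are_exact_complements(self):
        turns = self._turns(4)
        pat = relabel_history(turns, "patient", system_prompt="P")
        inter = relabel_history(turns, "interviewer", system_prompt="I")
        swap = {"user": "assistant", "assistant": "user"}
        assert [m.role for m in inter[1:]] == [swap[m.role] for m in pat[1:]]
        assert [m.content for m in inter[1:]] == [m.content for m in pat[1:]]

    def test_empty_history(self):
        msgs = relabel_history([], "patient", system_prompt="P", opener="Q0")
        assert [(m.role, m.content) for m in msgs] == [("system", "P"), ("user", "Q0")]

    def test_non_alternating_history_rejected(self):
        turns = [
            Turn(index=0, speaker="patient", text="a", raw="a"),
            Turn(index=1, speaker="patient", text="b", raw="b"),
        ]
        with pytest.raises(ProtocolError, match="non-alternating"):
            relabel_history(turns, "patient", system_prompt="P")


@pytest.fixture(scope="module")
def compliant(request):
    cfg = request.getfixturevalue("cfg")
    bank = request.getfixturevalue("bank")
    patient = request.getfixturevalue("patient")
    return run_interview(
        patient, bank,
        ScriptedMockBackend(seed=50, vague_rate=0.2),
        ScriptedMockBackend(seed=50),
        seed=50,
    )


class TestRunInterview:
    def test_compliant_run_delivers_every_point_once_in_order(self, compliant, bank):
        assert compliant.status == "compliant"
        assert compliant.delivered_points == list(range(bank.n_points))
        asked = [t.point_index for t in compliant.turns if t.point_index is not None]
        assert asked == sorted(set(asked))

    def test_turns_alternate_starting_with_patient(self, compliant):
        for i, turn in enumerate(compliant.turns):
            assert turn.speaker == ("patient" if i % 2 == 0 else "interviewer")

    def test_notes_count_matches_non_stop_interviewer_turns(self, compliant):
        interviewer_turns = [
            t for t in compliant.turns if t.speaker == "interviewer" and not t.is_stop
        ]
        assert len(compliant.notes) == len(interviewer_turns)

    def test_active_context_stays_under_num_ctx(self, compliant):
        assert 0 < compliant.max_context_estimate <= compliant.options.num_ctx

    def test_clarifications_do_not_duplicate_or_drop_points(self, cfg, bank, patient):
        """Heavy vagueness triggers the clarification loop without breaking
        point conservation."""
        result = run_interview(
            patient, bank,
            ScriptedMockBackend(seed=51, vague_rate=0.6),
            ScriptedMockBackend(seed=51),
            seed=51,
        )
        assert result.status == "compliant"
        assert result.delivered_points == list(range(bank.n_points))
        assert len(result.turns) > 2 * bank.n_points  # clarifications occurred

    def test_no_stop_fault_yields_full_failure(self, cfg, bank, patient):
        result = run_interview(
            patient, bank,
            ScriptedMockBackend(seed=52),
            ScriptedMockBackend(seed=52, faults={"no_stop"}),
            seed=52,
        )
        assert result.status == "full_failure"
        assert result.error is not None

    def test_backend_error_midstream_gives_partial_full_failure(self, cfg, bank, patient):
        from synthintake.backends import BackendError, ChatBackend

        class Flaky(ChatBackend):
            deterministic = True

            def __init__(self):
                self.calls = 0

            def chat(self, messages, options):
                self.calls += 1
                if self.calls > 6:
                    raise BackendError("connection reset")
                return ScriptedMockBackend(seed=1).chat(messages, options)

        result = run_interview(patient, bank, ScriptedMockBackend(seed=1), Flaky(), seed=1)
        assert result.status == "full_failure"
        assert result.turns  # partial transcript retained
        assert "connection reset" in result.error


class TestClassifySession:
    def test_premature_stop_is_full_failure(self, cfg, bank, patient):
        result = run_interview(
            patient, bank,
            ScriptedMockBackend(seed=53),
            ScriptedMockBackend(seed=53, faults={"premature_end"}),
            seed=53,
        )
        assert result.turns[-1].is_stop
        assert result.status == "full_failure"

    def test_leaked_cot_on_otherwise_clean_run_is_soft_failure(self, cfg, bank, patient):
        result = run_interview(
            patient, bank,
            ScriptedMockBackend(seed=54),
            ScriptedMockBackend(seed=54, faults={"leak_cot"}),
            seed=54,
        )
        assert result.status == "soft_failure"
        assert result.delivered_points == list(range(bank.n_points))

    def test_classify_recomputes_from_result(self, compliant):
        assert classify_session(compliant) == "compliant"


class TestSummary:
    def test_mock_summary_contains_every_note(self):
        notes = [
            Note(text=f"digest {i}", section="Medical History", point_index=i) for i in range(3)
        ]
        summary, fallback = compose_summary(notes, None)
        assert not fallback
        assert all(f"digest {i}" in summary for i in range(3))

    def test_empty_notes_fixed_summary(self):
        summary, _ = compose_summary([], None)
        assert summary == "No notes were recorded during this interview."

    def test_deterministic(self):
        notes = [Note(text="a", section="S", point_index=0)]
        assert compose_summary(notes, None) == compose_summary(notes, None)


class TestExport:
    def test_json_roundtrip_and_txt_layout(self, compliant, tmp_path):
        json_path, txt_path = export_transcript(compliant, tmp_path, "s1")
        assert read_transcript(json_path) == compliant
        lines = txt_path.read_text().splitlines()
        expected = 2 + len(compliant.turns) + len(compliant.summary.splitlines())
        assert len(lines) == expected
        assert lines[1].startswith("Interviewer: ")

    def test_status_and_seed_present_in_json(self, compliant, tmp_path):
        json_path, _ = export_transcript(compliant, tmp_path, "s2")
        doc = json.loads(json_path.read_text())
        assert doc["status"] == "compliant"
        assert doc["seed"] == 50

    def test_byte_identical_reexport(self, cfg, bank, patient, tmp_path):
        """(profile, bank, seed) determine the JSON export byte for byte."""
        results = [
            run_interview(
                patient, bank,
                ScriptedMockBackend(seed=55, vague_rate=0.2),
                ScriptedMockBackend(seed=55),
                seed=55,
            )
            for _ in range(2)
        ]
        paths = [export_transcript(r, tmp_path, f"run{i}")[0] for i, r in enumerate(results)]
        b0 = paths[0].read_bytes().replace(b"run0", b"runX")
        b1 = paths[1].read_bytes().replace(b"run1", b"runX")
        assert b0 == b1


class TestChunking:
    def test_tiny_bank_dump_and_preload(self, patient):
        """A two-section bank exercises preloading and context dumping; the
        archived transcript still contains every turn."""
        bank = parse_question_bank(
            "## First\n1. What is your full name?\n2. How would you describe your sleep lately?\n"
            "## Second\n3. What are your main interests or hobbies?\n"
        )
        result = run_interview(
            patient, bank,
            ScriptedMockBackend(seed=60),
            ScriptedMockBackend(seed=60),
            seed=60,
        )
        assert result.status == "compliant"
        assert result.delivered_points == [0, 1, 2]
        assert len(result.turns) == 2 * (bank.n_points + 1)  # answers + questions + opener answer/stop

    def test_max_turns_limit_terminates_as_full_failure(self, bank, patient):
        result = run_interview(
            patient, bank,
            ScriptedMockBackend(seed=61),
            ScriptedMockBackend(seed=61),
            limits=Limits(max_turns=6),
            seed=61,
        )
        assert result.status == "full_failure"
        assert "turn limit" in result.error
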