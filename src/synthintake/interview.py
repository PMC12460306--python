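"""Two-agent interview orchestration.

The engine alternates a patient model and an interview-assistant model around
a strict message protocol: every conversational output begins with
``RESPONSE:``, the assistant additionally emits one structured
``Note: … <END_NOTE>`` block per answered question, and the session ends when
the assistant's response payload is exactly ``<STOP>``.

Context management follows a chunking-and-dumping discipline. The question
bank's sections are loaded one chunk at a time; the next chunk is preloaded
just as the assistant is about to ask the final question of the current one,
and once a chunk is completed its turns are evicted from the active window
and replaced by a brief summary seeded from that chunk's notes. Archived
turns remain in the result, so the exported transcript is always complete.

Role handling: each model sees its own turns labeled ``assistant`` and the
counterpart's labeled ``user``, with its own prompt as the ``system``
message; the labeling under one perspective is the exact user/assistant
mirror of the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

from .backends import (
    NOTE_CLOSE,
    NOTE_OPEN,
    RESPONSE_PREFIX,
    STOP_TOKEN,
    FINAL_SECTION_MARKER,
    BackendError,
    ChatBackend,
    InferenceOptions,
    Message,
    ProtocolError,
    estimate_tokens,
)
from .patients import PatientProfile
from .questionbank import ChunkCursor, QuestionBank

__all__ = [
    "ProtocolTags",
    "Turn",
    "Note",
    "Limits",
    "ParsedOutput",
    "InterviewResult",
    "OPENER",
    "relabel_history",
    "parse_model_output",
    "run_interview",
    "classify_session",
    "compose_summary",
    "export_transcript",
    "read_transcript",
]

_ASSETS = Path(__file__).parent / "assets"

# Hard-coded starting question handed to the patient model before any
# assistant turn exists.
OPENER = "Can you tell me your full name and what brings you in today?"

SUMMARY_TOKEN_BUDGET = 200  # per evicted chunk, in estimated tokens

Speaker = Literal["patient", "interviewer"]
Status = Literal["compliant", "full_failure", "soft_failure"]


@dataclass(frozen=True)
class ProtocolTags:
    response_prefix: str = RESPONSE_PREFIX
    note_open: str = NOTE_OPEN
    note_close: str = NOTE_CLOSE
    stop_token: str = STOP_TOKEN


@dataclass(frozen=True)
class Turn:
    index: int
    speaker: Speaker
    text: str            # final RESPONSE payload
    raw: str             # full completion
    note: str | None = None
    leaked_cot: bool = False
    is_stop: bool = False
    point_index: int | None = None  # global bank index of the point delivered


@dataclass(frozen=True)
class Note:
    text: str
    section: str
    point_index: int | None


@dataclass(frozen=True)
class Limits:
    max_turns: int | None = None          # default: 4 x total points
    max_clarifications_per_point: int = 2

    def resolved_max_turns(self, bank: QuestionBank) -> int:
        return self.max_turns if self.max_turns is not None else 4 * bank.n_points


@dataclass(frozen=True)
class ParsedOutput:
    payload: str
    note: str | None
    is_stop: bool
    leaked_cot: bool


@dataclass
class InterviewResult:
    turns: list[Turn]
    notes: list[Note]
    summary: str
    status: Status
    profile_id: int
    seed: int
    options: InferenceOptions
    bank_titles: tuple[str, ...]
    bank_n_points: int
    delivered_points: list[int]
    opener: str = OPENER
    error: str | None = None
    max_context_estimate: int = 0
    summary_fallback: bool = False


def parse_model_output(raw: str, speaker: Speaker) -> ParsedOutput:
    """Parse one completion against the message protocol.

    The payload is the text after the *last* ``RESPONSE:`` prefix, trimmed.
    A note is extracted between ``Note:`` and ``<END_NOTE>`` for interviewer
    completions. ``leaked_cot`` flags chain-of-thought disclosure: any
    non-whitespace text before the prefix other than a single well-formed
    note block, more than one prefix, or a missing prefix (in which case the
    payload falls back to the full raw text). All anomalies are flags, never
    exceptions.
    """
    if not raw:
        raise ValueError("empty completion cannot be parsed")
    note: str | None = None
    if speaker == "interviewer":
        n_start = raw.find(NOTE_OPEN)
        if n_start >= 0:
            n_end = raw.find(NOTE_CLOSE, n_start)
            if n_end > n_start:
                note = raw[n_start + len(NOTE_OPEN): n_end].strip()

    count = raw.count(RESPONSE_PREFIX)
    if count == 0:
        return ParsedOutput(payload=raw.strip(), note=note, is_stop=False, leaked_cot=True)
    first = raw.find(RESPONSE_PREFIX)
    last = raw.rfind(RESPONSE_PREFIX)
    payload = raw[last + len(RESPONSE_PREFIX):].strip()

    prefix_text = raw[:first]
    if note is not None:
        n_start = prefix_text.find(NOTE_OPEN)
        n_end = prefix_text.find(NOTE_CLOSE, n_start) if n_start >= 0 else -1
        if n_start >= 0 and n_end > n_start:
            prefix_text = prefix_text[:n_start] + prefix_text[n_end + len(NOTE_CLOSE):]
    leaked = bool(prefix_text.strip()) or count > 1
    return ParsedOutput(
        payload=payload,
        note=note,
        is_stop=payload == STOP_TOKEN,
        leaked_cot=leaked,
    )


def relabel_history(
    turns: Sequence[Turn],
    perspective: Speaker,
    system_prompt: str = "",
    opener: str = OPENER,
    include_opener: bool = True,
) -> list[Message]:
    """Relabel a turn history for one model's perspective: its own turns carry
    role ``assistant``, the counterpart's ``user``, preceded by its system
    prompt and (at conversation start) the hard-coded opener. The labeling
    under the opposite perspective is the exact user/assistant swap."""
    for i, turn in enumerate(turns):
        expected: Speaker = "patient" if i % 2 == 0 else "interviewer"
        if turn.speaker != expected and include_opener:
            raise ProtocolError(
                f"non-alternating history: turn {i} spoken by {turn.speaker!r}, "
                f"expected {expected!r}"
            )
    messages = [Message(role="system", content=system_prompt)]
    if include_opener:
        opener_role = "user" if perspective == "patient" else "assistant"
        messages.append(Message(role=opener_role, content=opener))
    for turn in turns:
        role = "assistant" if turn.speaker == perspective else "user"
        messages.append(Message(role=role, content=turn.text))
    return messages


def compose_summary(notes: Sequence[Note], backend: ChatBackend | None = None) -> tuple[str, bool]:
    """Build the end-of-interview summary from the recorded notes.

    With no backend or a deterministic one, the summary is a deterministic
    concatenation of note digests grouped by bank section. A non-deterministic
    backend is prompted instead; on failure the summary falls back to the
    structured note list and the fallback flag is set.
    """
    if not notes:
        return "No notes were recorded during this interview.", False
    if backend is None or backend.deterministic:
        return _local_summary(notes), False
    prompt = (
        "You are the interview assistant. Produce a structured summary of a "
        "completed psychiatric intake interview from the recorded notes below, "
        "grouped by section.\n\n" + _local_summary(notes)
    )
    try:
        text = backend.chat(
            [Message(role="system", content=prompt),
             Message(role="user", content="Write the summary now.")],
            InferenceOptions(),
        ).strip()
        if not text:
            raise BackendError("empty summary")
        return text, False
    except BackendError:
        return "Summary generation failed; structured notes follow.\n" + _local_summary(notes), True


def _local_summary(notes: Sequence[Note]) -> str:
    lines = ["Interview summary:"]
    current = None
    for note in notes:
        if note.section != current:
            current = note.section
            lines.append(f"[{current}]")
        lines.append(f"- {note.text}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _patient_system(profile: PatientProfile) -> str:
    template = (_ASSETS / "prompts" / "patient_prompt.txt").read_text()
    return template.replace(
        "{profile}", json.dumps(profile.to_json_dict(), ensure_ascii=False, sort_keys=True)
    )


def _interviewer_system(
    bank: QuestionBank,
    loaded_sections: Sequence[int],
    summaries: Sequence[str],
    limits: Limits,
) -> str:
    template = (_ASSETS / "prompts" / "interviewer_prompt.txt").read_text()
    lines: list[str] = []
    for sec_idx in loaded_sections:
        section = bank.sections[sec_idx]
        lines.append(f"## {section.title}")
        lines.extend(f"{i + 1}. {p}" for i, p in enumerate(section.points))
    blocks = []
    if summaries:
        blocks.append("Summary of earlier sections:\n" + "\n".join(summaries))
    if loaded_sections and loaded_sections[-1] == len(bank.sections) - 1:
        blocks.append(FINAL_SECTION_MARKER)
    return (
        template
        .replace("{questions}", "\n".join(lines))
        .replace("{summary_block}", ("\n" + "\n".join(blocks) + "\n") if blocks else "")
        .replace("{max_clarifications}", str(limits.max_clarifications_per_point))
    )


def _loaded_sections(cursor: ChunkCursor, bank: QuestionBank) -> list[int]:
    """Active question chunks for the next assistant call: the section of the
    next expected point, plus the following section when the next point is the
    section-final one (preemptive chunk loading)."""
    if cursor.exhausted:
        return [len(bank.sections) - 1]
    _, boundary = cursor.peek()
    sections = [cursor.current_section]
    if boundary and cursor.current_section + 1 < len(bank.sections):
        sections.append(cursor.current_section + 1)
    return sections


def _truncate_tokens(text: str, budget: int) -> str:
    words = text.split()
    while words and estimate_tokens(" ".join(words)) > budget:
        words = words[: max(1, int(len(words) * 0.9) - 1)]
        if len(words) == 1 and estimate_tokens(words[0]) > budget:
            break
    return " ".join(words)


def run_interview(
    profile: PatientProfile,
    bank: QuestionBank,
    patient_backend: ChatBackend,
    interviewer_backend: ChatBackend,
    options: InferenceOptions | None = None,
    limits: Limits | None = None,
    seed: int = 0,
) -> InterviewResult:
    """Run one structured interview to completion.

    The patient answers the hard-coded opener first; thereafter patient
    answers and assistant turns strictly alternate until the assistant's
    payload is exactly the stop token, the turn limit is reached, or a
    backend fails (which yields a partial transcript classified as a full
    failure). Chunk eviction replaces completed sections in the active
    window with a note-seeded summary; evicted turns remain in the result.
    """
    options = options or InferenceOptions()
    limits = limits or Limits()
    max_turns = limits.resolved_max_turns(bank)
    cursor = ChunkCursor(bank)
    patient_system = _patient_system(profile)

    turns: list[Turn] = []
    notes: list[Note] = []
    delivered: list[int] = []
    chunk_summaries: list[str] = []
    active_start = 0          # index into turns of the first active turn
    notes_start_of_section = 0
    dumped_through_section = -1
    post_exhaustion_turns = 0
    max_ctx = 0
    error: str | None = None
    ended_with_stop = False

    while True:
        if len(turns) >= max_turns:
            error = f"turn limit {max_turns} reached without stop token"
            break
        patient_move = not turns or turns[-1].speaker == "interviewer"
        if patient_move:
            messages = relabel_history(
                turns[active_start:],
                "patient",
                system_prompt=patient_system,
                include_opener=active_start == 0,
            )
            max_ctx = max(max_ctx, sum(estimate_tokens(m.content) for m in messages))
            try:
                raw = patient_backend.chat(messages, options)
            except (BackendError, ProtocolError) as exc:
                error = f"patient backend failed at turn {len(turns)}: {exc}"
                break
            parsed = parse_model_output(raw, "patient")
            turns.append(
                Turn(
                    index=len(turns),
                    speaker="patient",
                    text=parsed.payload,
                    raw=raw,
                    leaked_cot=parsed.leaked_cot,
                )
            )
            continue

        # interviewer move
        loaded = _loaded_sections(cursor, bank)
        system = _interviewer_system(bank, loaded, chunk_summaries, limits)
        messages = relabel_history(
            turns[active_start:],
            "interviewer",
            system_prompt=system,
            include_opener=active_start == 0,
        )
        max_ctx = max(max_ctx, sum(estimate_tokens(m.content) for m in messages))
        try:
            raw = interviewer_backend.chat(messages, options)
        except (BackendError, ProtocolError) as exc:
            error = f"interviewer backend failed at turn {len(turns)}: {exc}"
            break
        parsed = parse_model_output(raw, "interviewer")

        point_index: int | None = None
        if not parsed.is_stop and not cursor.exhausted:
            next_point, _ = cursor.peek()
            if next_point in parsed.payload:
                section_of_point = cursor.current_section
                global_index = len(delivered)
                cursor.advance()
                point_index = global_index
                delivered.append(global_index)
                # Chunk completed: evict its turns from the active window and
                # seed a summary from its notes.
                if section_of_point > 0 and dumped_through_section < section_of_point - 1:
                    evicted_notes = notes[notes_start_of_section:]
                    summary_text = "; ".join(n.text for n in evicted_notes)
                    title = bank.sections[section_of_point - 1].title
                    chunk_summaries.append(
                        _truncate_tokens(f"[{title}] {summary_text}", SUMMARY_TOKEN_BUDGET)
                    )
                    dumped_through_section = section_of_point - 1
                    active_start = len(turns)  # keep only this new assistant turn onward
                    notes_start_of_section = len(notes)

        if parsed.note is not None and not parsed.is_stop:
            if point_index is not None:
                note_section = bank.sections[
                    _section_of_global_index(bank, point_index)
                ].title
            elif delivered:
                note_section = bank.sections[
                    _section_of_global_index(bank, delivered[-1])
                ].title
            else:
                note_section = bank.sections[0].title
            notes.append(Note(text=parsed.note, section=note_section, point_index=point_index))

        turns.append(
            Turn(
                index=len(turns),
                speaker="interviewer",
                text=parsed.payload,
                raw=raw,
                note=parsed.note,
                leaked_cot=parsed.leaked_cot,
                is_stop=parsed.is_stop,
                point_index=point_index,
            )
        )

        if parsed.is_stop:
            ended_with_stop = True
            break
        if cursor.exhausted and point_index is None:
            post_exhaustion_turns += 1
            # After the bank is exhausted the assistant may still clarify the
            # final answer, but must stop within the clarification budget.
            if post_exhaustion_turns > limits.max_clarifications_per_point:
                error = "assistant failed to emit the stop token after the final question"
                break

    summary, fallback = compose_summary(notes, interviewer_backend)
    result = InterviewResult(
        turns=turns,
        notes=notes,
        summary=summary,
        status="compliant",  # provisional; classified below
        profile_id=profile.patient_id,
        seed=seed,
        options=options,
        bank_titles=bank.titles,
        bank_n_points=bank.n_points,
        delivered_points=delivered,
        error=error,
        max_context_estimate=max_ctx,
        summary_fallback=fallback,
    )
    result.status = classify_session(result, ended_with_stop=ended_with_stop)
    return result


def _section_of_global_index(bank: QuestionBank, idx: int) -> int:
    for s, section in enumerate(bank.sections):
        if idx < len(section.points):
            return s
        idx -= len(section.points)
    raise IndexError(idx)


def classify_session(result: InterviewResult, ended_with_stop: bool | None = None) -> Status:
    """Prompt-adherence classification.

    Full failure: the session never terminated with the stop token, or points
    remained undelivered at termination (premature end), or a backend error
    cut the session short. Soft failure: any turn leaked chain-of-thought.
    Otherwise compliant.
    """
    if ended_with_stop is None:
        ended_with_stop = bool(result.turns) and result.turns[-1].is_stop
    if result.error is not None or not ended_with_stop:
        return "full_failure"
    if len(result.delivered_points) < result.bank_n_points:
        return "full_failure"
    if any(turn.leaked_cot for turn in result.turns):
        return "soft_failure"
    return "compliant"


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def _result_to_dict(result: InterviewResult, session_id: str) -> dict:
    return {
        "schema_version": 1,
        "id": session_id,
        "seed": result.seed,
        "profile_id": result.profile_id,
        "status": result.status,
        "opener": result.opener,
        "options": result.options.model_dump(),
        "bank": {"titles": list(result.bank_titles), "n_points": result.bank_n_points},
        "turns": [
            {
                "index": t.index,
                "speaker": t.speaker,
                "text": t.text,
                "raw": t.raw,
                "note": t.note,
                "leaked_cot": t.leaked_cot,
                "is_stop": t.is_stop,
                "point_index": t.point_index,
            }
            for t in result.turns
        ],
        "notes": [
            {"text": n.text, "section": n.section, "point_index": n.point_index}
            for n in result.notes
        ],
        "summary": result.summary,
        "summary_fallback": result.summary_fallback,
        "delivered_points": list(result.delivered_points),
        "error": result.error,
        "max_context_estimate": result.max_context_estimate,
    }


def export_transcript(result: InterviewResult, out_dir: str | Path, session_id: str | None = None) -> tuple[Path, Path]:
    """Write ``<id>.json`` (full schema, machine-readable) and ``<id>.txt``
    (human-readable) exports.

    TXT layout: line 1 is the session header, line 2 the opener
    (``Interviewer: …``), then one line per turn, then the summary's lines —
    so the file has exactly ``2 + len(turns) + summary line count`` lines.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    session_id = session_id or f"session_{result.profile_id:04d}_seed{result.seed}"
    json_path = out_dir / f"{session_id}.json"
    txt_path = out_dir / f"{session_id}.txt"
    json_path.write_text(
        json.dumps(_result_to_dict(result, session_id), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    lines = [f"Session {session_id} | status: {result.status} | seed: {result.seed}"]
    lines.append(f"Interviewer: {result.opener}")
    for turn in result.turns:
        speaker = "Patient" if turn.speaker == "patient" else "Interviewer"
        lines.append(f"{speaker}: {' '.join(turn.text.splitlines())}")
    lines.extend(result.summary.splitlines())
    txt_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return json_path, txt_path


def read_transcript(path: str | Path) -> InterviewResult:
    """Read a JSON export back into an :class:`InterviewResult` (exact inverse
    of the export, minus the session id)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return InterviewResult(
        turns=[
            Turn(
                index=t["index"],
                speaker=t["speaker"],
                text=t["text"],
                raw=t["raw"],
                note=t["note"],
                leaked_cot=t["leaked_cot"],
                is_stop=t["is_stop"],
                point_index=t["point_index"],
            )
            for t in doc["turns"]
        ],
        notes=[Note(text=n["text"], section=n["section"], point_index=n["point_index"]) for n in doc["notes"]],
        summary=doc["summary"],
        status=doc["status"],
        profile_id=doc["profile_id"],
        seed=doc["seed"],
        options=InferenceOptions(**doc["options"]),
        bank_titles=tuple(doc["bank"]["titles"]),
        bank_n_points=doc["bank"]["n_points"],
        delivered_points=list(doc["delivered_points"]),
        opener=doc["opener"],
        error=doc["error"],
        max_context_estimate=doc["max_context_estimate"],
        summary_fallback=doc.get("summary_fallback", False),
    )
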