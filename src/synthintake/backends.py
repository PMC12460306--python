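"""Chat-completion backends: the message/options contract, a deterministic
scripted mock covering every role the pipeline calls (template authoring,
narrative enrichment, patient, interview assistant), and an HTTP adapter for
an Ollama-compatible server.

The mock is a pure function of ``(messages, seed)`` plus its configured fault
flags, which exist solely to exercise failure classification downstream:

* ``no_stop`` — the interviewer never emits the ``<STOP>`` token;
* ``premature_end`` — the interviewer emits ``<STOP>`` after only a few points;
* ``leak_cot`` — the interviewer prefixes its step-by-step reasoning to every
  completion instead of emitting only the note block and final response;
* ``patient_leak_cot`` — same leak, on the patient side.

Sampling parameters (temperature, top-k, top-p, context size) are forwarded
options, not implemented decoders; the mock ignores all but ``num_ctx`` and
the HTTP adapter forwards them verbatim.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
import urllib.error
import urllib.request
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Iterable, Sequence

from pydantic import BaseModel, ConfigDict, field_validator

from .questionbank import parse_question_bank

__all__ = [
    "Message",
    "InferenceOptions",
    "ChatBackend",
    "ScriptedMockBackend",
    "OllamaBackend",
    "ProtocolError",
    "BackendError",
    "estimate_tokens",
    "RESPONSE_PREFIX",
    "NOTE_OPEN",
    "NOTE_CLOSE",
    "STOP_TOKEN",
]

# Literal, case-sensitive protocol tags exchanged between the two agents.
RESPONSE_PREFIX = "RESPONSE:"
NOTE_OPEN = "Note:"
NOTE_CLOSE = "<END_NOTE>"
STOP_TOKEN = "<STOP>"

ROLES = ("system", "user", "assistant")

CLARIFY_PHRASES = (
    "Could you tell me a little more about that?",
    "I want to make sure I understand — could you expand on that a bit?",
    "Would you mind giving me a few more details?",
)
ACK_PHRASES = (
    "Thank you for sharing that.",
    "I appreciate you telling me.",
    "That is helpful to know, thank you.",
    "Thank you, that gives me a clearer picture.",
    "I understand, thank you for being open about it.",
)
VAGUE_MARKERS = ("not sure", "hard to say", "i guess", "maybe")

FINAL_SECTION_MARKER = "FINAL_SECTION: true"
_ENUM_RE = re.compile(r"^\s*\d+[.)]\s+")
_MAXCLAR_RE = re.compile(r"MAX_CLARIFICATIONS:\s*(\d+)")


class ProtocolError(ValueError):
    """Malformed message sequence passed to a backend."""


class BackendError(RuntimeError):
    """A backend failed to produce a completion."""


@dataclass(frozen=True)
class Message:
    role: str
    content: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ProtocolError(f"unknown message role {self.role!r}; expected one of {ROLES}")
        if self.content is None:
            raise ProtocolError("message content must not be null")


class InferenceOptions(BaseModel):
    """Decoding options forwarded to the inference server.

    Defaults balance prompt adherence with conversational variability:
    temperature 0.9 with nucleus sampling at top_p 0.9 and a top_k of 40,
    inside a 6,144-token context window managed by chunking-and-dumping.
    """

    model_config = ConfigDict(frozen=True)

    temperature: float = 0.9
    top_k: int = 40
    top_p: float = 0.9
    num_ctx: int = 6144

    @field_validator("temperature")
    @classmethod
    def _t(cls, v: float) -> float:
        if v < 0:
            raise ValueError("temperature must be >= 0")
        return v

    @field_validator("top_p")
    @classmethod
    def _p(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("top_p must be in (0, 1]")
        return v

    @field_validator("top_k")
    @classmethod
    def _k(cls, v: int) -> int:
        if v < 1:
            raise ValueError("top_k must be >= 1")
        return v

    @field_validator("num_ctx")
    @classmethod
    def _c(cls, v: int) -> int:
        if v < 1024:
            raise ValueError("num_ctx must be >= 1024")
        return v


def estimate_tokens(text: str) -> int:
    """Heuristic token count: whitespace tokens times 1.3, rounded up.

    Deterministic, non-negative, and monotone under concatenation
    (``estimate_tokens(a + b) >= max(estimate_tokens(a), estimate_tokens(b))``).
    A whitespace heuristic is used because token counting is otherwise a
    property of the serving model's tokenizer.
    """
    n = len(text.split())
    return math.ceil(n * 1.3)


def validate_sequence(messages: Sequence[Message]) -> None:
    """Enforce the chat precondition: one leading system message, then strictly
    alternating user/assistant roles."""
    if not messages:
        raise ProtocolError("empty message list")
    if messages[0].role != "system":
        raise ProtocolError(f"first message must be system, got {messages[0].role!r}")
    prev = None
    for i, msg in enumerate(messages[1:], start=1):
        if msg.role == "system":
            raise ProtocolError(f"unexpected system message at position {i}")
        if msg.role == prev:
            raise ProtocolError(
                f"protocol error: two consecutive {msg.role!r} messages at position {i}"
            )
        prev = msg.role


def _stable_int(*parts: object) -> int:
    blob = "\x1f".join(str(p) for p in parts).encode("utf-8")
    return int.from_bytes(hashlib.blake2b(blob, digest_size=8).digest(), "big")


def _pick(options: Sequence[str], *key: object) -> str:
    return options[_stable_int(*key) % len(options)]


class ChatBackend(ABC):
    """Contract shared by the mock and the HTTP adapter."""

    backend_id: str = "backend"
    deterministic: bool = False

    @abstractmethod
    def chat(self, messages: Sequence[Message], options: InferenceOptions) -> str:
        """Return a non-empty completion for a valid message sequence."""


# ---------------------------------------------------------------------------
# scripted mock
# ---------------------------------------------------------------------------


class ScriptedMockBackend(ChatBackend):
    """Deterministic scripted stand-in for the chat model, for offline runs
    and testing. Dispatches on markers in the system message:

    * ``[TEMPLATE TASK]`` — emits a profile template covering every section
      of the embedded question bank, one field per point;
    * ``[NARRATIVE TASK]`` — emits a short narrative paragraph, a pure
      function of the target field and the profile's fixed attributes;
    * ``<PATIENT_INFO>`` — answers the latest interviewer question from the
      embedded profile, with an optional seeded vague-answer mode that
      exercises the clarification path;
    * ``<QUESTIONS>`` — plays the interview assistant: one note block plus
      one acknowledgment-and-question response per turn, ``<STOP>`` when the
      final question of the final section has been answered.
    """

    deterministic = True

    def __init__(
        self,
        seed: int = 0,
        faults: Iterable[str] = (),
        vague_rate: float = 0.0,
    ) -> None:
        self.seed = int(seed)
        self.faults = frozenset(faults)
        unknown = self.faults - {"no_stop", "premature_end", "leak_cot", "patient_leak_cot"}
        if unknown:
            raise ValueError(f"unknown fault flags: {sorted(unknown)}")
        self.vague_rate = float(vague_rate)
        self.backend_id = f"mock(seed={self.seed})"

    # -- dispatch -----------------------------------------------------------

    def chat(self, messages: Sequence[Message], options: InferenceOptions) -> str:
        validate_sequence(messages)
        system = messages[0].content
        if "[TEMPLATE TASK]" in system:
            return self._template(system)
        if "[NARRATIVE TASK]" in system:
            return self._narrative(system)
        if "<PATIENT_INFO>" in system:
            return self._patient(system, messages)
        if "<QUESTIONS>" in system:
            return self._interviewer(system, messages)
        raise BackendError(f"[{self.backend_id}] system prompt matches no scripted role")

    # -- template authoring --------------------------------------------------

    FIXED_KEYWORDS = (
        "name", "date of birth", "age", "live", "work", "ethnicity",
        "relationship status", "children", "disability", "brings you in",
        "diagnosed", "medications", "supplements", "allergies", "substances",
    )

    def _template(self, system: str) -> str:
        bank_text = _between(system, "<QUESTION_BANK>", "</QUESTION_BANK>")
        if bank_text is None:
            raise BackendError(f"[{self.backend_id}] template task without question bank")
        bank = parse_question_bank(bank_text)
        fields = []
        seen: set[str] = set()
        for section in bank.sections:
            for point in section.points:
                fid = _slug(point)
                while fid in seen:
                    fid += "_x"
                seen.add(fid)
                lower = point.lower()
                kind = "fixed" if any(k in lower for k in self.FIXED_KEYWORDS) else "narrative"
                fields.append(
                    {
                        "field_id": fid,
                        "section": section.title,
                        "kind": kind,
                        "prompt_hint": point,
                    }
                )
        return json.dumps({"fields": fields}, indent=2)

    # -- narrative enrichment ------------------------------------------------

    NARRATIVE_TEMPLATES = {
        "family_social_history": (
            "{name} grew up in {city} and stays in {contact} contact with family. "
            "{name} describes the household growing up as {tone}, and currently "
            "leans on {support} for day-to-day support.",
            "{name} was raised mostly in {city}; family relationships are {tone}. "
            "These days {name} keeps in {contact} touch with relatives and counts "
            "on {support} when things get difficult.",
        ),
        "health_injury_history": (
            "{name} reports {injury} in the past and no major surgeries. General "
            "health is otherwise {health}, with routine checkups {checkups}.",
            "Aside from {injury} some years ago, {name} has had an otherwise "
            "{health} medical course; checkups happen {checkups}.",
        ),
        "interests": (
            "{name} enjoys {hobby1} and {hobby2}, and tries to make time for "
            "them most weeks despite work as a {occupation}.",
            "Main interests for {name} are {hobby1} and {hobby2}; work as a "
            "{occupation} leaves limited but protected time for both.",
        ),
        "daily_lifestyle": (
            "A typical day for {name} starts {start}, centres on work as a "
            "{occupation}, and winds down with {wind_down} in the evening.",
            "{name} usually wakes {start}, spends the day working as a "
            "{occupation}, and ends the day with {wind_down}.",
        ),
        "children_details": (
            "{name} has {kidcount} at home; parenting is described as demanding "
            "but grounding, and routines are built around school hours.",
            "{name} is a parent of {kidcount}; much of the week is organised "
            "around the children's school and activities.",
        ),
    }
    _SLOTS = {
        "contact": ("regular", "occasional", "close"),
        "tone": ("warm but strict", "loving if chaotic", "quiet and reserved", "supportive"),
        "support": ("a close friend", "a sibling", "their partner", "a small circle of friends"),
        "injury": ("a minor sports injury", "a broken wrist", "a concussion", "no notable injuries"),
        "health": ("good", "fair", "stable"),
        "checkups": ("yearly", "sporadically", "regularly"),
        "hobby1": ("hiking", "reading", "cooking", "photography", "swimming"),
        "hobby2": ("board games", "gardening", "cycling", "painting", "music"),
        "start": ("early, around six", "around seven thirty", "slowly, closer to nine"),
        "wind_down": ("a walk and some television", "reading in bed", "video calls with friends"),
        "kidcount": ("one child", "two children"),
    }

    def _narrative(self, system: str) -> str:
        m = re.search(r"NARRATIVE_FIELD:\s*(\S+)", system)
        if not m:
            raise BackendError(f"[{self.backend_id}] narrative task without field id")
        field_id = m.group(1)
        profile_text = _between(system, "<PROFILE_SO_FAR>", "</PROFILE_SO_FAR>") or "{}"
        profile = json.loads(profile_text)
        identity = profile.get("identity", {})
        name = (identity.get("name") or "The patient").split()[0]
        occupation = identity.get("occupation", "their current job")
        # Variant and slot choices hash over the *non-name* fixed fields so two
        # profiles differing only by name get narratives differing only where
        # the name is interpolated.
        fixed_key = json.dumps(
            {
                "demographics": profile.get("demographics"),
                "relationship_status": profile.get("relationship_status"),
                "conditions": profile.get("conditions"),
                "attributes": profile.get("attributes"),
                "occupation": occupation,
            },
            sort_keys=True,
        )
        templates = self.NARRATIVE_TEMPLATES.get(
            field_id,
            ("{name} has nothing unusual to report for this area of life.",),
        )
        template = _pick(templates, self.seed, field_id, fixed_key)
        slots = {
            slot: _pick(values, self.seed, field_id, slot, fixed_key)
            for slot, values in self._SLOTS.items()
        }
        city = "the area where they still live"
        address = identity.get("address", "")
        if "," in address:
            city = address.rsplit(",", 1)[-1].strip()
        return template.format(name=name, occupation=occupation, city=city, **slots)

    # -- patient role --------------------------------------------------------

    def _patient(self, system: str, messages: Sequence[Message]) -> str:
        profile_text = _between(system, "<PATIENT_INFO>", "</PATIENT_INFO>")
        if profile_text is None:
            raise BackendError(f"[{self.backend_id}] patient prompt without profile block")
        profile = json.loads(profile_text)
        if messages[-1].role != "user":
            raise ProtocolError("patient backend expects the interviewer question last")
        question = messages[-1].content
        is_clarification = any(phrase in question for phrase in CLARIFY_PHRASES)
        if is_clarification:
            # Find the substantive question being clarified.
            target = question
            for msg in reversed(messages[1:-1]):
                if msg.role == "user" and not any(p in msg.content for p in CLARIFY_PHRASES):
                    target = msg.content
                    break
            body = self._patient_answer(profile, target, detailed=True)
        else:
            vague = (
                self.vague_rate > 0
                and (_stable_int(self.seed, "vague", question) % 10_000) / 10_000
                < self.vague_rate
            )
            if vague:
                body = _pick(
                    (
                        "I'm not sure, maybe... it's hard to say.",
                        "I guess so? I'm not sure how to put it.",
                        "Hmm, hard to say really. Maybe a bit.",
                    ),
                    self.seed, "vague-text", question,
                )
            else:
                body = self._patient_answer(profile, question, detailed=False)
        out = f"{RESPONSE_PREFIX} {body}"
        if "patient_leak_cot" in self.faults:
            out = (
                "Step 1: The most recent question was about my situation. "
                "Step 2: I recall the relevant profile details. "
                "Step 3: I compose a brief answer.\n" + out
            )
        return out

    def _patient_answer(self, profile: dict, question: str, detailed: bool) -> str:
        identity = profile.get("identity", {})
        demo = profile.get("demographics", {})
        attrs = profile.get("attributes", {})
        narrative = {
            k: (v.get("text", "") if isinstance(v, dict) else str(v))
            for k, v in profile.get("narrative", {}).items()
        }
        q = question.lower()
        name = identity.get("name", "")
        first = name.split()[0] if name else "me"

        def conditions_phrase() -> str:
            conds = profile.get("conditions", [])
            if not conds:
                return "I've never actually been given a diagnosis"
            return "; ".join(
                f"{c['condition']}, for which I take {c['medication']}" for c in conds
            )

        rules: list[tuple[tuple[str, ...], str]] = [
            (("full name", "your name"), f"My name is {name}, and {first} is fine."),
            (("date of birth",), f"I was born on {identity.get('date_of_birth', '')}, so I'm {demo.get('age', '')} now."),
            (("where do you currently live", "who lives with you"), f"I live at {identity.get('address', '')}."),
            (("work", "occupation"), f"I work as a {identity.get('occupation', '')}; it's been a few years now."),
            (("ethnicity", "cultural background"), f"My background is {demo.get('ethnicity', '')}."),
            (("relationship status",), f"I'm {_article_free(profile.get('relationship_status', ''))} at the moment."),
            (("children",), self._children_answer(profile, narrative)),
            (("disability", "long-term condition"), self._disability_answer(profile)),
            (("brings you in", "reason for this visit"), f"Mainly {attrs.get('visit_reason', 'I just wanted to talk to someone')}."),
            (("diagnosed", "mental health condition"), f"Yes — {conditions_phrase()}."),
            (("currently taking any psychiatric medications",), self._meds_answer(profile)),
            (("medications in the past",), "There was one earlier medication that we stopped because it didn't sit well with me."),
            (("supplements", "vitamins"), f"Just {attrs.get('supplements', 'nothing regular')}."),
            (("allergies",), f"Allergies — {attrs.get('allergies', 'none that I know of')}."),
            (("hospitalized",), "No, I've never been hospitalized for my mental health."),
            (("harming yourself",), "I've had some dark moments, but nothing recent and no plans; I want to be clear about that."),
            (("medical conditions", "injuries", "surgeries"), narrative.get("health_injury_history", "Nothing major, a few scrapes over the years.")),
            (("sleep",), "Sleep has been rough lately — I wake up a few times most nights and feel unrested."),
            (("appetite", "weight"), "My appetite has dipped a little these past months; my weight is more or less stable."),
            (("alcohol", "tobacco", "cannabis", "recreational"), f"As for substances, {attrs.get('recreational_drugs', 'nothing really')}."),
            (("parents living",), "My parents are both around; we talk, though it can be complicated."),
            (("siblings",), "I have a sibling; we get along fine, mostly birthdays and holidays."),
            (("mental illness in your family",), "There's some history on one side of the family — mood problems, mostly, never formally treated."),
            (("substance use problems in your family",), "An uncle struggled with drinking, but it was rarely discussed openly."),
            (("conditions that run in your family",), "Heart disease runs in the family on my father's side."),
            (("closest to",), narrative.get("family_social_history", "Probably a close friend I've known for years.")),
            (("growing up", "disruptions in your family"), "We moved around a bit when I was young, which was disruptive, but nothing dramatic beyond that."),
            (("family situation now",), "Things at home are mostly calm, though money and schedules cause friction sometimes."),
            (("where were you born",), narrative.get("family_social_history", "I was born locally and grew up nearby.")),
            (("childhood",), "My childhood was ordinary on the surface, though I was an anxious kid."),
            (("school",), "I finished high school and did some college; school was okay academically, harder socially."),
            (("work history",), f"I've mostly worked steadily — these days as a {identity.get('occupation', '')}, with a couple of job changes before that."),
            (("past marriages", "significant relationships"), "There was one long relationship in my past that mattered a lot."),
            (("relationships ended",), "It ended mostly because we wanted different things; it was sad but not bitter."),
            (("typical day",), narrative.get("daily_lifestyle", "Work, errands, a quiet evening — fairly routine.")),
            (("relax", "manage stress"), "To unwind I usually walk, listen to music, or just take quiet time alone."),
            (("interests", "hobbies"), narrative.get("interests", "I like reading and being outdoors when I can.")),
            (("social life", "friendships"), "My social circle is small but solid — a handful of people I trust."),
            (("traumatic", "distressing events"), "There was a period a few years ago I'd call genuinely distressing; I can talk about it if it's relevant."),
            (("legal problems", "courts"), "No legal trouble, nothing beyond a parking ticket."),
            (("financially",), "Finances are tight some months, but I'm managing."),
            (("goals", "hopes"), "I'd like to feel steadier, and maybe take on more at work once I do."),
            (("worried about regarding treatment",), "I worry a little about side effects, mainly."),
            (("help with",), "Mostly I want help getting my mood and sleep back on track."),
            (("questions for me",), "Not right now — maybe once I've thought things over."),
            (("anything else", "not covered", "before we finish"), "No, I think we've covered everything that matters for now."),
        ]
        for keys, answer in rules:
            if any(k in q for k in keys):
                body = answer
                break
        else:
            topic = " ".join(w for w in re.findall(r"[a-z']+", q) if len(w) > 3)[:60]
            body = f"Honestly, about {topic or 'that'} — nothing stands out that I haven't already mentioned."
        if detailed:
            body += " " + _pick(
                (
                    "To be more specific, it started around three months ago and comes up most days.",
                    "If I had to put numbers on it, I'd say it happens several times a week and has for a few months.",
                    "Looking back, it became noticeable earlier this year and has slowly worn me down.",
                ),
                self.seed, "detail", question,
            )
        return body

    @staticmethod
    def _children_answer(profile: dict, narrative: dict) -> str:
        if profile.get("has_children"):
            extra = narrative.get("children_details", "")
            return ("Yes, I have children. " + extra).strip()
        return "No, I don't have any children."

    @staticmethod
    def _disability_answer(profile: dict) -> str:
        disabilities = profile.get("disabilities", [])
        if disabilities:
            return (
                f"I do — I'd describe it as a {', '.join(d.lower() for d in disabilities)} "
                "difficulty that affects my day-to-day."
            )
        return "No, nothing I'd call a disability."

    @staticmethod
    def _meds_answer(profile: dict) -> str:
        conds = profile.get("conditions", [])
        if not conds:
            return "No, I'm not on any psychiatric medication right now."
        meds = ", ".join(c["medication"] for c in conds)
        return f"Yes — currently {meds}."

    # -- interview assistant role -------------------------------------------

    def _interviewer(self, system: str, messages: Sequence[Message]) -> str:
        block = _between(system, "<QUESTIONS>", "</QUESTIONS>")
        if block is None:
            raise BackendError(f"[{self.backend_id}] interviewer prompt without questions block")
        points = [
            _ENUM_RE.sub("", line.strip())
            for line in block.splitlines()
            if line.strip() and not line.strip().startswith("##")
        ]
        final_section = FINAL_SECTION_MARKER in system
        m = _MAXCLAR_RE.search(system)
        max_clar = int(m.group(1)) if m else 2
        if messages[-1].role != "user":
            raise ProtocolError("interviewer backend expects the patient answer last")
        last_answer = messages[-1].content

        # Highest-index point already asked within the active history, and the
        # number of clarification turns issued since then.
        asked = -1
        asked_pos = -1
        clar_since = 0
        for pos, msg in enumerate(messages[1:], start=1):
            if msg.role != "assistant":
                continue
            for idx, point in enumerate(points):
                if point and point in msg.content and idx > asked:
                    asked, asked_pos = idx, pos
        for pos, msg in enumerate(messages[1:], start=1):
            if msg.role == "assistant" and pos > asked_pos and any(
                p in msg.content for p in CLARIFY_PHRASES
            ):
                clar_since += 1

        note = f"{NOTE_OPEN} {_digest(last_answer)} {NOTE_CLOSE}"
        prefix = ""
        if "leak_cot" in self.faults:
            prefix = (
                "Step 1: The previous question has been identified. "
                "Step 2: I summarize the patient's latest answer. "
                "Step 3: I assess completeness against clarity, detail, and relevance.\n"
            )

        vague = any(marker in last_answer.lower() for marker in VAGUE_MARKERS)
        if asked >= 0 and vague and clar_since < max_clar:
            phrase = _pick(CLARIFY_PHRASES, self.seed, "clarify", asked, clar_since)
            return f"{prefix}{note}\n{RESPONSE_PREFIX} {phrase}"

        if asked >= len(points) - 1:
            if final_section and "no_stop" not in self.faults:
                return f"{prefix}{RESPONSE_PREFIX} {STOP_TOKEN}"
            return (
                f"{prefix}{note}\n{RESPONSE_PREFIX} Thank you so much for your time "
                "today; that concludes our interview."
            )
        if "premature_end" in self.faults and asked >= 2:
            return f"{prefix}{RESPONSE_PREFIX} {STOP_TOKEN}"
        ack = _pick(ACK_PHRASES, self.seed, "ack", asked + 1, last_answer)
        return f"{prefix}{note}\n{RESPONSE_PREFIX} {ack} {points[asked + 1]}"


def _digest(answer: str, max_words: int = 14) -> str:
    words = answer.split()
    clipped = " ".join(words[:max_words])
    if len(words) > max_words:
        clipped += "…"
    return clipped


def _between(text: str, open_tag: str, close_tag: str) -> str | None:
    start = text.find(open_tag)
    if start < 0:
        return None
    start += len(open_tag)
    end = text.find(close_tag, start)
    if end < 0:
        return None
    return text[start:end].strip()


def _slug(point: str, max_words: int = 6) -> str:
    words = re.findall(r"[a-z0-9]+", point.lower())
    return "_".join(words[:max_words]) or "point"


def _article_free(status: str) -> str:
    return status.lower() if status else "single"


# ---------------------------------------------------------------------------
# HTTP adapter
# ---------------------------------------------------------------------------


class OllamaBackend(ChatBackend):
    """Adapter for an Ollama-compatible chat endpoint.

    POSTs ``{model, messages[{role, content}], stream: false, options{...}}``
    to ``<base_url>/api/chat`` and returns ``message.content`` from the JSON
    reply. Options are forwarded verbatim; connection problems surface as
    :class:`BackendError` carrying the backend id.
    """

    deterministic = False

    def __init__(self, base_url: str, model: str, timeout: float = 300.0) -> None:
        self.base_url = base_url.rstrip("/")
        self.model = model
        self.timeout = timeout
        self.backend_id = f"ollama({model}@{self.base_url})"

    def chat(self, messages: Sequence[Message], options: InferenceOptions) -> str:
        validate_sequence(messages)
        body = json.dumps(
            {
                "model": self.model,
                "messages": [{"role": m.role, "content": m.content} for m in messages],
                "stream": False,
                "options": {
                    "temperature": options.temperature,
                    "top_k": options.top_k,
                    "top_p": options.top_p,
                    "num_ctx": options.num_ctx,
                },
            }
        ).encode("utf-8")
        request = urllib.request.Request(
            f"{self.base_url}/api/chat",
            data=body,
            headers={"Content-Type": "application/json"},
            method="POST",
        )
        try:
            with urllib.request.urlopen(request, timeout=self.timeout) as resp:
                payload = json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, TimeoutError, OSError) as exc:
            raise BackendError(f"[{self.backend_id}] request failed: {exc}") from exc
        try:
            content = payload["message"]["content"]
        except (KeyError, TypeError) as exc:
            raise BackendError(f"[{self.backend_id}] malformed reply: {payload!r}") from exc
        if not content:
            raise BackendError(f"[{self.backend_id}] empty completion")
        return content
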