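"""Header-structured question bank: parsing into ordered sections ("chunks")
and cursor-based delivery with chunk-boundary flags.

A bank file is plain text. A line starting with ``##`` (or, when enabled, an
ALL-CAPS line) opens a new section; every other non-blank line is one
question point. Points may carry a leading ``N.`` enumeration, which is
stripped on parse and regenerated (globally numbered) on serialization. The
packaged fixture covers a full psychiatric intake: five sections —
General Information, Medical History, Family History, Personal History,
Additional Comments — totalling 47 points, including explicit follow-up
points and a final interview-closing point.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Section",
    "QuestionBank",
    "ChunkCursor",
    "QuestionBankError",
    "parse_question_bank",
    "load_question_bank",
    "packaged_bank_path",
]

_ENUM_RE = re.compile(r"^\s*\d+[.)]\s+")


class QuestionBankError(ValueError):
    """Raised on malformed question-bank text or cursor misuse."""


@dataclass(frozen=True)
class Section:
    title: str
    points: tuple[str, ...]


@dataclass(frozen=True)
class QuestionBank:
    sections: tuple[Section, ...]

    def __post_init__(self) -> None:
        titles = [s.title for s in self.sections]
        if len(set(titles)) != len(titles):
            raise QuestionBankError(f"duplicate section titles: {titles}")
        for s in self.sections:
            if not s.points:
                raise QuestionBankError(f"format error: section {s.title!r} has no points")

    @property
    def titles(self) -> tuple[str, ...]:
        return tuple(s.title for s in self.sections)

    @property
    def points(self) -> tuple[str, ...]:
        """All points, in global order (concatenation of section orders)."""
        return tuple(p for s in self.sections for p in s.points)

    @property
    def n_points(self) -> int:
        return sum(len(s.points) for s in self.sections)

    def serialize(self) -> str:
        """Canonical text form; ``parse_question_bank(bank.serialize()) == bank``."""
        out: list[str] = []
        n = 0
        for i, section in enumerate(self.sections):
            if i:
                out.append("")
            out.append(f"## {section.title}")
            for point in section.points:
                n += 1
                out.append(f"{n}. {point}")
        return "\n".join(out) + "\n"


def parse_question_bank(text: str, allcaps_headers: bool = False) -> QuestionBank:
    """Parse bank text into ordered sections of ordered points.

    ``allcaps_headers`` additionally treats an all-uppercase line as a section
    header, for banks authored without markdown-style markers.
    """
    sections: list[tuple[str, list[str]]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        is_header = line.startswith("##") or (
            allcaps_headers and line.isupper() and any(c.isalpha() for c in line)
        )
        if is_header:
            title = line.lstrip("#").strip()
            if not title:
                raise QuestionBankError(f"format error: empty section header at line {lineno}")
            sections.append((title, []))
        else:
            if not sections:
                raise QuestionBankError(
                    f"format error: question point before any section header at line {lineno}"
                )
            sections[-1][1].append(_ENUM_RE.sub("", line))
    if not sections:
        raise QuestionBankError("format error: no section header found")
    return QuestionBank(
        sections=tuple(Section(title=t, points=tuple(pts)) for t, pts in sections)
    )


def load_question_bank(path: str | Path, allcaps_headers: bool = False) -> QuestionBank:
    return parse_question_bank(Path(path).read_text(), allcaps_headers=allcaps_headers)


def packaged_bank_path() -> Path:
    return Path(__file__).parent / "assets" / "question_bank.txt"


@dataclass
class ChunkCursor:
    """Delivers a bank's points in global order, once each, flagging section-final
    points so the caller can preload the next chunk just before they are asked."""

    bank: QuestionBank
    current_section: int = 0
    next_point: int = 0
    exhausted: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.bank.sections:
            raise QuestionBankError("empty bank")

    def peek(self) -> tuple[str, bool]:
        """The next point and its chunk-boundary flag, without advancing."""
        if self.exhausted:
            raise QuestionBankError("cursor exhausted: no points remain")
        section = self.bank.sections[self.current_section]
        point = section.points[self.next_point]
        boundary = self.next_point == len(section.points) - 1
        return point, boundary

    def advance(self) -> tuple[str, bool]:
        """Return ``(point, chunk_boundary)`` and move past the point.

        ``chunk_boundary`` is True exactly on each section's final point.
        Advancing past exhaustion raises.
        """
        point, boundary = self.peek()
        if boundary:
            if self.current_section == len(self.bank.sections) - 1:
                self.exhausted = True
            else:
                self.current_section += 1
                self.next_point = 0
        else:
            self.next_point += 1
        return point, boundary
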