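"""Lexical-diversity and demographic-fidelity metrics.

Three evaluation instruments:

* **Distinct-1** — the fraction of unique unigram tokens over total unigram
  tokens in a text; 1 means every word is unique, values near 0 mean heavy
  repetition. Computed per transcript and per speaking role.
* **Duplicate Ratio** — the fraction of generated segments (e.g. narrative
  field values across a cohort) whose exact text occurs more than once. By
  default every occurrence of a repeated value counts toward the numerator
  (four identical segments give a ratio of 1.0); an ``excess`` counting rule
  (occurrences minus one per repeated value) is available behind a flag.
* **χ² goodness-of-fit** — observed category counts against configured
  expected proportions; non-significance (p > 0.05) indicates demographic
  fidelity. Parental status is compared with a one-sided z-test on the
  pooled proportion.

The tokenizer is fixed and documented: lowercase, punctuation stripped,
internal apostrophes kept, whitespace-split. Published diversity values from
other tokenizers should be compared with a tolerance of about ±0.03.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interview import InterviewResult, read_transcript
from .patients import NARRATIVE_FIELDS, CONDITIONAL_NARRATIVE_FIELDS, PatientProfile
from .population import CategoricalDist, ConditionalTable, PopulationConfig

__all__ = [
    "tokenize",
    "DiversityScore",
    "distinct1",
    "DuplicateReport",
    "duplicate_ratio",
    "transcript_diversity",
    "cohort_transcript_medians",
    "profile_duplicate_report",
    "profile_distinct1",
    "Chi2Result",
    "chi2_pvalue",
    "chi2_gof",
    "one_sided_z_p",
    "FidelityReport",
    "cohort_fidelity",
    "MetricsError",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")


class MetricsError(ValueError):
    pass


def tokenize(text: str) -> list[str]:
    """Lowercase unigram tokens: punctuation stripped except internal
    apostrophes, split on everything else. ``"I can't sleep"`` →
    ``['i', "can't", 'sleep']``."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class DiversityScore:
    distinct1: float
    n_tokens: int
    n_unique: int


def distinct1(tokens: Sequence[str]) -> DiversityScore:
    """Unique unigrams over total unigrams. Undefined for an empty sequence."""
    if not tokens:
        raise MetricsError("distinct1 is undefined for an empty token sequence")
    n_unique = len(set(tokens))
    return DiversityScore(
        distinct1=n_unique / len(tokens), n_tokens=len(tokens), n_unique=n_unique
    )


@dataclass(frozen=True)
class DuplicateReport:
    n_dup: int
    n_tot: int
    ratio: float
    value_counts: dict[str, int] = field(default_factory=dict)


def duplicate_ratio(
    segments: Sequence[str], rule: Literal["all", "excess"] = "all"
) -> DuplicateReport:
    """Fraction of segments whose exact text appears more than once.

    ``rule="all"`` (default): every occurrence of a repeated value counts.
    ``rule="excess"``: each repeated value contributes ``count - 1``.
    """
    if not segments:
        raise MetricsError("duplicate_ratio is undefined for an empty segment list")
    counts = Counter(segments)
    if rule == "all":
        n_dup = sum(c for c in counts.values() if c > 1)
    elif rule == "excess":
        n_dup = sum(c - 1 for c in counts.values() if c > 1)
    else:
        raise MetricsError(f"unknown duplicate counting rule {rule!r}")
    n_tot = len(segments)
    return DuplicateReport(
        n_dup=n_dup,
        n_tot=n_tot,
        ratio=n_dup / n_tot,
        value_counts={v: c for v, c in counts.items() if c > 1},
    )


# ---------------------------------------------------------------------------
# transcript metrics
# ---------------------------------------------------------------------------


def transcript_diversity(result: InterviewResult) -> dict[str, DiversityScore | None]:
    """Per-role Distinct-1 for one transcript: each role's response payloads
    (stop turn excluded) are concatenated, tokenized, and scored. A role with
    no turns is reported as ``None`` rather than an error."""
    out: dict[str, DiversityScore | None] = {}
    for role in ("patient", "interviewer"):
        texts = [t.text for t in result.turns if t.speaker == role and not t.is_stop]
        tokens = tokenize(" ".join(texts))
        out[role] = distinct1(tokens) if tokens else None
    return out


def cohort_transcript_medians(
    results: Iterable[InterviewResult] | str | Path,
    inliers_only: bool = False,
    stop_compliant_only: bool = False,
) -> dict[str, float | None]:
    """Median per-transcript Distinct-1 by role over a set of transcripts
    (an iterable of results, or a directory of exported ``.json`` files).

    ``stop_compliant_only`` keeps sessions that terminated with the stop
    token (excludes full failures); ``inliers_only`` additionally excludes
    soft failures. Medians use the standard midpoint convention
    (``numpy.median``)."""
    if isinstance(results, (str, Path)):
        results = [read_transcript(p) for p in sorted(Path(results).glob("*.json"))]
    per_role: dict[str, list[float]] = {"patient": [], "interviewer": []}
    for result in results:
        if inliers_only and result.status != "compliant":
            continue
        if stop_compliant_only and result.status == "full_failure":
            continue
        for role, score in transcript_diversity(result).items():
            if score is not None:
                per_role[role].append(score.distinct1)
    return {
        role: (float(np.median(vals)) if vals else None) for role, vals in per_role.items()
    }


# ---------------------------------------------------------------------------
# profile metrics
# ---------------------------------------------------------------------------


def profile_duplicate_report(
    cohort: Sequence[PatientProfile], rule: Literal["all", "excess"] = "all"
) -> dict[str, DuplicateReport]:
    """Per-narrative-field Duplicate Ratio across a cohort: the segments for a
    field are its generated values, one per patient that carries the field."""
    fields = list(NARRATIVE_FIELDS) + list(CONDITIONAL_NARRATIVE_FIELDS)
    out = {}
    for field_name in fields:
        segments = [
            p.narrative[field_name]["text"] for p in cohort if field_name in p.narrative
        ]
        if segments:
            out[field_name] = duplicate_ratio(segments, rule=rule)
    return out


def profile_distinct1(profile: PatientProfile) -> DiversityScore:
    """Distinct-1 over all backend-generated narrative content of one patient."""
    text = " ".join(v["text"] for v in profile.narrative.values())
    return distinct1(tokenize(text))


# ---------------------------------------------------------------------------
# demographic fidelity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float
    observed: dict[str, int]
    expected: dict[str, float]
    low_expected_warning: bool


def chi2_pvalue(stat: float, df: int) -> float:
    """Upper-tail probability of the χ² distribution (the test's p-value at a
    given statistic). For df = 2 this equals ``exp(-stat / 2)`` exactly."""
    return float(stats.chi2.sf(stat, df))


def chi2_gof(observed: Mapping[str, int], expected: CategoricalDist) -> Chi2Result:
    """χ² goodness-of-fit of observed category counts against expected
    proportions; df = categories − 1. A zero expected probability with a
    nonzero observed count is an error; any expected count below 5 sets the
    small-sample warning flag."""
    if set(observed) - set(expected.labels):
        raise MetricsError(
            f"consistency error: observed categories {sorted(set(observed) - set(expected.labels))} "
            "absent from the expected distribution"
        )
    obs = np.array([observed.get(label, 0) for label in expected.labels], dtype=float)
    n = obs.sum()
    if n < 1:
        raise MetricsError("chi2_gof requires at least one observation")
    probs = np.array(expected.probs)
    exp = probs * n
    if np.any((exp == 0) & (obs > 0)):
        bad = [l for l, e, o in zip(expected.labels, exp, obs) if e == 0 and o > 0]
        raise MetricsError(f"expected count 0 with nonzero observed for {bad}")
    keep = exp > 0
    chi2 = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
    df = int(len(expected.labels) - 1)
    return Chi2Result(
        chi2=chi2,
        df=df,
        p=chi2_pvalue(chi2, df),
        observed={l: int(o) for l, o in zip(expected.labels, obs)},
        expected={l: float(e) for l, e in zip(expected.labels, exp)},
        low_expected_warning=bool(np.any(exp < 5)),
    )


def one_sided_z_p(z: float) -> float:
    """Lower-tail standard-normal probability of a z statistic."""
    return float(stats.norm.cdf(z))


@dataclass
class FidelityReport:
    gof: dict[str, Chi2Result]
    parental_z: float
    parental_p: float
    parental_observed: int
    parental_expected: float
    relationship_by_age: pd.DataFrame
    relationship_by_age_expected: pd.DataFrame
    parental_by_age: pd.DataFrame
    parental_by_age_expected: pd.DataFrame
    n_patients: int

    def to_json_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "gof": {
                name: {
                    "chi2": r.chi2,
                    "df": r.df,
                    "p": r.p,
                    "observed": r.observed,
                    "expected": r.expected,
                    "low_expected_warning": r.low_expected_warning,
                }
                for name, r in self.gof.items()
            },
            "parental": {
                "z": self.parental_z,
                "p": self.parental_p,
                "observed_parents": self.parental_observed,
                "expected_parents": self.parental_expected,
            },
            "heatmaps": {
                "relationship_by_age": json.loads(self.relationship_by_age.to_json()),
                "relationship_by_age_expected": json.loads(
                    self.relationship_by_age_expected.to_json()
                ),
                "parental_by_age": json.loads(self.parental_by_age.to_json()),
                "parental_by_age_expected": json.loads(self.parental_by_age_expected.to_json()),
            },
        }

    def write_csv(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.relationship_by_age.to_csv(out_dir / "relationship_by_age_observed.csv")
        self.relationship_by_age_expected.to_csv(out_dir / "relationship_by_age_expected.csv")
        self.parental_by_age.to_csv(out_dir / "parental_by_age_observed.csv")
        self.parental_by_age_expected.to_csv(out_dir / "parental_by_age_expected.csv")


def _demographics(p) -> tuple[str, str, str, bool, Sequence[str]]:
    # Accept PatientProfile or a bare Demographics-like bundle.
    if hasattr(p, "demographics"):
        d = p.demographics
        return d.ethnicity, d.age_bracket, d.sex, p.has_children, list(p.disabilities)
    return p.ethnicity, p.age_bracket, p.sex, p.has_children, list(getattr(p, "disabilities", ()))


def cohort_fidelity(cohort: Sequence, cfg: PopulationConfig) -> FidelityReport:
    """Demographic-fidelity report for a generated cohort: goodness-of-fit
    rows for ethnicity, age group, and disability type; relationship-by-age
    and parental-by-age heatmap tables with configured expectations; and the
    pooled one-sided z-test for parental status."""
    if not cohort:
        raise MetricsError("cohort_fidelity requires a non-empty cohort")
    rows = [_demographics(p) for p in cohort]
    n = len(rows)

    eth_counts = Counter(r[0] for r in rows)
    age_counts = Counter(r[1] for r in rows)
    dis_counts: Counter[str] = Counter()
    for r in rows:
        dis_counts.update(r[4])

    gof = {
        "ethnicity": chi2_gof(eth_counts, cfg.ethnicity),
        "age_group": chi2_gof(age_counts, cfg.age_groups),
    }
    if sum(dis_counts.values()):
        gof["disability_type"] = chi2_gof(dis_counts, cfg.disability_type_shares)

    # Parental status: pooled one-sided z against the per-cell expectations.
    expected_p = np.array(
        [cfg.parental_by_age_sex[ConditionalTable.key(r[1], r[2])] for r in rows]
    )
    observed_parents = sum(1 for r in rows if r[3])
    mu = float(expected_p.sum())
    var = float((expected_p * (1 - expected_p)).sum())
    z = (observed_parents - mu) / np.sqrt(var) if var > 0 else 0.0
    p_parental = one_sided_z_p(float(z))

    brackets = list(cfg.age_groups.labels)
    rel_cats = list(cfg.relationship_by_age_sex.categories)
    obs_rel = pd.DataFrame(0.0, index=rel_cats, columns=brackets)
    per_bracket = Counter(r[1] for r in rows)
    for p_row in cohort:
        eth, bracket, sex, has_children, _ = _demographics(p_row)
        status = (
            p_row.relationship_status
            if hasattr(p_row, "relationship_status")
            else p_row.relationship_status
        )
        if status not in rel_cats:
            raise MetricsError(
                f"consistency error: relationship status {status!r} absent from configuration"
            )
        obs_rel.loc[status, bracket] += 1
    for bracket in brackets:
        if per_bracket[bracket]:
            obs_rel[bracket] /= per_bracket[bracket]

    # Expected relationship proportions per bracket, sex-weighted.
    exp_rel = pd.DataFrame(0.0, index=rel_cats, columns=brackets)
    for bracket in brackets:
        for sex, sex_p in zip(cfg.sex.labels, cfg.sex.probs):
            dist = cfg.relationship_by_age_sex.dist(bracket, sex)
            for cat, prob in zip(dist.labels, dist.probs):
                exp_rel.loc[cat, bracket] += sex_p * prob

    obs_par = pd.DataFrame(0.0, index=["has_children"], columns=brackets)
    for bracket in brackets:
        in_bracket = [r for r in rows if r[1] == bracket]
        if in_bracket:
            obs_par.loc["has_children", bracket] = sum(r[3] for r in in_bracket) / len(in_bracket)
    exp_par = pd.DataFrame(0.0, index=["has_children"], columns=brackets)
    for bracket in brackets:
        exp_par.loc["has_children", bracket] = sum(
            sex_p * cfg.parental_by_age_sex[ConditionalTable.key(bracket, sex)]
            for sex, sex_p in zip(cfg.sex.labels, cfg.sex.probs)
        )

    return FidelityReport(
        gof=gof,
        parental_z=float(z),
        parental_p=p_parental,
        parental_observed=observed_parents,
        parental_expected=mu,
        relationship_by_age=obs_rel,
        relationship_by_age_expected=exp_rel,
        parental_by_age=obs_par,
        parental_by_age_expected=exp_par,
        n_patients=n,
    )
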