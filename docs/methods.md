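# Methods

This note documents the models and procedures behind `synthintake`, the
assumptions they make, the parameters that matter, and what the packaged
fixtures and mock backend do and do not establish about real-model runs.

## Population model and demographic sampling

A patient's fixed attributes are drawn from a single validated JSON
configuration of census-style tables. The sampling chain per patient is:

1. ethnicity ~ categorical over 9 groups;
2. age bracket ~ categorical over 5 adult brackets (18–24 … 55–64), then an
   exact age uniform over the bracket's integer years;
3. sex ~ categorical over the two categories used by the conditioning
   tables (the schema accepts additional categories, but every conditional
   table must then cover them);
4. relationship status ~ the (age bracket, sex) row of a 6-category
   conditional table (Single, Living-apart-together, Married, Common-law,
   Divorced/Separated, Widowed);
5. parental status ~ Bernoulli with the (age bracket, sex) cell probability;
6. disability: Bernoulli prevalence by (age bracket, sex); on success,
   exactly one of ten types (Mental-health related, Pain-related, Seeing,
   Learning, Memory, Mobility, Flexibility, Hearing, Dexterity,
   Developmental) from the global type-share distribution. One type per
   patient is an intentional simplification; multi-disability assignment is
   out of scope.
7. psychiatric conditions: with probability `prob_any` (fixture default
   0.6), a comorbidity count over {1, 2, 3} (fixture default 0.6/0.3/0.1),
   then that many distinct conditions without replacement, each paired with
   one medication string from its catalog list. The fixture's `prob_any`
   and count weights are deliberate defaults chosen to make comorbid
   patients common without dominating; only the 1–3 range is externally
   constrained, so these two knobs are documented as modeling choices.

All probabilities are absolute fractions validated to sum to 1 within 1e-9;
a table may opt into explicit renormalization (`"normalize": true`) since
published percentages rarely sum exactly. Every (bracket, sex) cell of every
conditional table must be present — missing cells are load-time errors that
name the cell.

The packaged `population_config.json` is a synthetic fixture: structurally
faithful to regional census tables for an urban Canadian-style adult
catchment (category sets, conditioning structure, plausible magnitudes) but
not any agency's published figures. Regional re-targeting means editing this
one file.

**Identity.** Names come from packaged per-locale tables; the locale is
drawn from a census-weighted distribution so name assignment tracks the
configured ethnicity mix. The identity provider is an in-package weighted
name-table sampler; occupations, street names, and cities come from small
packaged lists. Date of birth is uniform over the days consistent with the
exact age at the configured reference date (fixture: 2025-01-01), so age,
bracket, and DOB always agree.

**Seeding.** One master seed per cohort; patient *i* uses
`default_rng([master_seed, i])`. This makes patient *i* identical whether
generated alone or in any batch, and keeps cohort generation trivially
parallelizable.

## Profile template and narrative enrichment

A profile template is requested from the backend given the serialized
question bank; the scripted mock derives one field per question point
(kind `fixed` for keyword-matched structured attributes, `narrative`
otherwise), and the packaged canonical template is exactly this derivation
for the packaged bank, against which the backend path is validated. Narrative
fields — family/social history, health/injury history, interests, daily
lifestyle, plus children's details for parents — are filled per field through
the backend with the fixed attributes as grounding. The mock's narrative text
is a pure function of (field id, non-name fixed attributes, backend seed)
with the name interpolated afterwards, which is what makes the
"two patients differing only by name" diff test meaningful.

## Interview engine

The patient model answers a hard-coded opener; thereafter the two agents
strictly alternate. Each model sees the history relabeled from its own
perspective (own turns `assistant`, counterpart `user`, own prompt as
`system`), and the two perspectives are exact user/assistant mirrors.

Protocol: completions must carry a final `RESPONSE:` prefix; the payload is
taken after the **last** prefix occurrence. Interviewer completions carry one
`Note: … <END_NOTE>` block per answered question. The parser never raises on
malformed output — a missing prefix, a duplicated prefix, or extra text
before the prefix (beyond one well-formed note block) sets a
chain-of-thought-leak flag instead, and a missing prefix falls back to the
raw text as payload. The stop condition is the payload being exactly
`<STOP>` after trimming; a stop token embedded in longer text is not a stop.

**Chunking and dumping.** The question bank's sections are context chunks.
The engine loads the chunk containing the next expected point and preloads
the following chunk when that point is section-final, so the assistant never
runs out of questions mid-chunk. When the assistant delivers the first point
of a new section, the completed section's turns are evicted from the active
window and replaced by a summary concatenated from that section's notes,
truncated to 200 estimated tokens and carried in the system message. Evicted
turns remain in the result; exports are always complete. Two boundary
consequences of this design: the note for a section's final answer is
recorded by the turn that opens the next section (and is therefore attributed
to the new section), and a vague answer to a section-final question is not
clarified (the engine has already moved the window). Both are deliberate,
minor trade-offs for a simple eviction rule.

Token accounting uses a documented heuristic — whitespace tokens × 1.3,
rounded up — because true token counts are a property of the serving model's
tokenizer. The instrumented maximum over all calls is recorded per session
and stays well under the default 6,144-token window in mock runs.

**Clarification loop.** The assistant assesses answers for clarity, detail,
and relevance; the mock operationalizes this as hedge-marker detection. At
most `max_clarifications_per_point` (default 2) clarifications are asked per
point, a cap the engine also applies after bank exhaustion: once all points
are delivered, the assistant must stop within the clarification budget or
the session ends as a full failure.

**Limits and classification.** `max_turns` defaults to 4 × total points,
guaranteeing termination. Classification: `full_failure` when the session
did not end with the stop token, ended with points undelivered, hit the turn
limit, or lost a backend mid-session (the partial transcript is retained);
otherwise `soft_failure` when any turn leaked reasoning; otherwise
`compliant`. Flagged sessions are excluded from "inlier" metric summaries.

**Decoding options** (temperature 0.9, top_k 40, top_p 0.9, num_ctx 6144)
are forwarded to the serving backend verbatim; the package configures, never
implements, the decoders.

## Scripted mock backend

The mock is a pure function of (messages, seed) per role — template author,
narrative writer, patient, interview assistant — dispatched on system-prompt
markers. The patient answers by keyword-matching the current question
against profile fields, with a seeded vague-answer mode to exercise
clarification; the assistant reconstructs its position from the active
history (highest already-asked point in the loaded chunk), never repeats a
point, and emits `<STOP>` only after the final point of the final loaded
section. Fault flags exist solely to test failure classification: `no_stop`
(suppresses the stop token), `premature_end` (stops after three points),
`leak_cot` / `patient_leak_cot` (prepend step-wise reasoning).

What mock-based results do and do not show: they validate the engine's
bookkeeping (point conservation, protocol parsing, context bounds,
classification, determinism) and the metric implementations, under text
whose lexical statistics are those of the scripted phrase banks — not of any
language model. Mock Distinct-1 levels therefore characterize the harness,
and real-model diversity or failure rates must be measured against a live
backend through the HTTP adapter.

## Metrics

Tokenizer: lowercase, punctuation stripped except internal apostrophes,
whitespace/word-boundary split. Published Distinct-1 values computed with
unspecified tokenizers should be compared only within about ±0.03.

Distinct-1 is unique/total unigrams per transcript and role (stop turn
excluded; a role with no turns is reported missing, not an error). Duplicate
Ratio counts, by default, every occurrence of a value that appears more than
once (four identical segments → 1.0); the alternative excess-count rule
(occurrences − 1) is available behind a flag. Profile-level segments are one
generated value per patient per narrative field, aggregated per field.

χ² goodness-of-fit uses Σ(O−E)²/E with E = p·n and df = k−1, p-values from
the χ² survival function (cross-checked in tests against an independent
library routine and, at df 2, against the closed form exp(−χ²/2)); expected
counts below 5 set a warning flag rather than failing. Parental status is
tested with a one-sided pooled z: under the null, the parent count is a sum
of per-patient Bernoullis with the configured cell probabilities, and
z = (O − Σpᵢ)/√Σpᵢ(1−pᵢ) with the lower-tail normal p. The relationship
table is reported as observed-vs-expected proportion heatmaps by age bracket
(sex-weighted expectations) rather than a single pooled χ², whose degrees of
freedom would depend on an arbitrary pooling convention; no multiple-testing
correction is applied across fidelity rows.

Calibration of the whole sampling-plus-testing loop is verified empirically:
over 500 seeded 1,000-patient cohorts drawn from the fixture configuration,
each goodness-of-fit test rejects at α = 0.05 in 5% ± 2% of cohorts.

## Numerical and interface choices

- Categorical draws invert the cumulative distribution with a single
  uniform variate; ties at boundaries resolve to the right, and the last
  label absorbs any floating-point residue.
- Question-bank syntax: `##`-prefixed headers (optionally ALL-CAPS lines);
  leading `N.` enumerations are stripped on parse and regenerated globally
  on serialization, making parse∘serialize the identity on canonical form.
- Exports: JSON (full schema, byte-stable for a fixed profile/bank/seed) and
  TXT (header line, opener line, one line per turn, then the summary lines).
- Profiles persist as JSON-lines; a malformed line errors with its line
  number.
- Problem sizes in the shipped acceptance script (300 calibration cohorts,
  40 end-to-end interviews, 25 fault seeds per mode) are chosen to keep the
  full recomputation around 15 s on one CPU while leaving Monte-Carlo noise
  well inside the tolerances being checked; the test suite uses larger sizes
  (500 cohorts, 100 interviews, 50 fault seeds) where the property demands.

## Known limitations

- The fixture's probabilities are plausible placeholders, not published
  statistics; conclusions about any real region require substituting real
  tables.
- At most one disability type per patient; children's details are
  backend-filled free text, not structured fields.
- No medication-safety or dosing validation; the condition→medication
  catalog is illustrative.
- The mock's clarification and vagueness handling are keyword heuristics;
  they exercise code paths, not clinical judgment.
- No hallucination, coherence, or role-deviation detection beyond the
  protocol flags; semantic and clinical quality assessment is out of scope.
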