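# synthintake

Synthetic psychiatric patients and intake-interview transcripts, for teams
building or evaluating language-model tools in mental health where real
patient data is locked behind privacy law. The package generates
demographically calibrated patient profiles, simulates a structured intake
interview between two chat agents (a patient model and an interview-assistant
model), and scores the output for lexical diversity and demographic fidelity.
Every model call goes through a chat-backend contract with a deterministic
scripted mock, so the full pipeline runs, tests, and reproduces offline; an
HTTP adapter targets any Ollama-compatible server for real-model runs.

## What it computes

**Profile sampling.** Fixed attributes are drawn from a validated population
configuration: ethnicity, a five-bracket age distribution with exact age,
sex, relationship status and parental status conditional on (age bracket,
sex), disability prevalence by (age bracket, sex) with shares over ten
disability types, 0–3 psychiatric conditions each paired with a commonly
prescribed medication, and census-weighted name locales. Narrative fields
(family/social history, health and injury history, interests, daily
lifestyle) are filled by the backend. One master seed reproduces a cohort;
patient *i* uses the stream `(seed, i)`, so patients are independent of
batch composition.

**Interview engine.** The patient answers a hard-coded opener; thereafter
the two agents alternate under a strict protocol — every output begins with
`RESPONSE:`, the assistant emits one `Note: … <END_NOTE>` block per answered
question, and ends with the literal payload `<STOP>`. The question bank is
delivered in header-defined chunks: the next chunk is preloaded just before
a chunk's final question, and completed chunks are evicted from the active
context and replaced by a note-seeded summary, keeping the window under
`num_ctx` (default 6,144 estimated tokens). Sessions are classified
`compliant`, `full_failure` (no stop token, premature stop, turn limit, or
backend error) or `soft_failure` (leaked step-by-step reasoning).

**Evaluation.**

- Distinct-1 = unique unigrams / total unigrams, per transcript and per role;
- Duplicate Ratio = N_dup / N_tot over generated field values;
- χ² goodness-of-fit of cohort category counts against configured
  proportions (ethnicity, age group, disability type; χ² = Σ(O−E)²/E,
  df = k−1), plus a one-sided pooled z-test for parental status and
  relationship-by-age / parental-by-age comparison tables.

## Worked example

```bash
synthintake generate-patients  --out cohort.jsonl --n 5 --seed 3
synthintake generate-transcripts --patients cohort.jsonl --out-dir tx --seed 3
synthintake evaluate --out report --patients cohort.jsonl --transcripts tx
```

With the default mock backend this finishes in a few seconds. The status
index `tx/index.csv` lists every session as `compliant` (5 of 5, 110–120
turns each), and `report/report.json` contains, for this seed:

```
"gof": ethnicity p=0.525, age_group p=0.497, disability_type p=0.602
"median_inliers": patient=0.377..., interviewer=0.252...
```

The goodness-of-fit p-values are well above 0.05: a 5-patient cohort drawn
from the packaged configuration shows no detectable deviation from it. The
per-role Distinct-1 medians describe the scripted mock's phrasing variety
(patient turns are more varied than the assistant's acknowledgment-heavy
turns); with a real model backend these numbers characterize the model
instead. Heatmap tables are written alongside as CSV.

A Python-level walkthrough of the same pipeline:

```python
from synthintake.population import load_population_config, packaged_config_path
from synthintake.questionbank import load_question_bank, packaged_bank_path
from synthintake.patients import canonical_template, generate_patient
from synthintake.backends import ScriptedMockBackend
from synthintake.interview import run_interview

cfg = load_population_config(packaged_config_path())
bank = load_question_bank(packaged_bank_path())          # 5 sections, 47 points
patient = generate_patient(cfg, canonical_template(), ScriptedMockBackend(seed=1),
                           master_seed=1, index=0)
result = run_interview(patient, bank,
                       ScriptedMockBackend(seed=1, vague_rate=0.15),
                       ScriptedMockBackend(seed=1), seed=1)
print(result.status, len(result.turns), len(result.notes))
# compliant 118 58
```

To run against a live server instead of the mock, pass
`--backend http --endpoint http://localhost:11434 --model llama3.3:70b`.

## Layout

- `src/synthintake/population.py` — config schema, validation, categorical sampling
- `src/synthintake/patients.py` — template, demographic/attribute/identity sampling, enrichment
- `src/synthintake/questionbank.py` — bank parsing and chunk cursor
- `src/synthintake/backends.py` — chat contract, scripted mock, Ollama HTTP adapter
- `src/synthintake/interview.py` — orchestration, protocol parsing, classification, export
- `src/synthintake/metrics.py` — Distinct-1, Duplicate Ratio, χ²/z fidelity report
- `src/synthintake/cli.py` — `generate-patients`, `generate-transcripts`, `evaluate`
- `src/synthintake/assets/` — packaged fixtures: population config, question bank,
  canonical profile template, prompts, name tables
- `docs/methods.md` — models, assumptions, parameter choices, limitations
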