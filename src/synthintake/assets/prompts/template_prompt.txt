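[TEMPLATE TASK]
You are preparing a structured patient profile template for a psychiatric
intake simulation. Given the question bank below, produce a profile template
that strictly adheres to the question bank's format: one field per question
point, grouped under the bank's section headers, so that a completed profile
can answer every point. Mark each field as "fixed" when it corresponds to a
structured attribute (demographics, diagnoses, medications, allergies) and
"narrative" when it requires free-text detail. Return the template as JSON.

Example field:
  {"field_id": "full_name", "section": "General Information",
   "kind": "fixed", "prompt_hint": "Can you tell me your full name?"}

<QUESTION_BANK>
{bank}
</QUESTION_BANK>
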