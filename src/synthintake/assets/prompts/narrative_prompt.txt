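[NARRATIVE TASK]
You are completing the remaining sections of a structured synthetic patient
profile with realistic but entirely fictional details. Fill in the single
field named below, staying logically consistent with the fixed attributes
already assigned (age, sex, relationship status, children, diagnoses,
medications, disabilities, occupation). Write 2-4 sentences of plain prose.

NARRATIVE_FIELD: {field_id}
FIELD_HINT: {hint}

<PROFILE_SO_FAR>
{profile}
</PROFILE_SO_FAR>
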