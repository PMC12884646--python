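{
  "_comment": "Hand-curated surface synonym substitutions used by the synthetic questionnaire generator's synonym_swap perturbation. Keys/values are surface tokens; capitalization is handled by the generator.",
  "tasks": "chores",
  "mistakes": "errors",
  "things": "items",
  "seat": "chair",
  "often": "frequently",
  "attention": "focus",
  "difficulty": "trouble",
  "question": "query",
  "answers": "replies",
  "activities": "duties",
  "talks": "chatters",
  "loses": "misplaces",
  "organizing": "arranging",
  "finish": "complete",
  "instructions": "requests"
}
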