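{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/actinf/model_spec.schema.json",
  "title": "actinf generative model specification",
  "type": "object",
  "required": ["n_states", "n_outcomes", "n_actions", "horizon", "A", "B", "D", "C", "policies"],
  "properties": {
    "n_states": {"type": "integer", "minimum": 1},
    "n_outcomes": {"type": "integer", "minimum": 1},
    "n_actions": {"type": "integer", "minimum": 1},
    "horizon": {"type": "integer", "minimum": 1},
    "A": {
      "description": "Likelihood matrix, row-major [outcome][state]; columns are distributions over outcomes.",
      "type": "array",
      "items": {"type": "array", "items": {"type": "number", "minimum": 0}}
    },
    "B": {
      "description": "One transition matrix per action, each [next_state][prev_state]; columns are distributions over next states.",
      "type": "array",
      "items": {
        "type": "array",
        "items": {"type": "array", "items": {"type": "number", "minimum": 0}}
      }
    },
    "D": {
      "description": "Initial-state prior.",
      "type": "array",
      "items": {"type": "number", "minimum": 0}
    },
    "C": {
      "description": "Outcome preferences: either the log of a proper distribution (optionally one row per future step) or raw utilities normalized via log-softmax.",
      "type": "object",
      "oneOf": [
        {"required": ["log_probs"]},
        {"required": ["utilities"]}
      ],
      "properties": {
        "log_probs": {"type": "array"},
        "utilities": {"type": "array"}
      }
    },
    "E": {
      "description": "Optional deontic matrix [outcome][policy]; columns are distributions over outcomes.",
      "type": "array",
      "items": {"type": "array", "items": {"type": "number", "minimum": 0}}
    },
    "E_counts": {
      "description": "Optional nonnegative concentration counts, same shape as E; E must equal the column-normalized counts.",
      "type": "array",
      "items": {"type": "array", "items": {"type": "number", "minimum": 0}}
    },
    "policies": {
      "description": "Explicit list of action-index sequences, each of length horizon.",
      "type": "array",
      "items": {"type": "array", "items": {"type": "integer", "minimum": 0}}
    },
    "gamma": {"type": "number", "exclusiveMinimum": 0, "default": 1.0}
  }
}
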