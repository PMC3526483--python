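{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "StudyDesign document (YAML/JSON)",
  "type": "object",
  "required": ["species", "subjects", "tasks", "participation"],
  "properties": {
    "species": {
      "type": "array",
      "items": {"type": "string"},
      "uniqueItems": true,
      "description": "Ordered species labels"
    },
    "subjects": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["subject_id", "species"],
        "properties": {
          "subject_id": {"type": "string"},
          "species": {"type": "string"}
        }
      }
    },
    "tasks": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["task_id", "domain", "response_type", "n_trials"],
        "properties": {
          "task_id": {"type": "string"},
          "domain": {"type": "string"},
          "response_type": {"enum": ["binomial", "rank"]},
          "n_trials": {"type": "integer", "minimum": 1}
        }
      }
    },
    "participation": {
      "type": "array",
      "items": {
        "type": "array",
        "prefixItems": [{"type": "string"}, {"type": "string"}],
        "minItems": 2,
        "maxItems": 2
      },
      "description": "(subject_id, task_id) pairs actually observed"
    }
  }
}
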