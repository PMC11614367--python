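{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/vibscale/dataset.schema.json",
  "title": "vibscale dataset",
  "description": "Molecules pairing experimental gas-phase fundamental transition wavenumbers with computed harmonic wavenumbers per quantum-chemical method. All wavenumbers in cm^-1.",
  "type": "object",
  "required": ["molecules"],
  "properties": {
    "molecules": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "id", "formula", "n_atoms", "is_linear", "charge",
          "multiplicity", "exp_frequencies", "calc_frequencies"
        ],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "formula": {"type": "string"},
          "n_atoms": {"type": "integer", "minimum": 2},
          "is_linear": {"type": "boolean"},
          "charge": {"type": "integer"},
          "multiplicity": {"type": "integer", "minimum": 1},
          "exp_frequencies": {
            "type": "array",
            "items": {"type": "number", "exclusiveMinimum": 0}
          },
          "calc_frequencies": {
            "type": "object",
            "additionalProperties": {
              "type": "array",
              "items": {"type": "number", "exclusiveMinimum": 0}
            }
          }
        }
      }
    }
  }
}
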