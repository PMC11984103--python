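{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "adcomm species model",
 "description": "Canonical JSON dialect for one organism's stoichiometric model. Metabolite ids end in _c (cytosol), _e (species extracellular), or _m (shared medium), matching their compartment. Exchange reactions touch exactly one medium metabolite; other reactions touch none.",
 "type": "object",
 "required": ["species_id", "biomass_reaction_id", "metabolites", "reactions"],
 "properties": {
  "species_id": {"type": "string", "minLength": 1},
  "taxonomy_label": {"type": "string"},
  "biomass_reaction_id": {"type": "string", "minLength": 1},
  "extracellular_enzymes": {
   "type": "array",
   "items": {
    "type": "array",
    "prefixItems": [{"type": "string"}, {"type": "string"}],
    "minItems": 2,
    "maxItems": 2
   }
  },
  "metabolites": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "compartment"],
    "properties": {
     "id": {"type": "string", "pattern": "^.+_(c|e|m)$"},
     "name": {"type": "string"},
     "compartment": {"enum": ["c", "e", "m"]},
     "formula": {"type": ["string", "null"]},
     "charge": {"type": ["integer", "null"]}
    }
   }
  },
  "reactions": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "stoichiometry"],
    "properties": {
     "id": {"type": "string", "minLength": 1},
     "name": {"type": "string"},
     "stoichiometry": {
      "type": "object",
      "additionalProperties": {"type": "number"},
      "minProperties": 1
     },
     "lower_bound": {"type": "number"},
     "upper_bound": {"type": "number"},
     "is_exchange": {"type": "boolean"},
     "is_extracellular": {"type": "boolean"},
     "gene_rule": {"type": ["string", "null"]}
    }
   }
  }
 }
}
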