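{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "neobasket patient record",
  "description": "One row of the individual-patient-data table. Comma-separated, UTF-8, one header row, literal 'NA' for absent values. Durations are months from start of study treatment.",
  "type": "object",
  "required": [
    "id", "cohort", "age", "sex", "ecog", "lynch", "clinical_t",
    "clinical_n_positive", "site", "regimen", "kras", "nras", "braf",
    "surgery", "cycles_preop", "cycles_postop", "tts_months", "yp_t", "yp_n",
    "trg", "r0", "ccr", "watch_and_wait", "efs_months", "efs_event",
    "dfs_months", "dfs_event", "os_months", "os_event", "followup_months"
  ],
  "properties": {
    "id": {"type": "string", "minLength": 1},
    "cohort": {"enum": ["colon", "rectum"]},
    "age": {"type": "integer", "minimum": 18},
    "sex": {"enum": ["male", "female"]},
    "ecog": {"type": "integer", "minimum": 0, "maximum": 1},
    "lynch": {"enum": ["yes", "no", "unknown"]},
    "clinical_t": {"enum": ["T1", "T2", "T3", "T4a", "T4b"]},
    "clinical_n_positive": {"type": "boolean"},
    "site": {"type": "string"},
    "regimen": {
      "type": "string",
      "pattern": "^(TORI)(\\+IRI)?(\\+BEV)?$",
      "description": "'+'-joined subset of {TORI, IRI, BEV}; TORI always present"
    },
    "kras": {"enum": ["wild", "mutant", "unknown"]},
    "nras": {"enum": ["wild", "mutant", "unknown"]},
    "braf": {"enum": ["wild", "mutant", "unknown"]},
    "surgery": {"type": "boolean"},
    "cycles_preop": {"type": "integer", "minimum": 1},
    "cycles_postop": {"type": "integer", "minimum": 0},
    "tts_months": {"type": ["number", "null"], "exclusiveMinimum": 0},
    "yp_t": {"type": ["string", "null"], "pattern": "^ypT(0|1|2|3|4a)$"},
    "yp_n": {"type": ["string", "null"], "pattern": "^ypN(0|1|1a|1b|2)$"},
    "trg": {"type": ["integer", "null"], "minimum": 0, "maximum": 3},
    "r0": {"type": ["boolean", "null"]},
    "ccr": {"type": "boolean"},
    "watch_and_wait": {"type": "boolean"},
    "efs_months": {"type": "number", "exclusiveMinimum": 0},
    "efs_event": {"type": "boolean"},
    "dfs_months": {"type": ["number", "null"], "exclusiveMinimum": 0},
    "dfs_event": {"type": ["boolean", "null"]},
    "os_months": {"type": "number", "exclusiveMinimum": 0},
    "os_event": {"type": "boolean"},
    "followup_months": {"type": "number", "exclusiveMinimum": 0}
  },
  "allOf": [
    {
      "description": "no pathology, surgery timing or DFS without surgery",
      "if": {"properties": {"surgery": {"const": false}}},
      "then": {
        "properties": {
          "tts_months": {"type": "null"}, "yp_t": {"type": "null"},
          "yp_n": {"type": "null"}, "trg": {"type": "null"},
          "dfs_months": {"type": "null"}
        }
      }
    },
    {
      "description": "watch-and-wait implies clinical complete response and no surgery",
      "if": {"properties": {"watch_and_wait": {"const": true}}},
      "then": {
        "properties": {"ccr": {"const": true}, "surgery": {"const": false}}
      }
    }
  ]
}
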