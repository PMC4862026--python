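{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "MCCP run report",
  "type": "object",
  "required": [
    "config",
    "seeds",
    "n_proteins",
    "n_experiments",
    "n_positives",
    "oob",
    "cv",
    "cutoff",
    "shift_scan"
  ],
  "properties": {
    "config": {"type": "object"},
    "seeds": {
      "type": "object",
      "required": ["master_seed"],
      "properties": {
        "master_seed": {"type": "integer"},
        "forest_seeds": {"type": "array", "items": {"type": "integer"}}
      }
    },
    "n_proteins": {"type": "integer"},
    "n_experiments": {"type": "integer"},
    "n_positives": {"type": "integer"},
    "oob": {
      "type": "object",
      "required": ["per_model", "mean", "sd"],
      "properties": {
        "per_model": {"type": "array", "items": {"type": "number"}},
        "mean": {"type": "number"},
        "sd": {"type": "number"}
      }
    },
    "cv": {
      "type": "object",
      "required": ["per_model_auc", "auc_mean"],
      "properties": {
        "per_model_auc": {"type": "array", "items": {"type": "number"}},
        "auc_mean": {"type": "number"},
        "folds": {"type": "integer"}
      }
    },
    "auc": {"type": "number"},
    "cutoff": {
      "type": "object",
      "required": ["threshold", "n_selected", "counts", "fp_fraction"],
      "properties": {
        "threshold": {"type": "number"},
        "n_selected": {"type": "integer"},
        "counts": {"type": "object"},
        "fp_fraction": {"type": "number"}
      }
    },
    "shift_scan": {
      "type": "object",
      "required": ["n_experiments", "n_testable", "n_significant_05"],
      "properties": {
        "n_experiments": {"type": "integer"},
        "n_testable": {"type": "integer"},
        "n_significant_05": {"type": "integer"}
      }
    },
    "consensus": {"type": "object"}
  }
}
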