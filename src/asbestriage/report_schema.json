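{
  "schema_version": "1",
  "estimate": {
    "type": "object",
    "keys": {
      "name": "string",
      "point": "number",
      "ci_low": "number",
      "ci_high": "number",
      "n_boot": "integer",
      "seed": "integer",
      "n_skipped": "integer"
    }
  },
  "report": {
    "type": "object",
    "keys": {
      "schema_version": "string",
      "software_version": "string",
      "timestamp": "string",
      "config": "object",
      "seeds": "object",
      "cohort": {
        "type": "object",
        "keys": {"n_cases": "integer", "n_reference_positive": "integer"}
      },
      "triage": {
        "type": "object",
        "keys": {
          "category_counts": "object",
          "category_percent": "object",
          "verdict_counts": "object",
          "verdict_percent": "object"
        }
      },
      "adjudication": {
        "type": "object",
        "keys": {
          "verdict_count_distribution": "object",
          "n_reference_positive": "integer"
        }
      },
      "metrics": {
        "type": "object",
        "keys": {
          "confusion": {
            "type": "object",
            "keys": {"tp": "integer", "fp": "integer", "tn": "integer", "fn": "integer"}
          },
          "estimates": {"type": "array", "items": "$estimate"},
          "auc_comparison": {
            "type": "object",
            "keys": {
              "auc_composite": "number",
              "auc_score_only": "number",
              "diff": "number",
              "p_value": "number",
              "method": "string"
            }
          },
          "kendall_tau_score_vs_final": "number"
        }
      },
      "agreement": {
        "type": "object",
        "keys": {
          "n_items": "integer",
          "n_excluded": "integer",
          "randolph_kappa": "object",
          "fleiss_kappa": "number",
          "subgroup_kappas": "object",
          "five_rater_kappa_uncertain": "number?",
          "n_uncertain_complete": "integer"
        }
      },
      "power_design": {
        "type": "object",
        "keys": {
          "p_true": "number",
          "power_target": "number",
          "lower_bound": "number",
          "ci_method": "string",
          "n_positives": "integer",
          "k_threshold": "integer",
          "achieved_power": "number",
          "point_sensitivity": "number",
          "ci_low": "number",
          "ci_high": "number"
        }
      }
    }
  }
}
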