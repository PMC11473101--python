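{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "StatsReport",
  "type": "object",
  "required": ["provenance", "contrasts", "anova", "paired", "correlations", "modulation_scores", "subjects"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package_version", "seed", "config_hash", "mode", "n_subjects", "conditions"],
      "properties": {
        "package_version": {"type": "string"},
        "seed": {"type": "integer"},
        "config_hash": {"type": "string"},
        "mode": {"type": "string"},
        "n_subjects": {"type": "integer"},
        "conditions": {"type": "array", "items": {"type": "string"}}
      }
    },
    "contrasts": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["df", "forming_threshold", "exact", "n_permutations", "t_series", "clusters", "uncorrected_sig_windows", "corrected_sig_windows"],
        "properties": {
          "df": {"type": "integer"},
          "forming_threshold": {"type": "number"},
          "exact": {"type": "boolean"},
          "n_permutations": {"type": "integer"},
          "t_series": {"type": "array", "items": {"type": "number"}},
          "bin_centers_ms": {"type": "array", "items": {"type": "number"}},
          "clusters": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["start_ms", "end_ms", "signed_mass", "p"],
              "properties": {
                "start_ms": {"type": "number"},
                "end_ms": {"type": "number"},
                "signed_mass": {"type": "number"},
                "p": {"type": "number"}
              }
            }
          },
          "uncorrected_sig_windows": {"type": "array", "items": {"type": "array", "items": {"type": "number"}}},
          "corrected_sig_windows": {"type": "array", "items": {"type": "array", "items": {"type": "number"}}}
        }
      }
    },
    "anova": {
      "type": "object",
      "required": ["F", "df_effect", "df_error", "p_uncorrected", "p_gg", "partial_eta_sq", "gg_epsilon", "p_preferred"],
      "properties": {
        "F": {"type": "number"},
        "df_effect": {"type": "number"},
        "df_error": {"type": "number"},
        "df_effect_gg": {"type": "number"},
        "df_error_gg": {"type": "number"},
        "p_uncorrected": {"type": "number"},
        "p_gg": {"type": "number"},
        "partial_eta_sq": {"type": "number"},
        "gg_epsilon": {"type": "number"},
        "mauchly_w": {"type": "number", "nullable": true},
        "mauchly_p": {"type": "number", "nullable": true},
        "p_preferred": {"type": "number"}
      }
    },
    "paired": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "t", "df", "p_uncorrected", "p_holm", "p_bonferroni", "cohens_dz", "mean_diff", "mean_diff_ci95"],
        "properties": {
          "name": {"type": "string"},
          "t": {"type": "number"},
          "df": {"type": "integer"},
          "p_uncorrected": {"type": "number"},
          "p_holm": {"type": "number"},
          "p_bonferroni": {"type": "number"},
          "cohens_dz": {"type": "number"},
          "mean_diff": {"type": "number"},
          "mean_diff_ci95": {"type": "array", "items": {"type": "number"}}
        }
      }
    },
    "correlations": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["r", "n", "df", "p", "ci95"],
        "properties": {
          "r": {"type": "number"},
          "n": {"type": "integer"},
          "df": {"type": "integer"},
          "p": {"type": "number"},
          "ci95": {"type": "array", "items": {"type": "number"}}
        }
      }
    },
    "reliability": {
      "type": "object",
      "nullable": true,
      "required": ["test_retest_r", "cronbach_alpha"],
      "properties": {
        "test_retest_r": {"type": "number"},
        "cronbach_alpha": {"type": "number"}
      }
    },
    "modulation_scores": {
      "type": "object",
      "additionalProperties": {"type": "array", "items": {"type": "number"}}
    },
    "subjects": {"type": "array", "items": {"type": "string"}}
  }
}
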