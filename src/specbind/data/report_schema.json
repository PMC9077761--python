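{
  "$schema-note": "Minimal JSON schema for specbind reports, version specbind-report/1. Subset of JSON Schema: type, required, properties, items.",
  "type": "object",
  "required": ["schema", "provenance", "results"],
  "properties": {
    "schema": {"type": "string"},
    "provenance": {"type": "object"},
    "results": {"type": "object"}
  },
  "blockSchemas": {
    "quenching": {
      "type": "object",
      "required": ["fits", "mechanism"],
      "properties": {
        "fits": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["temperature_K", "k_sv_per_M", "k_sv_se_per_M", "r_corr", "k_q_per_M_s", "tau0_s"],
            "properties": {
              "temperature_K": {"type": "number"},
              "k_sv_per_M": {"type": "number"},
              "k_sv_se_per_M": {"type": "number"},
              "r_corr": {"type": "number"},
              "k_q_per_M_s": {"type": "number"},
              "tau0_s": {"type": "number"}
            }
          }
        },
        "mechanism": {
          "type": "object",
          "required": ["verdict", "evidence"],
          "properties": {
            "verdict": {"type": "string"},
            "evidence": {"type": "array"}
          }
        }
      }
    },
    "binding": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["temperature_K", "k_binding_per_M", "n_sites", "r_corr"],
        "properties": {
          "temperature_K": {"type": "number"},
          "k_binding_per_M": {"type": "number"},
          "k_binding_se_per_M": {"type": "number"},
          "n_sites": {"type": "number"},
          "r_corr": {"type": "number"}
        }
      }
    },
    "thermodynamics": {
      "type": "object",
      "required": ["delta_h_kj_per_mol", "delta_s_j_per_mol_K", "delta_g_kj_per_mol", "force_type"],
      "properties": {
        "delta_h_kj_per_mol": {"type": "number"},
        "delta_s_j_per_mol_K": {"type": "number"},
        "delta_g_kj_per_mol": {"type": "object"},
        "delta_g_from_k_kj_per_mol": {"type": "object"},
        "force_type": {"type": "string"}
      }
    },
    "lifetime": {
      "type": "object",
      "required": ["fits"],
      "properties": {
        "fits": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["amplitudes", "lifetimes_ns", "avg_lifetime_ns", "chi2_reduced", "n_components"],
            "properties": {
              "amplitudes": {"type": "array", "items": {"type": "number"}},
              "lifetimes_ns": {"type": "array", "items": {"type": "number"}},
              "avg_lifetime_ns": {"type": "number"},
              "chi2_reduced": {"type": "number"},
              "n_components": {"type": "integer"}
            }
          }
        },
        "comparison": {"type": "object"}
      }
    },
    "cd": {
      "type": "object",
      "required": ["mre_208_deg_cm2_dmol", "alpha_helix_pct", "alpha_helix_pct_clipped"],
      "properties": {
        "mre_208_deg_cm2_dmol": {"type": "number"},
        "alpha_helix_pct": {"type": "number"},
        "alpha_helix_pct_clipped": {"type": "number"}
      }
    },
    "peaks": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["reference_peak_nm", "sample_peak_nm", "shift_nm", "intensity_ratio", "verdict"],
        "properties": {
          "intensity_ratio": {"type": "number"},
          "verdict": {"type": "string"},
          "tolerance_nm": {"type": "number"}
        }
      }
    },
    "displacement": {
      "type": "object",
      "required": ["series", "site_assignment"],
      "properties": {
        "series": {"type": "array"},
        "site_assignment": {"type": "string"}
      }
    }
  }
}
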