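{
  "schema_version": 1,
  "description": "Per-variant relative IKs/KCNQ1 current amplitudes (r, variant/WT at the analysis voltage) and activation shifts (delta V1/2, mV, positive = depolarizing). Entries with source 'text' carry values printed in the study's running text; entries with source 'figure_placeholder' are approximate values read off bar graphs and activation fits, bundled only so every expression context of every variant is runnable. They are stand-ins, not measured claims.",
  "default_analysis_voltage_mV": 40.0,
  "variants": {
    "G119R": {
      "entries": [
        {"context": "WITH_E1", "zygosity": "HET", "r": 0.74, "delta_v_half_mV": 0.0, "source": "text"},
        {"context": "WITH_E1", "zygosity": "HOMO", "r": 0.10, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HET", "r": 0.35, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HOMO", "r": 0.30, "delta_v_half_mV": 0.0, "source": "figure_placeholder"}
      ]
    },
    "delF166": {
      "entries": [
        {"context": "WITH_E1", "zygosity": "HET", "r": 1.00, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "WITH_E1", "zygosity": "HOMO", "r": 0.10, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HET", "r": 0.55, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HOMO", "r": 0.40, "delta_v_half_mV": 0.0, "source": "figure_placeholder"}
      ]
    },
    "delG186_L187": {
      "entries": [
        {"context": "WITH_E1", "zygosity": "HET", "r": 0.40, "delta_v_half_mV": 8.0, "source": "figure_placeholder"},
        {"context": "WITH_E1", "zygosity": "HOMO", "r": 0.15, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HET", "r": 0.30, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HOMO", "r": 0.20, "delta_v_half_mV": 0.0, "source": "figure_placeholder"}
      ]
    },
    "V254L": {
      "entries": [
        {"context": "WITH_E1", "zygosity": "HET", "r": 0.45, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "WITH_E1", "zygosity": "HOMO", "r": 0.10, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HET", "r": 0.35, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HOMO", "r": 0.25, "delta_v_half_mV": 0.0, "source": "figure_placeholder"}
      ]
    },
    "L273V": {
      "entries": [
        {"context": "WITH_E1", "zygosity": "HET", "r": 0.60, "delta_v_half_mV": 12.0, "source": "figure_placeholder", "analysis_voltage_mV": 20.0},
        {"context": "WITH_E1", "zygosity": "HOMO", "r": 0.50, "delta_v_half_mV": 15.0, "source": "figure_placeholder", "analysis_voltage_mV": 20.0},
        {"context": "NO_E1", "zygosity": "HET", "r": 1.30, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HOMO", "r": 1.60, "delta_v_half_mV": 0.0, "source": "figure_placeholder"}
      ]
    },
    "K421E": {
      "entries": [
        {"context": "WITH_E1", "zygosity": "HET", "r": 0.84, "delta_v_half_mV": 0.0, "source": "text"},
        {"context": "WITH_E1", "zygosity": "HOMO", "r": 0.34, "delta_v_half_mV": 0.0, "source": "text"},
        {"context": "NO_E1", "zygosity": "HET", "r": 0.60, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HOMO", "r": 0.40, "delta_v_half_mV": 0.0, "source": "figure_placeholder"}
      ]
    },
    "G430fs*28": {
      "entries": [
        {"context": "WITH_E1", "zygosity": "HET", "r": 1.00, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "WITH_E1", "zygosity": "HOMO", "r": 1.00, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HET", "r": 1.00, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HOMO", "r": 1.00, "delta_v_half_mV": 0.0, "source": "figure_placeholder"}
      ]
    },
    "R539L": {
      "entries": [
        {"context": "WITH_E1", "zygosity": "HET", "r": 0.45, "delta_v_half_mV": 8.0, "source": "figure_placeholder"},
        {"context": "WITH_E1", "zygosity": "HOMO", "r": 0.18, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HET", "r": 1.00, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HOMO", "r": 1.40, "delta_v_half_mV": 0.0, "source": "figure_placeholder"}
      ]
    },
    "R591C": {
      "entries": [
        {"context": "WITH_E1", "zygosity": "HET", "r": 0.72, "delta_v_half_mV": 0.0, "source": "text"},
        {"context": "WITH_E1", "zygosity": "HOMO", "r": 0.16, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HET", "r": 0.60, "delta_v_half_mV": 0.0, "source": "figure_placeholder"},
        {"context": "NO_E1", "zygosity": "HOMO", "r": 0.45, "delta_v_half_mV": 0.0, "source": "figure_placeholder"}
      ]
    }
  }
}
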