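{
  "comment": "Machine-readable transcription of the published evaluation tables: confusion matrices (rows observed H/E/C, columns predicted H/E/C), printed scores, case-study structure strings, and main-chain hydrogen-bond tallies.",
  "cb513": {
    "n_residues": 51634,
    "models": {
      "SSP_CV": {
        "confusion": [[16469, 48, 1840], [92, 8804, 2955], [2313, 2032, 17081]],
        "printed": {
          "q3": 82.03, "q_H": 89.72, "q_E": 74.29, "q_C": 79.73,
          "sov": 79.46, "sov_H": 83.14, "sov_E": 72.24, "sov_C": 75.46,
          "mcc_H": 0.82, "mcc_E": 0.71, "mcc_C": 0.64
        }
      },
      "SSP_55": {
        "confusion": [[16333, 62, 1962], [87, 9001, 2763], [2288, 2279, 16859]],
        "printed": {
          "q3": 81.72, "q_H": 88.98, "q_E": 75.96, "q_C": 78.69,
          "sov": 78.93, "sov_H": 82.19, "sov_E": 73.43, "sov_C": 74.5,
          "mcc_H": 0.81, "mcc_E": 0.71, "mcc_C": 0.63
        }
      }
    }
  },
  "gsw25": {
    "n_residues": 1400,
    "models": {
      "SSP_CV": {
        "confusion": [[682, 1, 39], [58, 352, 136], [53, 40, 39]],
        "printed": {
          "q3": 76.65, "q_H": 94.46, "q_E": 64.47, "q_C": 29.55,
          "sov": 59.07, "sov_H": 100.0, "sov_E": 66.04, "sov_C": 62.75,
          "mcc_H": 0.79, "mcc_E": 0.65, "mcc_C": 0.13,
          "q_he_error": 4.2
        }
      },
      "SSP_55": {
        "confusion": [[680, 0, 42], [25, 384, 137], [51, 20, 61]],
        "printed": {
          "q3": 80.36, "q_H": 94.19, "q_E": 70.33, "q_C": 46.22,
          "sov": 62.44, "sov_H": 100.0, "sov_E": 63.68, "sov_C": 78.91,
          "mcc_H": 0.83, "mcc_E": 0.73, "mcc_C": 0.25,
          "q_he_error": 1.8
        }
      }
    }
  },
  "inhibitors": {
    "trypsin": {
      "pdb_id": "1MCT",
      "full_sequence": "RICPRIWMECTRDSDCMAKCICVAGHCG",
      "region_sequence": "RIWMECTRDSDCMAKCICVA",
      "observed": "CCCCECCCHHHCCCCCCEEC",
      "predicted": "EEEEECCCCCCCCCEEEECE",
      "printed": {"q_C": 42.8}
    },
    "kinase": {
      "pdb_id": "1ATP",
      "full_sequence": "TTYADFIASGRTGRRNAIHD",
      "region_sequence": "FIASGRTGRRNA",
      "observed": "HHHCCCCCCCCC",
      "predicted": "HHCCCCCCCCCC",
      "printed": {"q_C": 100.0}
    }
  },
  "hbond_tally": {
    "R_CC": {"mm": 10345, "mh": 14690, "all_bonds": 78700, "n_residues": 19182,
             "printed": {"mm_mh": 25035, "frac_mm": 41.3, "frac_mh": 58.7}},
    "R_CE": {"mm": 1685, "mh": 1898, "all_bonds": 10652, "n_residues": 2584,
             "printed": {"mm_mh": 3583, "frac_mm": 47.0, "frac_mh": 53.0}},
    "R_EC": {"mm": 3972, "mh": 2303, "all_bonds": 17052, "n_residues": 3193,
             "printed": {"mm_mh": 6275, "frac_mm": 63.3, "frac_mh": 36.7}},
    "R_EE": {"mm": 15143, "mh": 5732, "all_bonds": 51286, "n_residues": 10370,
             "printed": {"mm_mh": 20875, "frac_mm": 72.5, "frac_mh": 27.5}}
  }
}
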