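{
  "_comment": [
    "Proton chemical shifts (ppm, water-referenced at 4.65 ppm) and scalar",
    "coupling constants (Hz) for the bundled spin systems.",
    "GABA shifts follow the standard proton NMR compilation of brain",
    "metabolites (C2H2 2.284, C3H2 1.889, C4H2 3.0128 ppm); the J-coupling",
    "matrix uses the later refined measurement set (the one distributed",
    "with the common density-matrix simulation toolkits), whose unequal",
    "C4-C3 vicinal couplings are what give the edited 3.0-ppm multiplet",
    "its characteristic slow echo-time dependence.",
    "Lysine serves as the simulation surrogate for the J-coupled",
    "macromolecular resonances at ~1.7/~3.0 ppm; its delta-CH2/epsilon-CH2",
    "constants are the part that matters for co-editing and are listed to",
    "match the ~1.70/~3.03 ppm positions reported for that use.",
    "The matrices are symmetric with zero diagonal; geminal couplings",
    "between chemically equivalent protons are spectrally silent but kept",
    "for completeness."
  ],
  "systems": {
    "gaba": {
      "shifts_ppm": [3.0128, 3.0128, 1.889, 1.889, 2.284, 2.284],
      "group_labels": [
        "GABA-C4H2 3.01 ppm", "GABA-C4H2 3.01 ppm",
        "GABA-C3H2 1.89 ppm", "GABA-C3H2 1.89 ppm",
        "GABA-C2H2 2.28 ppm", "GABA-C2H2 2.28 ppm"
      ],
      "j_hz": [
        [0.0, -12.021, 5.372, 6.982, 0.0, 0.0],
        [-12.021, 0.0, 7.127, 6.707, 0.0, 0.0],
        [5.372, 7.127, 0.0, -13.121, 10.578, 7.678],
        [6.982, 6.707, -13.121, 0.0, 10.064, 6.98],
        [0.0, 0.0, 10.578, 10.064, 0.0, -10.744],
        [0.0, 0.0, 7.678, 6.98, -10.744, 0.0]
      ]
    },
    "lys": {
      "shifts_ppm": [3.7583, 1.9068, 1.8971, 1.4706, 1.5039, 1.7046, 1.7046, 3.0283, 3.0283],
      "group_labels": [
        "Lys-C2H 3.76 ppm",
        "Lys-C3H2 1.90 ppm", "Lys-C3H2 1.90 ppm",
        "Lys-C4H2 1.49 ppm", "Lys-C4H2 1.49 ppm",
        "Lys-C5H2 1.70 ppm", "Lys-C5H2 1.70 ppm",
        "Lys-C6H2 3.03 ppm", "Lys-C6H2 3.03 ppm"
      ],
      "j_hz": [
        [0.0, 5.742, 6.466, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [5.742, 0.0, -13.84, 8.33, 6.36, 0.0, 0.0, 0.0, 0.0],
        [6.466, -13.84, 0.0, 6.36, 8.33, 0.0, 0.0, 0.0, 0.0],
        [0.0, 8.33, 6.36, 0.0, -13.5, 7.93, 6.91, 0.0, 0.0],
        [0.0, 6.36, 8.33, -13.5, 0.0, 6.91, 7.93, 0.0, 0.0],
        [0.0, 0.0, 0.0, 7.93, 6.91, 0.0, -13.01, 7.57, 7.57],
        [0.0, 0.0, 0.0, 6.91, 7.93, -13.01, 0.0, 7.57, 7.57],
        [0.0, 0.0, 0.0, 0.0, 0.0, 7.57, 7.57, 0.0, -12.1],
        [0.0, 0.0, 0.0, 0.0, 0.0, 7.57, 7.57, -12.1, 0.0]
      ]
    }
  },
  "fragments": {
    "lys_fragment": {
      "parent": "lys",
      "proton_indices": [5, 6, 7, 8],
      "note": "delta-CH2 (1.70 ppm) / epsilon-CH2 (3.03 ppm) subsystem used for offset sweeps"
    }
  }
}
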