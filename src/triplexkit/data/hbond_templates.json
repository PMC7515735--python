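{
  "comment": "Initial third-strand hydrogen-bond templates per triplet type and bond class (H = Hoogsteen-like, RH = reverse-Hoogsteen-like). Each bond is [third-strand atom, duplex base role, duplex atom]; donor/acceptor roles are inferred from base chemistry. Keys are '<third>.<duplex purine>|<class>'. Variants are named recurring alternative patterns observed in trajectories.",
  "templates": {
    "C+.G|H": [["N3", "purine", "N7"], ["N4", "purine", "O6"]],
    "C+.G|RH": [["N3", "purine", "O6"], ["N4", "purine", "N7"]],
    "T.A|H": [["N3", "purine", "N7"], ["O4", "purine", "N6"]],
    "T.A|RH": [["N3", "purine", "N7"], ["O2", "purine", "N6"]],
    "G.G|H": [["N1", "purine", "O6"], ["N2", "purine", "N7"]],
    "G.G|RH": [["N1", "purine", "N7"], ["N2", "purine", "O6"]],
    "A.G|H": [["N6", "purine", "O6"]],
    "A.G|RH": [["N6", "purine", "N7"]],
    "A+.G|H": [["N1", "purine", "N7"], ["N6", "purine", "O6"]],
    "A+.G|RH": [["N1", "purine", "O6"], ["N6", "purine", "N7"]],
    "A.A|H": [["N6", "purine", "N7"], ["N7", "purine", "N6"]],
    "A.A|RH": [["N6", "purine", "N7"], ["N1", "purine", "N6"]],
    "G.A|H": [["N1", "purine", "N7"]],
    "G.A|RH": [["O6", "purine", "N6"]]
  },
  "variants": {
    "G.G": {
      "GG-O6N4-bridge": [["O6", "pyrimidine", "N4"], ["N1", "purine", "O6"]],
      "GG-bifurcated-O6": [["N1", "purine", "O6"], ["N2", "purine", "O6"]],
      "GG-bifurcated-N7": [["N1", "purine", "N7"], ["N2", "purine", "N7"]]
    },
    "A.A": {
      "AA-duplex-bridge": [["N6", "pyrimidine", "O4"], ["N1", "purine", "N6"]],
      "AA-N1N6": [["N1", "purine", "N6"]],
      "AA-T-only": [["N6", "pyrimidine", "O4"]]
    },
    "A+.G": {
      "A+G-N1O6": [["N1", "purine", "O6"], ["N6", "purine", "O6"]],
      "A+G-N1N7-only": [["N1", "purine", "N7"]]
    },
    "G.A": {
      "GA-bifurcated-N7": [["N1", "purine", "N7"], ["N2", "purine", "N7"]],
      "GA-O6N6-N2O4": [["O6", "purine", "N6"], ["N2", "pyrimidine", "O4"]]
    }
  }
}
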