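{
  "water_ethanol_transfer": {
    "description": "Side-chain transfer free energies from water to ethanol, kcal/mol (Nozaki-Tanford lineage). Negative = hydrophobic (transfer into ethanol favourable); charged side chains are assigned positive values. Editable.",
    "convention": "negative_hydrophobic",
    "units": "kcal/mol",
    "values": {
      "TRP": -3.40,
      "ILE": -2.97,
      "TYR": -2.87,
      "PHE": -2.65,
      "PRO": -2.60,
      "LEU": -2.42,
      "VAL": -1.69,
      "MET": -1.30,
      "CYS": -1.00,
      "ALA": -0.73,
      "HIS": -0.50,
      "THR": -0.44,
      "GLN": -0.10,
      "SER": -0.04,
      "ASN": -0.01,
      "GLY": 0.00,
      "LYS": 0.46,
      "ASP": 0.54,
      "GLU": 0.55,
      "ARG": 0.73
    }
  },
  "kyte_doolittle": {
    "description": "Kyte-Doolittle hydropathy index (dimensionless). Positive = hydrophobic.",
    "convention": "positive_hydrophobic",
    "units": "dimensionless",
    "values": {
      "ILE": 4.5,
      "VAL": 4.2,
      "LEU": 3.8,
      "PHE": 2.8,
      "CYS": 2.5,
      "MET": 1.9,
      "ALA": 1.8,
      "GLY": -0.4,
      "THR": -0.7,
      "SER": -0.8,
      "TRP": -0.9,
      "TYR": -1.3,
      "PRO": -1.6,
      "HIS": -3.2,
      "GLU": -3.5,
      "GLN": -3.5,
      "ASP": -3.5,
      "ASN": -3.5,
      "LYS": -3.9,
      "ARG": -4.5
    }
  }
}
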