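{
  "descriptors": ["nS", "GATS5s", "VR1_Dze", "ETA_dBetaP", "L3i"],
  "coefficients": [-0.124851343, -5.137570104, 0.000256939, 12.790319005, -0.173566533],
  "intercept": 6.319854761,
  "metadata": {
    "endpoint": "pIC50, cytotoxicity against the HCT116 colorectal carcinoma cell line",
    "chemical_series": "imidazol-5-ones",
    "training": "25-compound training set, GFA descriptor selection + MLR",
    "descriptors": {
      "nS": "number of sulfur atoms (2D atom count)",
      "GATS5s": "Geary autocorrelation, lag 5, weighted by intrinsic state (2D)",
      "VR1_Dze": "Randic-like eigenvector index from the Barysz matrix, Sanderson electronegativity weighted (2D)",
      "ETA_dBetaP": "extended topochemical atom measure of relative unsaturation content (2D)",
      "L3i": "3rd-component size directional WHIM index, first-ionization-potential weighted (3D)"
    }
  }
}
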