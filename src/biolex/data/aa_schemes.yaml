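# Published amino-acid colour schemes (hex tables as popularized by Jalview /
# ClustalX).  Gaps and X are unstyled and intentionally absent.
clustal:  # ClustalX default residue groups
  A: "#80a0f0"
  I: "#80a0f0"
  L: "#80a0f0"
  M: "#80a0f0"
  F: "#80a0f0"
  W: "#80a0f0"
  V: "#80a0f0"
  K: "#f01505"
  R: "#f01505"
  E: "#c048c0"
  D: "#c048c0"
  N: "#15c015"
  Q: "#15c015"
  S: "#15c015"
  T: "#15c015"
  C: "#f08080"
  G: "#f09048"
  P: "#c0c000"
  H: "#15a4a4"
  Y: "#15a4a4"
taylor:  # Taylor (1997) rainbow wheel
  A: "#ccff00"
  R: "#0000ff"
  N: "#cc00ff"
  D: "#ff0000"
  C: "#ffff00"
  Q: "#ff00cc"
  E: "#ff0066"
  G: "#ff9900"
  H: "#0066ff"
  I: "#66ff00"
  L: "#33ff00"
  K: "#6600ff"
  M: "#00ff00"
  F: "#00ff66"
  P: "#ffcc00"
  S: "#ff3300"
  T: "#ff6600"
  W: "#00ccff"
  Y: "#00ffcc"
  V: "#99ff00"
zappo:  # physicochemical groups
  I: "#ffafaf"
  L: "#ffafaf"
  V: "#ffafaf"
  A: "#ffafaf"
  M: "#ffafaf"
  F: "#ffc800"
  W: "#ffc800"
  Y: "#ffc800"
  K: "#6464ff"
  R: "#6464ff"
  H: "#6464ff"
  D: "#ff0000"
  E: "#ff0000"
  S: "#00ff00"
  T: "#00ff00"
  N: "#00ff00"
  Q: "#00ff00"
  P: "#ff00ff"
  G: "#ff00ff"
  C: "#ffff00"
hydrophobicity:  # Kyte-Doolittle scale mapped red (hydrophobic) -> blue
  I: "#ff0000"
  V: "#f60009"
  L: "#ea0015"
  F: "#cb0034"
  C: "#c2003d"
  M: "#b0004f"
  A: "#ad0052"
  G: "#6a0095"
  T: "#61009e"
  S: "#5e00a1"
  W: "#5b00a4"
  Y: "#4f00b0"
  P: "#4600b9"
  H: "#1500ea"
  E: "#0c00f3"
  Q: "#0c00f3"
  D: "#0c00f3"
  N: "#0c00f3"
  K: "#0000ff"
  R: "#0000ff"
  B: "#0c00f3"
  Z: "#0c00f3"
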