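# High-contrast theme: luminance-separated primaries that stay >= 0.15
# apart in relative luminance for {A,C,G,T,N} under simulated
# protanopia, deuteranopia and tritanopia.
name: high-contrast
mode: high-contrast
classes:
  aminoacid.A: {fg: "#80a0f0", bg: null, bold: false}
  aminoacid.B: null
  aminoacid.C: {fg: "#f08080", bg: null, bold: false}
  aminoacid.D: {fg: "#c048c0", bg: null, bold: false}
  aminoacid.E: {fg: "#c048c0", bg: null, bold: false}
  aminoacid.F: {fg: "#80a0f0", bg: null, bold: false}
  aminoacid.G: {fg: "#f09048", bg: null, bold: false}
  aminoacid.H: {fg: "#15a4a4", bg: null, bold: false}
  aminoacid.I: {fg: "#80a0f0", bg: null, bold: false}
  aminoacid.K: {fg: "#f01505", bg: null, bold: false}
  aminoacid.L: {fg: "#80a0f0", bg: null, bold: false}
  aminoacid.M: {fg: "#80a0f0", bg: null, bold: false}
  aminoacid.N: {fg: "#15c015", bg: null, bold: false}
  aminoacid.P: {fg: "#c0c000", bg: null, bold: false}
  aminoacid.Q: {fg: "#15c015", bg: null, bold: false}
  aminoacid.R: {fg: "#f01505", bg: null, bold: false}
  aminoacid.S: {fg: "#15c015", bg: null, bold: false}
  aminoacid.T: {fg: "#15c015", bg: null, bold: false}
  aminoacid.V: {fg: "#80a0f0", bg: null, bold: false}
  aminoacid.W: {fg: "#80a0f0", bg: null, bold: false}
  aminoacid.X: null
  aminoacid.Y: {fg: "#15a4a4", bg: null, bold: false}
  aminoacid.Z: null
  cigar.deletion: {fg: "#ff5f5f", bg: null, bold: false}
  cigar.eq: {fg: "#00af87", bg: null, bold: false}
  cigar.hard-clip: {fg: "#ff8700", bg: null, bold: false}
  cigar.insertion: {fg: "#ff5fff", bg: null, bold: false}
  cigar.match: {fg: "#00d700", bg: null, bold: false}
  cigar.mismatch: {fg: "#ff0087", bg: null, bold: true}
  cigar.pad: {fg: "#bcbcbc", bg: null, bold: false}
  cigar.skip: {fg: "#5f5fff", bg: null, bold: false}
  cigar.soft-clip: {fg: "#ffff5f", bg: null, bold: false}
  comment: {fg: "#808080", bg: null, bold: false}
  coordinate: {fg: "#00af5f", bg: null, bold: true}
  feature.cds: {fg: null, bg: "#005f00", bold: false}
  feature.start-codon: {fg: null, bg: "#005f5f", bold: false}
  feature.stop-codon: {fg: null, bg: "#5f0000", bold: false}
  feature.utr: {fg: null, bg: "#3a3a00", bold: false}
  flag: {fg: "#d78700", bg: null, bold: false}
  meta-key: {fg: "#5f87ff", bg: null, bold: false}
  meta-value: {fg: "#9e9e9e", bg: null, bold: false}
  nucleotide.A: {fg: "#6e8cd2", bg: null, bold: false}
  nucleotide.B: {fg: "#bc928b", bg: null, bold: false}
  nucleotide.C: {fg: "#d23719", bg: null, bold: false}
  nucleotide.D: {fg: "#a6a4b3", bg: null, bold: false}
  nucleotide.G: {fg: "#ebc369", bg: null, bold: false}
  nucleotide.H: {fg: "#a186a2", bg: null, bold: false}
  nucleotide.K: {fg: "#5c4d4d", bg: null, bold: false}
  nucleotide.M: {fg: "#784958", bg: null, bold: false}
  nucleotide.N: {fg: "#ffffff", bg: null, bold: false}
  nucleotide.R: {fg: "#aca89e", bg: null, bold: false}
  nucleotide.S: {fg: "#de7d41", bg: null, bold: false}
  nucleotide.T: {fg: "#0a0a64", bg: null, bold: false}
  nucleotide.U: {fg: "#282882", bg: null, bold: false}
  nucleotide.V: {fg: "#d2aea3", bg: null, bold: false}
  nucleotide.W: {fg: "#3c4b9b", bg: null, bold: false}
  nucleotide.Y: {fg: "#6e203e", bg: null, bold: false}
  quality.0: {fg: "#782828", bg: null, bold: false}
  quality.1: {fg: "#a05028", bg: null, bold: false}
  quality.2: {fg: "#be7832", bg: null, bold: false}
  quality.3: {fg: "#c8aa3c", bg: null, bold: false}
  quality.4: {fg: "#b4dc50", bg: null, bold: false}
  quality.5: {fg: "#8cff8c", bg: null, bold: false}
  read-name: {fg: "#5fd7d7", bg: null, bold: false}
  record-type: {fg: "#ffd700", bg: null, bold: true}
  sample-info: {fg: "#87d7ff", bg: null, bold: false}
  strand: {fg: "#d75fd7", bg: null, bold: true}
  unknown: null
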