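# Methods

## What the tool does

`biolex` is a display-layer lexer: it classifies byte spans of one line at a
time into biological style classes and re-emits the line with colour escapes
inserted at span boundaries. It never re-interprets data (no 0/1-based
coordinate conversion, no record validation, no BAM/BCF decoding — binary
formats are expected to arrive as text via `samtools view -h` or
`bcftools view`). Two invariants define correctness:

1. **Losslessness** — removing the escapes (or HTML tags) from the output
   recovers the input line exactly, so the tool is safe inside shell
   pipelines.
2. **Totality** — no input line raises; content that fits no rule is either
   left unstyled or classed `unknown`. A viewer must survive dirty data.

Lines are processed independently given a small carried state (header/body
flag, FASTQ phase 0–3, FASTA alphabet guess), so memory is O(1) in stream
length; the 100,000-line SAM benchmark in the acceptance script runs at
roughly 7–9 k lines/s on one CPU with a flat high-water mark.

## The style-class system

Classes form a closed, enumerable set (68 members): structural classes
(`record-type`, `meta-key`, `meta-value`, `comment`, `unknown`), biological
classes shared across formats (`coordinate`, `read-name`, `sample-info`,
`flag`, `strand`), per-operator CIGAR classes, `nucleotide.<code>` for all
16 IUPAC codes, `aminoacid.<res>` for the 20 standard residues plus B/Z/X,
six `quality.<bin>` gradient classes, and four background-styled
`feature.*` classes for GTF coding annotations. Unification is deliberate:
chromosome/position fields of BED, GTF, SAM and VCF all carry `coordinate`,
so one learned colour transfers across formats.

Assignments the upstream format specifications do not pin down were chosen
here and are listed so they are not mistaken for format semantics: SAM TLEN,
VCF FILTER, GTF source/frame, PDB serial/occupancy → `meta-value`; VCF ID
(rsID-like) → `read-name`; all SAM optional-field values regardless of type
letter → `meta-value`; SAM `=`/`.` in SEQ → the fully-ambiguous
`nucleotide.N` class (keeps the nucleotide class set equal to the IUPAC
set).

GTF lines whose feature is CDS/UTR/start_codon/stop_codon are tinted across
the whole line: the gap spans (tabs and uncovered bytes) receive the
background-only `feature.*` class while field tokens keep their own classes.
This keeps tokens sorted and non-overlapping while visually separating
protein-coding annotation rows.

## Quality gradients

All score-like fields reuse one six-bin gradient
(`bin = min(floor(norm × 6), 5)`) whose theme colours rise strictly in
relative luminance. Normalizations, per field:

| field | normalization | rationale |
|---|---|---|
| SAM MAPQ | /60, capped | common aligner maximum |
| per-base PHRED (FASTQ, SAM QUAL) | /40, capped | Illumina-era 0–40 range |
| BED, GTF score | /1000 | format-defined 0–1000 range |
| VCF QUAL | /100, capped | typical working range |
| PDB B-factor | /100, capped | typical crystallographic range |

The per-base PHRED divisor is this package's choice; only ordering within
the gradient matters for display. PHRED decoding supports offsets 33 and 64.

## Nucleotide colour model

Primaries (default theme): A `#00c840` (cool green), C `#ff0000` (warm
red), G `#ffb000` (warm orange), T `#0000ff` (cool blue). Ambiguity codes
are the channel-wise arithmetic mean of their members ("approximate"
additive mixing); N is fixed white. Because a 4-dimensional base space must
fold into 3 colour channels, the two-base aMino (M = A/C) and Keto
(K = G/T) codes are darkened by d = 0.75 and the three-base codes lightened
toward white by l = 0.35, giving the "increasingly lighter with increasing
ambiguity" reading one consistent quantification. d and l are config
constants in `palette.py`.

A theme's nucleotide set is valid when (i) N is white, (ii) G and C are
warm (`r > b`) and A and T cool (`r < b`), (iii) M and K are darker than
the mean of their parents, and (iv) all 16 codes are pairwise distinct.
`validate_nucleotide_theme` returns violations as data; both shipped themes
return none. One subtlety: mixing maps U onto the T primary (U ≡ T
biologically), which would violate (iv) if themes used raw mixing output, so
the shipped themes give `nucleotide.U` its own lighter-blue tint — mixing
semantics and display distinctness live at different layers.

Warmth is operationalized as `(r − b)/255`, the minimal definition that
makes the GC-content claim testable: mean sequence warmth is strictly
increasing in GC fraction (checked over seeded random 20-mers at GC 0,
0.25, 0.5, 0.75, 1). Relative luminance is the sRGB-weighted sum
`0.2126 r + 0.7152 g + 0.0722 b` without linearization — adequate for the
ordering and contrast checks used here, and much simpler; nothing in the
package depends on photometric accuracy.

## High-contrast theme and dichromacy

The high-contrast primaries were chosen by luminance spacing: A `#6e8cd2`
(0.54), C `#d23719` (0.34), G `#ebc369` (0.77), T `#0a0a64` (0.07), N white
(1.0). Under each of the three dichromacy simulations (Machado, Oliveira &
Fernandes 2009 severity-1.0 matrices, shipped as YAML config) the five
luminances stay pairwise ≥ 0.15 apart; the worst margin is 0.154
(deuteranopia, C vs A). The simulation is a 3×3 linear RGB transform with
channel clamping; its rows sum to ≈1, so grays are fixed points — the only
property the test suite relies on beyond the published values.

ANSI output uses the xterm-256 palette only in the range 16–255 (the 16
system colours are terminal-theme dependent); the mapping from RGB is
nearest-neighbour in Euclidean RGB over the 6×6×6 cube plus the 24-step
gray ramp, ties to the lowest index, and is verified against an exhaustive
scan.

## Amino-acid schemes

Protein residues can be coloured by the ClustalX group scheme (default in
the shipped themes), Taylor's rainbow wheel, Zappo physicochemical groups,
or a Kyte–Doolittle hydrophobicity ramp; the hex tables ship as YAML config.
Gaps and X are always unstyled; B/Z are unstyled where a scheme's table
omits them. `--aa-scheme` swaps the `aminoacid.*` entries of the active
theme at load time.

## Synthetic fixtures

The fixture generators exist so the whole test surface needs no downloads:
each produces a structurally valid file fully determined by
(format, params, seed). They emulate the features the lexers exercise —
IUPAC-ambiguous bases at a 2% default rate, per-position PHRED decay
(~38 → ~18 across the read with σ = 2 noise), PCR-duplicate reads in SAM
(identical POS+SEQ, 0x400 flag set, at a configurable fraction), coding and
non-coding GTF features, fixed-column PDB ATOM records, and a CLUSTAL
conservation line. They do **not** emulate biological realism: no reference
genome, no mate-pair consistency, no linkage between coordinates and
sequence. Passing tests therefore demonstrate format-level correctness of
lexing and rendering, not behaviour on every real-world corner case (e.g.
exotic SAM optional-field types are all displayed as generic metadata).

Default sizes (e.g. 30 SAM records of 50 bp, 15 VCF records, 12 GTF
features) keep fixture files small; the streaming benchmark scales the SAM
generator to 100,000 lines at run time.

## Numerical and degenerate-input choices

- Offsets index the decoded line (UTF-8 with surrogate-escape); for these
  ASCII-structured formats this equals byte offsets, and non-ASCII payload
  is passed through without ever being split inside a token.
- A trailing `\r` is excluded from all tokens and emitted unstyled.
- `*` placeholders (SAM CIGAR/SEQ/QUAL, `.` scores) are left unstyled
  rather than classed `unknown` — absence is not an error.
- Headerless SAM: the stream simply starts in body mode at the first
  non-`@` line; the header flag can never turn back on.
- Empty `--no-color` output equals input byte-for-byte, including through
  gzip decompression.
- Tie-breaks: quality binning clamps 1.0 into the top bin; ANSI-256 ties
  resolve to the lowest palette index.

## Known limitations

- GFF3, BAM/BCF/CRAM and tabix-indexed access are out of scope by design.
- PDB support covers the common record types lexically (fixed columns for
  ATOM/HETATM); it is not a structure parser.
- The CLUSTAL lexer colours residues with amino-acid classes even for
  nucleotide alignments.
- HTML output is per-line spans inside a `<pre>`; it targets documentation
  snippets, not a full web viewer.
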