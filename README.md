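# biolex

Streaming syntax highlighting for the plain-text file formats of
computational biology: **FASTA, FASTQ, SAM, VCF, BED, GTF, PDB and
CLUSTAL**, rendered as ANSI-coloured terminal output (pager-friendly) or
HTML.

Low-level biological files are easy for machines to parse and hard for
humans to read: an alignment header, a CIGAR string like `37M1I12M5S`, or a
wall of PHRED quality characters all hide structure in undifferentiated
text. `biolex` tokenizes each line into a small set of *biological* style
classes that are shared across formats — genomic coordinates are one class
(and one colour, dark green) whether they come from BED, GTF, SAM or VCF —
so experience reading one format transfers to the others.

## The colour model

**IUPAC nucleotides by additive mixing.** The four primary bases get two
contrasting colour pairs — strong bases G, C warm (orange, red), weak bases
A, T cool (green, blue) — and every ambiguity code is the channel-wise mean
of its members: R = {A,G} mixes to `#80bc20`, Y = {C,T} to magenta, and the
"any base" N is white. The two aMino/Keto codes (M, K) are darkened by a
factor 0.75 and three-base codes lightened toward white by 0.35, so
increasing ambiguity reads as increasingly lighter tone. Because warm maps
to GC and cool to AT, the overall warmth of a coloured sequence approximates
its GC content at a glance:

```
GCGCGCGCGC  warmth =  1.0
ACGTACGTNN  warmth =  0.15
ATATATATAT  warmth = -0.625
```

(warmth of a colour is `(r − b)/255`; sequence warmth is the mean over
bases).

**Gradients for scores.** PHRED base qualities, mapping qualities, BED/GTF
scores, VCF QUAL and PDB B-factors are normalized to [0, 1] and binned into
a six-step gradient whose luminance rises strictly with the score, so poor
quality regions form visibly dark blocks.

**CIGAR deconstruction.** Alignment CIGARs are split into per-operator
tokens (`10M`, `3D`, `10M` each coloured by operator class), e.g.
`parse_cigar("10M1I5M2S") → [(10,M), (1,I), (5,M), (2,S)]`.

**Accessibility.** Besides the default theme there is a high-contrast theme
whose five core colours {A, C, G, T, N} keep a pairwise relative-luminance
separation ≥ 0.15 — verified both as-is and under simulated protanopia,
deuteranopia and tritanopia (Machado et al. 2009 matrices) — so bases stay
distinguishable even at the monochrome level.

## Usage

```sh
samtools view -h sample.bam | sam-less -
gzip -dc gencode.v26.gtf.gz | grep MYC - | gtf-less -x 10
biolex variants.vcf.gz                  # format detected, gzip transparent
biolex --theme high-contrast reads.fq
biolex --aa-scheme taylor proteins.faa  # clustal, taylor, zappo, hydrophobicity
biolex --html alignment.sam > alignment.html
biolex --no-color x.sam                 # identity: emits the input unchanged
biolex fixtures sam --seed 1 -o demo.sam   # seeded synthetic example files
```

When stdout is an interactive terminal the output is piped through
`less -R`; in a pipeline the ANSI text streams straight through. Format
comes from the file extension when available, otherwise from content
sniffing; `--format/-f` forces it. The `*-less` aliases (`sam-less`,
`vcf-less`, `gtf-less`, `bed-less`, `fa-less`, `fq-less`, `pdb-less`,
`aln-less`) preset the format.

## Worked example

```python
from biolex import generate_fixture, lex_line, load_theme, render_ansi
from biolex.core import FormatId, LexState

sam = generate_fixture(FormatId.SAM, {"n_records": 2, "read_length": 20}, seed=1)
state = LexState(format=FormatId.SAM)
for line in sam.splitlines():
    tokens, state = lex_line(state, line)
    print(render_ansi(line, tokens, load_theme("default")))
```

The last body line
`read2 0 chr1 394957 27 10M3D10M = 394957 0 TATTTGACG...` tokenizes as

```
(0, 5)   'read2'   -> read-name
(6, 7)   '0'       -> flag
(8, 12)  'chr1'    -> coordinate
(13, 19) '394957'  -> coordinate
(20, 22) '27'      -> quality.2      # MAPQ 27/60 -> gradient bin 2
(23, 26) '10M'     -> cigar.match
(26, 28) '3D'      -> cigar.deletion
(28, 31) '10M'     -> cigar.match
```

followed by one token per base (`nucleotide.T`, `nucleotide.A`, ...) and one
gradient token per quality character. Stripping the ANSI escapes from the
rendered line always recovers the input byte-for-byte.

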