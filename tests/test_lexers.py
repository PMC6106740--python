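"""Lexers: detection, alphabet sniffing, CIGAR grammar, per-line tokenization."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from biolex.core import FormatId, LexState, Token
from biolex.lexers import detect_format, lex_line, parse_cigar, sniff_alphabet

ALL_FORMATS = [f for f in FormatId if f is not FormatId.PLAIN]


# ---------------------------------------------------------------------------
# detect_format
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "path,lines,expected",
    [
        ("NA12878.sam", None, FormatId.SAM),
        ("x.vcf.gz", None, FormatId.VCF),
        ("reads.FASTQ", None, FormatId.FASTQ),
        ("genome.fna", None, FormatId.FASTA),
        ("model.ent", None, FormatId.PDB),
        ("aln.clustal", None, FormatId.CLUSTAL),
        (None, ["##fileformat=VCFv4.2"], FormatId.VCF),
        (None, ["@HD\tVN:1.5"], FormatId.SAM),
        (None, ["CLUSTAL W (1.2.4) multiple sequence alignment"], FormatId.CLUSTAL),
        (None, [">chr1", "ACGT"], FormatId.FASTA),
        (None, ["@r1", "ACGT", "+", "IIII"], FormatId.FASTQ),
        (None, ["HEADER    HYDROLASE"], FormatId.PDB),
        (None, ["chr1\t100\t200\tx\t0\t+"], FormatId.BED),
        (None, ["chr1\tsrc\texon\t1\t50\t.\t+\t.\tgene_id \"g\";"], FormatId.GTF),
        ("notes.txt", ["hello"], FormatId.PLAIN),
        (None, ["just words"], FormatId.PLAIN),
    ],
)
def test_detect_format(path, lines, expected):
    assert detect_format(path, lines) is expected


def test_extension_wins_over_content():
    assert detect_format("x.bed", ["##fileformat=VCFv4.2"]) is FormatId.BED


# ---------------------------------------------------------------------------
# sniff_alphabet
# ---------------------------------------------------------------------------


def test_sniff_alphabet():
    assert sniff_alphabet(["ACGTACGTNN"]) == "nucleotide"
    assert sniff_alphabet(["MKVLWAALLVTFLAGCQA"]) == "aminoacid"
    assert sniff_alphabet(["ACGT", "WWWW"]) == "aminoacid"  # 4/8 < 0.90
    assert sniff_alphabet(["acgu-n..."]) == "nucleotide"
    with pytest.raises(ValueError):
        sniff_alphabet(["---", "  "])


# ---------------------------------------------------------------------------
# parse_cigar
# ---------------------------------------------------------------------------


def test_parse_cigar_examples():
    assert parse_cigar("4M") == [(4, "M")]
    assert parse_cigar("*") == []
    assert parse_cigar("10M1I5M2S") == [(10, "M"), (1, "I"), (5, "M"), (2, "S")]


@pytest.mark.parametrize("bad", ["MM", "10", "3Q", "", "4M5", "M4", "1.5M"])
def test_parse_cigar_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_cigar(bad)


def test_parse_cigar_error_names_offset():
    with pytest.raises(ValueError, match="offset 2"):
        parse_cigar("4MM5I")


@given(
    st.lists(
        st.tuples(st.integers(1, 9999), st.sampled_from("MIDNSHP=X")),
        min_size=1,
        max_size=20,
    )
)
@settings(max_examples=200, derandomize=True)
def test_cigar_roundtrip(ops):
    s = "".join(f"{n}{op}" for n, op in ops)
    assert [(o.length, o.op) for o in parse_cigar(s)] == ops


# ---------------------------------------------------------------------------
# lex_line: format-specific assignments
# ---------------------------------------------------------------------------


def lex_all(fmt, text):
    state = LexState(format=fmt)
    out = []
    for line in text.splitlines():
        toks, state = lex_line(state, line)
        out.append((line, toks))
    return out


def test_sam_header_token_offsets():
    state = LexState(format=FormatId.SAM)
    toks, new_state = lex_line(state, "@SQ\tSN:chr1\tLN:248956422")
    assert toks == [
        Token(0, 3, "record-type"),
        Token(4, 6, "meta-key"),
        Token(7, 11, "meta-value"),
        Token(12, 14, "meta-key"),
        Token(15, 24, "meta-value"),
    ]
    assert new_state.in_header


def test_sam_rg_values_are_sample_info():
    state = LexState(format=FormatId.SAM)
    toks, _ = lex_line(state, "@RG\tID:rg1\tSM:patient1")
    classes = {line_cls for _, _, line_cls in toks}
    assert "sample-info" in classes


def test_sam_body_cigar_deconstruction():
    line = "r1\t0\tchr1\t100\t60\t8M2I4M\t=\t100\t0\tACGTACGTACGTAC\t" + "I" * 14
    state = LexState(format=FormatId.SAM, in_header=False)
    toks, _ = lex_line(state, line)
    cigar_toks = [t for t in toks if t.cls.startswith("cigar.")]
    assert [t.cls for t in cigar_toks] == [
        "cigar.match", "cigar.insertion", "cigar.match",
    ]
    assert [line[t.start : t.end] for t in cigar_toks] == ["8M", "2I", "4M"]


def test_sam_body_field_classes():
    line = "r1\t16\tchr2\t500\t30\t4M\t=\t520\t24\tACGN\t!!~I\tNM:i:2"
    state = LexState(format=FormatId.SAM, in_header=False)
    toks, _ = lex_line(state, line)
    by_text = {line[t.start : t.end]: t.cls for t in toks}
    assert by_text["r1"] == "read-name"
    assert by_text["16"] == "flag"
    assert by_text["chr2"] == "coordinate"
    assert by_text["500"] == "coordinate"
    assert by_text["30"] == "quality.3"  # 30/60 -> bin 3
    assert by_text["N"] == "nucleotide.N"
    assert by_text["NM"] == "meta-key"
    # per-char QUAL: '!' is PHRED 0 -> bin 0, '~' caps at top bin
    qual_classes = [t.cls for t in toks if t.start >= line.index("!!~I")]
    assert qual_classes[:4] == ["quality.0", "quality.0", "quality.5", "quality.5"]


def test_sam_header_state_never_reenters():
    state = LexState(format=FormatId.SAM)
    _, state = lex_line(state, "@HD\tVN:1.5")
    assert state.in_header
    _, state = lex_line(state, "r1\t0\tchr1\t1\t0\t*\t*\t0\t0\t*\t*")
    assert not state.in_header
    _, state = lex_line(state, "@HD\tVN:1.5")  # '@' line in body stays body
    assert not state.in_header


def test_fasta_per_base_tokens():
    state = LexState(format=FormatId.FASTA, fasta_alphabet="nucleotide")
    toks, _ = lex_line(state, "ACGN")
    assert toks == [
        Token(0, 1, "nucleotide.A"),
        Token(1, 2, "nucleotide.C"),
        Token(2, 3, "nucleotide.G"),
        Token(3, 4, "nucleotide.N"),
    ]


def test_fasta_alphabet_sniffed_from_first_sequence_line():
    state = LexState(format=FormatId.FASTA)
    _, state = lex_line(state, ">prot1")
    assert state.fasta_alphabet == "undetermined"
    toks, state = lex_line(state, "MKVLWAALLVTFLAGCQA")
    assert state.fasta_alphabet == "aminoacid"
    assert toks[0].cls == "aminoacid.M"


def test_fastq_phase_cycle():
    state = LexState(format=FormatId.FASTQ)
    lines = ["@r1", "ACGT", "+", "II!~", "@r2"]
    classes = []
    for ln in lines:
        toks, state = lex_line(state, ln)
        classes.append(toks[0].cls if toks else None)
    assert classes[0] == "read-name"
    assert classes[1] == "nucleotide.A"
    assert classes[2] == "comment"
    assert classes[3].startswith("quality.")
    assert classes[4] == "read-name"  # phase wrapped 3 -> 0


def test_vcf_header_and_body_classes():
    state = LexState(format=FormatId.VCF)
    toks, state = lex_line(state, "##fileformat=VCFv4.2")
    assert toks[0].cls == "meta-key" and toks[1].cls == "meta-value"
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    toks, state = lex_line(state, header)
    assert toks == [Token(0, len(header), "record-type")]
    line = "chr1\t123\trs99\tA\tG\t50\tPASS\tDP=10;AF=0.5\tGT\t0/1"
    toks, state = lex_line(state, line)
    assert not state.in_header
    by_text = {line[t.start : t.end]: t.cls for t in toks}
    assert by_text["chr1"] == "coordinate"
    assert by_text["123"] == "coordinate"
    assert by_text["rs99"] == "read-name"
    assert by_text["A"] == "nucleotide.A"
    assert by_text["G"] == "nucleotide.G"
    assert by_text["DP"] == "meta-key"
    assert by_text["10"] == "meta-value"
    assert by_text["0/1"] == "sample-info"
    assert by_text["GT"] == "sample-info"


def test_bed_field_classes():
    line = "chr7\t1000\t2000\tpeak1\t500\t+"
    toks, _ = lex_line(LexState(format=FormatId.BED), line)
    assert [t.cls for t in toks] == [
        "coordinate", "coordinate", "coordinate",
        "read-name", "quality.3", "strand",
    ]


def test_gtf_coding_line_gets_background_fill():
    line = 'chr1\tsrc\tCDS\t10\t50\t.\t+\t0\tgene_id "g1";'
    toks, _ = lex_line(LexState(format=FormatId.GTF), line)
    # gaps (tabs) carry the feature class so the whole line is tinted
    covered = sum(t.end - t.start for t in toks)
    assert covered == len(line)
    assert any(t.cls == "feature.cds" for t in toks)
    # a non-coding feature line keeps gaps unstyled
    line2 = 'chr1\tsrc\texon\t10\t50\t.\t+\t.\tgene_id "g1";'
    toks2, _ = lex_line(LexState(format=FormatId.GTF), line2)
    assert sum(t.end - t.start for t in toks2) < len(line2)


def test_pdb_atom_columns():
    line = (
        f"ATOM  {1:5d}  {'N':<3s} {'ALA':>3s} A{1:4d}    "
        f"{11.104:8.3f}{6.134:8.3f}{-6.504:8.3f}{1.0:6.2f}{45.0:6.2f}"
        f"          {'N':>2s}  "
    )
    toks, _ = lex_line(LexState(format=FormatId.PDB), line)
    by_span = {(t.start, t.end): t.cls for t in toks}
    assert by_span[(0, 4)] == "record-type"
    assert any(cls.startswith("quality.") for cls in by_span.values())  # B-factor
    texts = {line[s:e]: c for (s, e), c in by_span.items()}
    assert texts["N"] in ("meta-key",)  # atom name or element
    assert texts["ALA"] == "meta-value"


def test_clustal_rows():
    state = LexState(format=FormatId.CLUSTAL)
    toks, state = lex_line(state, "CLUSTAL W (1.2.4) multiple sequence alignment")
    assert toks[0].cls == "record-type"
    toks, state = lex_line(state, "")
    assert toks == []
    line = "seq1      MKVL-WA 7"
    toks, state = lex_line(state, line)
    assert toks[0] == Token(0, 4, "read-name")
    residue_classes = [t.cls for t in toks if t.cls.startswith("aminoacid.")]
    assert residue_classes == [f"aminoacid.{c}" for c in "MKVLWA"]
    toks, state = lex_line(state, "          **:. * ")
    assert toks[0].cls == "comment"


def test_crlf_excluded_from_tokens():
    state = LexState(format=FormatId.FASTA, fasta_alphabet="nucleotide")
    toks, _ = lex_line(state, "ACGT\r")
    assert toks[-1].end == 4


def test_plain_format_refused():
    with pytest.raises(ValueError):
        lex_line(LexState(format=FormatId.PLAIN), "x")


# ---------------------------------------------------------------------------
# Totality and token validity under fuzz
# ---------------------------------------------------------------------------


def assert_valid_tokens(line, toks):
    prev = 0
    for t in toks:
        assert 0 <= t.start < t.end <= len(line), (line, t)
        assert t.start >= prev, (line, toks)
        prev = t.end


@given(
    fmt=st.sampled_from(ALL_FORMATS),
    line=st.text(
        alphabet=st.characters(min_codepoint=0, max_codepoint=0x2FF),
        max_size=200,
    ),
)
@settings(max_examples=300, derandomize=True)
def test_lexer_totality_and_token_validity(fmt, line):
    """No input line raises; tokens are sorted, non-overlapping, in bounds."""
    state = LexState(format=fmt)
    toks, new_state = lex_line(state, line)
    assert_valid_tokens(line[:-1] if line.endswith("\r") else line, toks)
    assert isinstance(new_state, LexState)


def test_coordinate_class_unified_across_formats(fixture_texts):
    """Chromosome/position fields lex to the one shared coordinate class."""
    for fmt in (FormatId.BED, FormatId.GTF, FormatId.SAM, FormatId.VCF):
        classes = set()
        for _, toks in lex_all(fmt, fixture_texts[fmt]):
            classes.update(t.cls for t in toks)
        assert "coordinate" in classes, fmt
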