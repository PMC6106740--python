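"""Format detection and per-line tokenization.

Each lexer maps one raw line to a sorted, non-overlapping list of
:class:`~biolex.core.Token` spans, carrying a :class:`~biolex.core.LexState`
between lines (header vs body, FASTQ phase, FASTA alphabet).  Lexers never
raise on malformed content — a viewer must not crash on dirty data — the
worst case is an ``unknown`` token.  Uncovered spans render unstyled.

Field-to-class assignment deliberately unifies biological meaning across
formats: chromosome/position fields in BED, GTF, SAM and VCF all carry the
single ``coordinate`` class.
"""

from __future__ import annotations

import re
from typing import Iterator, List, Optional, Sequence, Tuple

from .core import CIGAR_CLASS, FormatId, LexState, Token
from .palette import IUPAC_BASES, phred_score, quality_bin

__all__ = [
    "CigarOp",
    "detect_format",
    "sniff_alphabet",
    "parse_cigar",
    "lex_line",
]


# ---------------------------------------------------------------------------
# Format detection
# ---------------------------------------------------------------------------

_EXT_MAP = {
    ".fa": FormatId.FASTA,
    ".fasta": FormatId.FASTA,
    ".fna": FormatId.FASTA,
    ".faa": FormatId.FASTA,
    ".fq": FormatId.FASTQ,
    ".fastq": FormatId.FASTQ,
    ".sam": FormatId.SAM,
    ".vcf": FormatId.VCF,
    ".bed": FormatId.BED,
    ".gtf": FormatId.GTF,
    ".pdb": FormatId.PDB,
    ".ent": FormatId.PDB,
    ".aln": FormatId.CLUSTAL,
    ".clustal": FormatId.CLUSTAL,
}

_SAM_HEADER_RE = re.compile(r"^@(HD|SQ|RG|PG|CO)\t")
_PDB_RECORDS = ("HEADER", "ATOM  ", "HETATM", "TITLE ", "COMPND", "REMARK")


def detect_format(
    path_hint: Optional[str] = None,
    first_lines: Optional[Sequence[str]] = None,
) -> FormatId:
    """Guess the stream format from a filename and/or its first lines.

    Extension wins (a trailing ``.gz`` is stripped first); otherwise the
    content is sniffed; PLAIN is the fallback and no input ever raises.
    """
    if path_hint:
        name = path_hint.lower()
        if name.endswith(".gz"):
            name = name[:-3]
        dot = name.rfind(".")
        if dot != -1 and name[dot:] in _EXT_MAP:
            return _EXT_MAP[name[dot:]]
    lines = [ln for ln in (first_lines or []) if ln]
    if not lines:
        return FormatId.PLAIN
    first = lines[0]
    if first.startswith("##fileformat=VCF") or first.startswith("#CHROM\t"):
        return FormatId.VCF
    if first.startswith("CLUSTAL"):
        return FormatId.CLUSTAL
    if _SAM_HEADER_RE.match(first):
        return FormatId.SAM
    if any(first.startswith(rec) for rec in _PDB_RECORDS):
        return FormatId.PDB
    if first.startswith(">"):
        return FormatId.FASTA
    if (
        first.startswith("@")
        and len(lines) >= 3
        and lines[2].startswith("+")
        and not lines[1].startswith("@")
    ):
        return FormatId.FASTQ
    fields = first.split("\t")
    if len(fields) >= 8 and _is_int(fields[3]) and _is_int(fields[4]):
        return FormatId.GTF
    if len(fields) >= 3 and _is_int(fields[1]) and _is_int(fields[2]):
        return FormatId.BED
    if first.startswith("##"):
        return FormatId.VCF
    return FormatId.PLAIN


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# FASTA alphabet sniffing
# ---------------------------------------------------------------------------

_NT_CHARS = frozenset("ACGTUNacgtun")
_GAP_WS = frozenset("-.* \t\r\n")


def sniff_alphabet(sequence_lines: Sequence[str]) -> str:
    """Classify sequence content as ``nucleotide`` or ``aminoacid``.

    Looks at up to the first 10,000 residue characters (gaps and whitespace
    ignored); nucleotide iff >= 90% fall in {A,C,G,T,U,N} (either case).
    """
    seen = 0
    nt = 0
    for line in sequence_lines:
        for ch in line:
            if ch in _GAP_WS:
                continue
            seen += 1
            if ch in _NT_CHARS:
                nt += 1
            if seen >= 10000:
                break
        if seen >= 10000:
            break
    if seen == 0:
        raise ValueError("no residue characters to sniff")
    return "nucleotide" if nt / seen >= 0.90 else "aminoacid"


# ---------------------------------------------------------------------------
# CIGAR
# ---------------------------------------------------------------------------


class CigarOp(Tuple[int, str]):
    """(length, op) pair; op is one of M I D N S H P = X."""

    __slots__ = ()

    def __new__(cls, length: int, op: str):
        return super().__new__(cls, (length, op))

    @property
    def length(self) -> int:
        return self[0]

    @property
    def op(self) -> str:
        return self[1]


_CIGAR_TOKEN_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> List[CigarOp]:
    """Decompose a CIGAR string into ops; ``*`` (unavailable) gives ``[]``.

    Raises ValueError naming the offending offset for anything that does not
    match the ``(<int><op>)+`` grammar.
    """
    if not cigar:
        raise ValueError("empty CIGAR string")
    if cigar == "*":
        return []
    ops: List[CigarOp] = []
    pos = 0
    for m in _CIGAR_TOKEN_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR {cigar!r} at offset {pos}")
        length = int(m.group(1))
        if length < 1:
            raise ValueError(f"zero-length CIGAR op at offset {m.start()}")
        ops.append(CigarOp(length, m.group(2)))
        pos = m.end()
    if pos != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r} at offset {pos}")
    return ops


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------


def _fields(line: str, start: int = 0, end: Optional[int] = None) -> Iterator[Tuple[int, int, str]]:
    """Yield (start, end, text) for tab-separated fields of line[start:end]."""
    if end is None:
        end = len(line)
    pos = start
    while pos <= end:
        nxt = line.find("\t", pos, end)
        if nxt == -1:
            yield pos, end, line[pos:end]
            return
        yield pos, nxt, line[pos:nxt]
        pos = nxt + 1


_AA_CLASS_SET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX")


def _seq_tokens(out: List[Token], start: int, text: str, alphabet: str) -> None:
    """Per-residue tokens for a sequence span; gaps unstyled, junk -> unknown."""
    if alphabet == "nucleotide":
        for i, ch in enumerate(text):
            c = ch.upper()
            if c in IUPAC_BASES:
                out.append(Token(start + i, start + i + 1, "nucleotide." + c))
            elif c in "=.":
                out.append(Token(start + i, start + i + 1, "nucleotide.N"))
            elif ch in "-* ":
                continue
            else:
                out.append(Token(start + i, start + i + 1, "unknown"))
    else:
        for i, ch in enumerate(text):
            c = ch.upper()
            if c in _AA_CLASS_SET:
                out.append(Token(start + i, start + i + 1, "aminoacid." + c))
            elif ch in "-.* ":
                continue
            else:
                out.append(Token(start + i, start + i + 1, "unknown"))


def _qual_char_tokens(out: List[Token], start: int, text: str) -> None:
    """Per-character PHRED+33 gradient tokens (base-quality scale /40)."""
    for i, ch in enumerate(text):
        o = ord(ch)
        if o < 33 or o > 126:
            out.append(Token(start + i, start + i + 1, "unknown"))
        else:
            b = quality_bin(min((o - 33) / 40.0, 1.0))
            out.append(Token(start + i, start + i + 1, f"quality.{b}"))


def _score_bin_token(
    out: List[Token], start: int, end: int, text: str, divisor: float
) -> None:
    """One gradient token for a numeric score field; '.'/'*' unstyled."""
    t = text.strip()
    if t in (".", "*", ""):
        return
    try:
        v = float(t)
    except ValueError:
        out.append(Token(start, end, "unknown"))
        return
    b = quality_bin(min(max(v, 0.0) / divisor, 1.0))
    out.append(Token(start, end, f"quality.{b}"))


def _stripped_span(line: str, start: int, end: int) -> Optional[Tuple[int, int]]:
    """Trim spaces off a column range; None if blank or out of line."""
    end = min(end, len(line))
    if start >= end:
        return None
    while start < end and line[start] == " ":
        start += 1
    while end > start and line[end - 1] == " ":
        end -= 1
    if start >= end:
        return None
    return start, end


# ---------------------------------------------------------------------------
# Per-format lexers
# ---------------------------------------------------------------------------


def _lex_sam_header(line: str, out: List[Token]) -> None:
    rec = line[:3]
    out.append(Token(0, min(3, len(line)), "record-type"))
    if rec == "@CO":
        if len(line) > 4:
            out.append(Token(4, len(line), "comment"))
        return
    is_rg = rec == "@RG"
    for start, end, text in _fields(line, 4):
        if start >= end:
            continue
        colon = text.find(":")
        if colon >= 1:
            out.append(Token(start, start + colon, "meta-key"))
            if start + colon + 1 < end:
                value_cls = "sample-info" if is_rg else "meta-value"
                out.append(Token(start + colon + 1, end, value_cls))
        else:
            out.append(Token(start, end, "unknown"))


_SAM_OPT_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]:[AifZHB]:")


def _lex_sam_body(line: str, out: List[Token]) -> None:
    for idx, (start, end, text) in enumerate(_fields(line)):
        if start >= end:
            continue
        col = idx + 1
        if col == 1:
            out.append(Token(start, end, "read-name"))
        elif col == 2:
            out.append(Token(start, end, "flag"))
        elif col in (3, 4, 7, 8):
            out.append(Token(start, end, "coordinate"))
        elif col == 5:
            _score_bin_token(out, start, end, text, 60.0)
        elif col == 6:
            if text == "*":
                continue
            try:
                ops = parse_cigar(text)
            except ValueError:
                out.append(Token(start, end, "unknown"))
                continue
            pos = start
            for op in ops:
                w = len(str(op.length)) + 1
                out.append(Token(pos, pos + w, CIGAR_CLASS[op.op]))
                pos += w
        elif col == 9:
            out.append(Token(start, end, "meta-value"))  # TLEN
        elif col == 10:
            if text != "*":
                _seq_tokens(out, start, text, "nucleotide")
        elif col == 11:
            if text != "*":
                _qual_char_tokens(out, start, text)
        else:  # optional TAG:TYPE:VALUE fields
            if _SAM_OPT_RE.match(text):
                out.append(Token(start, start + 2, "meta-key"))
                out.append(Token(start + 3, start + 4, "meta-value"))
                if start + 5 < end:
                    out.append(Token(start + 5, end, "meta-value"))
            else:
                out.append(Token(start, end, "unknown"))


def _lex_vcf_meta(line: str, out: List[Token]) -> None:
    eq = line.find("=")
    if eq == -1:
        out.append(Token(0, len(line), "comment"))
        return
    out.append(Token(0, eq, "meta-key"))
    if eq + 1 < len(line):
        out.append(Token(eq + 1, len(line), "meta-value"))


def _lex_vcf_info(line: str, out: List[Token], start: int, end: int) -> None:
    pos = start
    while pos < end:
        semi = line.find(";", pos, end)
        stop = semi if semi != -1 else end
        eq = line.find("=", pos, stop)
        if eq != -1:
            if eq > pos:
                out.append(Token(pos, eq, "meta-key"))
            if eq + 1 < stop:
                out.append(Token(eq + 1, stop, "meta-value"))
        elif stop > pos:
            out.append(Token(pos, stop, "meta-key"))  # flag key
        if semi == -1:
            break
        pos = semi + 1


def _lex_vcf_body(line: str, out: List[Token]) -> None:
    for idx, (start, end, text) in enumerate(_fields(line)):
        if start >= end:
            continue
        col = idx + 1
        if col in (1, 2):
            out.append(Token(start, end, "coordinate"))
        elif col == 3:
            out.append(Token(start, end, "read-name"))
        elif col in (4, 5):
            _seq_tokens(out, start, text.replace(",", " "), "nucleotide")
        elif col == 6:
            _score_bin_token(out, start, end, text, 100.0)
        elif col == 7:
            out.append(Token(start, end, "meta-value"))  # FILTER
        elif col == 8:
            _lex_vcf_info(line, out, start, end)
        else:  # FORMAT + per-sample genotype columns
            out.append(Token(start, end, "sample-info"))


def _lex_bed(line: str, out: List[Token]) -> None:
    if line.startswith(("#", "track", "browser")):
        out.append(Token(0, len(line), "comment"))
        return
    for idx, (start, end, text) in enumerate(_fields(line)):
        if start >= end:
            continue
        col = idx + 1
        if col <= 3:
            out.append(Token(start, end, "coordinate"))
        elif col == 4:
            out.append(Token(start, end, "read-name"))
        elif col == 5:
            _score_bin_token(out, start, end, text, 1000.0)
        elif col == 6:
            out.append(Token(start, end, "strand"))
        else:
            out.append(Token(start, end, "meta-value"))


_GTF_FEATURE_CLASS = {
    "cds": "feature.cds",
    "utr": "feature.utr",
    "5utr": "feature.utr",
    "3utr": "feature.utr",
    "five_prime_utr": "feature.utr",
    "three_prime_utr": "feature.utr",
    "start_codon": "feature.start-codon",
    "stop_codon": "feature.stop-codon",
}

_GTF_ATTR_RE = re.compile(r'(\w+)\s+("[^"]*"|[^;]+)')


def _lex_gtf(line: str, out: List[Token]) -> None:
    if line.startswith("#"):
        out.append(Token(0, len(line), "comment"))
        return
    feature_cls: Optional[str] = None
    for idx, (start, end, text) in enumerate(_fields(line)):
        if start >= end:
            continue
        col = idx + 1
        if col in (1, 4, 5):
            out.append(Token(start, end, "coordinate"))
        elif col == 2:
            out.append(Token(start, end, "meta-value"))  # source
        elif col == 3:
            feature_cls = _GTF_FEATURE_CLASS.get(text.lower())
            out.append(Token(start, end, feature_cls or "record-type"))
        elif col == 6:
            _score_bin_token(out, start, end, text, 1000.0)
        elif col == 7:
            out.append(Token(start, end, "strand"))
        elif col == 8:
            out.append(Token(start, end, "meta-value"))  # frame
        elif col == 9:
            for m in _GTF_ATTR_RE.finditer(line, start, end):
                out.append(Token(m.start(1), m.end(1), "meta-key"))
                out.append(Token(m.start(2), m.end(2), "meta-value"))
    if feature_cls is not None:
        # protein-coding features get a whole-line background tint: fill the
        # gaps (tabs, uncovered bytes) with the bg-only feature class
        _fill_gaps(out, len(line), feature_cls)


def _fill_gaps(out: List[Token], line_len: int, cls: str) -> None:
    out.sort(key=lambda t: t.start)
    filled: List[Token] = []
    pos = 0
    for t in out:
        if t.start > pos:
            filled.append(Token(pos, t.start, cls))
        filled.append(t)
        pos = t.end
    if pos < line_len:
        filled.append(Token(pos, line_len, cls))
    out[:] = filled


# PDB v3.3 fixed columns for ATOM/HETATM, 0-based half-open: (start, end, class-or-None)
_PDB_ATOM_COLS = (
    (6, 11, "meta-value"),   # serial
    (12, 16, "meta-key"),    # atom name
    (17, 20, "meta-value"),  # resName
    (21, 22, "meta-key"),    # chainID
    (22, 26, "meta-value"),  # resSeq
    (30, 38, "meta-value"),  # x
    (38, 46, "meta-value"),  # y
    (46, 54, "meta-value"),  # z
    (54, 60, "meta-value"),  # occupancy
    (60, 66, None),          # B-factor -> quality bin
    (76, 78, "meta-key"),    # element
)


def _lex_pdb(line: str, out: List[Token]) -> None:
    span = _stripped_span(line, 0, 6)
    if span is None:
        return
    out.append(Token(span[0], span[1], "record-type"))
    rec = line[:6].strip()
    if rec in ("ATOM", "HETATM"):
        for cs, ce, cls in _PDB_ATOM_COLS:
            s = _stripped_span(line, cs, ce)
            if s is None:
                continue
            if cls is None:
                _score_bin_token(out, s[0], s[1], line[s[0] : s[1]], 100.0)
            else:
                out.append(Token(s[0], s[1], cls))
    elif rec == "REMARK":
        s = _stripped_span(line, 7, len(line))
        if s is not None:
            out.append(Token(s[0], s[1], "comment"))
    else:
        s = _stripped_span(line, 6, len(line))
        if s is not None:
            out.append(Token(s[0], s[1], "meta-value"))


_CLUSTAL_CONS = frozenset(" *:.")


def _lex_clustal(state: LexState, line: str, out: List[Token]) -> LexState:
    if state.record_phase == 0 and line.startswith("CLUSTAL"):
        out.append(Token(0, len(line), "record-type"))
        return state.with_(record_phase=1)
    if not line.strip():
        return state if state.record_phase else state.with_(record_phase=1)
    if all(ch in _CLUSTAL_CONS for ch in line):
        s = _stripped_span(line, 0, len(line))
        if s is not None:
            out.append(Token(s[0], s[1], "comment"))
        return state.with_(record_phase=1)
    # sequence row: name column, residues, optional trailing cumulative count
    m = re.match(r"^(\S+)(\s+)(\S+)(\s+\d+)?\s*$", line)
    if m is None:
        out.append(Token(0, len(line), "unknown"))
        return state.with_(record_phase=1)
    out.append(Token(m.start(1), m.end(1), "read-name"))
    _seq_tokens(out, m.start(3), m.group(3), "aminoacid")
    if m.group(4):
        s = _stripped_span(line, m.start(4), m.end(4))
        if s is not None:
            out.append(Token(s[0], s[1], "meta-value"))
    return state.with_(record_phase=1)


def _lex_fasta(state: LexState, line: str, out: List[Token]) -> LexState:
    if line.startswith((">", ";")):
        out.append(Token(0, len(line), "read-name" if line[0] == ">" else "comment"))
        return state
    alphabet = state.fasta_alphabet
    if alphabet == "undetermined":
        try:
            alphabet = sniff_alphabet([line])
        except ValueError:
            return state  # gaps/blank only — keep sniffing on later lines
        state = state.with_(fasta_alphabet=alphabet)
    _seq_tokens(out, 0, line, alphabet)
    return state


def _lex_fastq(state: LexState, line: str, out: List[Token]) -> LexState:
    phase = state.record_phase
    if phase == 0:
        if line:
            out.append(Token(0, len(line), "read-name" if line[0] == "@" else "unknown"))
    elif phase == 1:
        _seq_tokens(out, 0, line, "nucleotide")
    elif phase == 2:
        if line:
            out.append(Token(0, len(line), "comment" if line[0] == "+" else "unknown"))
    else:
        _qual_char_tokens(out, 0, line)
    return state.with_(record_phase=(phase + 1) % 4)


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------


def lex_line(state: LexState, line: str) -> Tuple[List[Token], LexState]:
    """Tokenize one line under *state*; returns (tokens, new_state).

    Tokens are sorted, non-overlapping and in-bounds; a trailing ``\\r`` is
    excluded and left unstyled.  Never raises on content: unparseable spans
    come back as class ``unknown``.
    """
    if state.format is FormatId.PLAIN:
        raise ValueError("PLAIN streams are not lexed")
    eff_len = len(line)
    if eff_len and line[-1] == "\r":
        eff_len -= 1
        line = line[:eff_len]
    out: List[Token] = []
    fmt = state.format
    new_state = state

    if fmt is FormatId.SAM:
        if state.in_header and line.startswith("@"):
            _lex_sam_header(line, out)
        else:
            if state.in_header:
                new_state = state.with_(in_header=False)
            if line:
                _lex_sam_body(line, out)
    elif fmt is FormatId.VCF:
        if state.in_header and line.startswith("##"):
            _lex_vcf_meta(line, out)
        elif state.in_header and line.startswith("#"):
            out.append(Token(0, eff_len, "record-type"))
        else:
            if state.in_header:
                new_state = state.with_(in_header=False)
            if line:
                _lex_vcf_body(line, out)
    elif fmt is FormatId.BED:
        if line:
            _lex_bed(line, out)
    elif fmt is FormatId.GTF:
        if line:
            _lex_gtf(line, out)
    elif fmt is FormatId.PDB:
        if line:
            _lex_pdb(line, out)
    elif fmt is FormatId.CLUSTAL:
        new_state = _lex_clustal(state, line, out)
    elif fmt is FormatId.FASTA:
        if line:
            new_state = _lex_fasta(state, line, out)
    elif fmt is FormatId.FASTQ:
        new_state = _lex_fastq(state, line, out)

    out.sort(key=lambda t: (t.start, t.end))
    # defensive: drop any overlap a malformed span produced
    cleaned: List[Token] = []
    prev_end = 0
    for t in out:
        if t.start >= prev_end and t.end <= eff_len and t.start < t.end:
            cleaned.append(t)
            prev_end = t.end
    return cleaned, new_state
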