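"""Shared vocabulary: formats, style classes, colours, themes, tokens, lexer state.

Every other module speaks in these types.  A :class:`Token` is a half-open
character span of one line plus a style class; a :class:`Theme` is a *total*
mapping from the closed style-class set to colours (``None`` = unstyled).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, NamedTuple, Optional, Tuple

__all__ = [
    "FormatId",
    "ColorSpec",
    "Theme",
    "Token",
    "LexState",
    "ansi256_of_rgb",
    "ALL_STYLE_CLASSES",
    "IUPAC_CODES",
    "AMINO_ACIDS",
    "QUALITY_BINS",
    "CIGAR_CLASS",
    "validate_tokens",
]


class FormatId(enum.Enum):
    """The nine recognized stream kinds; PLAIN passes through unhighlighted."""

    FASTA = "fasta"
    FASTQ = "fastq"
    SAM = "sam"
    VCF = "vcf"
    BED = "bed"
    GTF = "gtf"
    PDB = "pdb"
    CLUSTAL = "clustal"
    PLAIN = "plain"


# ---------------------------------------------------------------------------
# Style classes — a closed, enumerable set shared by all lexers.
# One class per biological meaning: `coordinate` is the same class whether the
# span came from BED, GTF, SAM or VCF.
# ---------------------------------------------------------------------------

IUPAC_CODES = "ACGTURYSWKMBDHVN"  # 16 codes, U kept distinct (RNA)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard one-letter codes
AMBIGUOUS_AA = "BZX"
QUALITY_BINS = 6

#: CIGAR operator character -> style class
CIGAR_CLASS: Dict[str, str] = {
    "M": "cigar.match",
    "I": "cigar.insertion",
    "D": "cigar.deletion",
    "N": "cigar.skip",
    "S": "cigar.soft-clip",
    "H": "cigar.hard-clip",
    "P": "cigar.pad",
    "=": "cigar.eq",
    "X": "cigar.mismatch",
}

_SIMPLE_CLASSES = (
    "coordinate",
    "sample-info",
    "read-name",
    "flag",
    "strand",
    "comment",
    "record-type",
    "meta-key",
    "meta-value",
    "unknown",
    "feature.cds",
    "feature.utr",
    "feature.start-codon",
    "feature.stop-codon",
)

ALL_STYLE_CLASSES: frozenset = frozenset(
    _SIMPLE_CLASSES
    + tuple(CIGAR_CLASS.values())
    + tuple(f"nucleotide.{c}" for c in IUPAC_CODES)
    + tuple(f"aminoacid.{a}" for a in AMINO_ACIDS + AMBIGUOUS_AA)
    + tuple(f"quality.{i}" for i in range(QUALITY_BINS))
)


# ---------------------------------------------------------------------------
# ANSI-256 nearest neighbour
# ---------------------------------------------------------------------------

_CUBE_LEVELS = (0, 95, 135, 175, 215, 255)


def _nearest_cube_level(v: int) -> int:
    """Index 0-5 of the nearest cube level; ties resolve to the lower level."""
    best_i, best_d = 0, abs(v - _CUBE_LEVELS[0])
    for i in range(1, 6):
        d = abs(v - _CUBE_LEVELS[i])
        if d < best_d:
            best_i, best_d = i, d
    return best_i


@lru_cache(maxsize=4096)
def ansi256_of_rgb(r: int, g: int, b: int) -> int:
    """Nearest xterm-256 palette index in 16..255 for an RGB triple.

    Distance is Euclidean in RGB over the 6x6x6 colour cube (16-231) and the
    24-step grayscale ramp (232-255); the 16 terminal-theme-dependent system
    colours are never used.  Ties break to the lowest index.
    """
    for v in (r, g, b):
        if not isinstance(v, int) or not 0 <= v <= 255:
            raise ValueError(f"RGB channel out of range 0..255: {v!r}")
    ri, gi, bi = (_nearest_cube_level(v) for v in (r, g, b))
    cube_idx = 16 + 36 * ri + 6 * gi + bi
    cr, cg, cb = _CUBE_LEVELS[ri], _CUBE_LEVELS[gi], _CUBE_LEVELS[bi]
    cube_d = (r - cr) ** 2 + (g - cg) ** 2 + (b - cb) ** 2
    best_gray_idx, best_gray_d = 232, None
    for i in range(24):
        gv = 8 + 10 * i
        d = (r - gv) ** 2 + (g - gv) ** 2 + (b - gv) ** 2
        if best_gray_d is None or d < best_gray_d:
            best_gray_idx, best_gray_d = 232 + i, d
    # tie between cube and gray -> cube (lower index)
    return cube_idx if cube_d <= best_gray_d else best_gray_idx


@dataclass(frozen=True)
class ColorSpec:
    """An RGB colour plus style flags; the ANSI-256 index is derived."""

    r: int
    g: int
    b: int
    bold: bool = False
    bg: Optional[Tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        for v in (self.r, self.g, self.b):
            if not 0 <= v <= 255:
                raise ValueError(f"RGB channel out of range: {v}")
        if self.bg is not None:
            for v in self.bg:
                if not 0 <= v <= 255:
                    raise ValueError(f"background channel out of range: {v}")

    @property
    def ansi256(self) -> int:
        return ansi256_of_rgb(self.r, self.g, self.b)

    @property
    def bg_ansi256(self) -> Optional[int]:
        if self.bg is None:
            return None
        return ansi256_of_rgb(*self.bg)

    @property
    def hex(self) -> str:
        return f"#{self.r:02x}{self.g:02x}{self.b:02x}"

    @classmethod
    def from_hex(
        cls,
        fg: Optional[str],
        bg: Optional[str] = None,
        bold: bool = False,
    ) -> Optional["ColorSpec"]:
        """Build from ``#RRGGBB`` strings; ``fg=None`` with no bg means unstyled."""

        def parse(h: str) -> Tuple[int, int, int]:
            h = h.lstrip("#")
            if len(h) != 6:
                raise ValueError(f"not a #RRGGBB colour: {h!r}")
            return int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16)

        if fg is None and bg is None:
            return None
        bgt = parse(bg) if bg else None
        if fg is None:
            # background-only style: foreground left at black but unused by
            # renderers, which key on bg presence via `fg_is_set`
            return cls(0, 0, 0, bold=bold, bg=bgt, )
        r, g, b = parse(fg)
        return cls(r, g, b, bold=bold, bg=bgt)


@dataclass
class Theme:
    """Total mapping from every style class to a colour (or None = unstyled)."""

    name: str
    mode: str
    mapping: Dict[str, Optional[ColorSpec]]
    #: classes whose YAML had fg: null (bg-only or fully unstyled)
    fg_unset: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = ALL_STYLE_CLASSES - self.mapping.keys()
        if missing:
            raise ValueError(
                f"theme {self.name!r} is not total; missing classes: "
                f"{sorted(missing)[:5]}..."
            )

    def color(self, style_class: str) -> Optional[ColorSpec]:
        return self.mapping[style_class]

    def has_fg(self, style_class: str) -> bool:
        return (
            self.mapping[style_class] is not None
            and style_class not in self.fg_unset
        )

    @classmethod
    def from_dict(cls, doc: dict) -> "Theme":
        mapping: Dict[str, Optional[ColorSpec]] = {}
        fg_unset = set()
        for name, entry in (doc.get("classes") or {}).items():
            if entry is None:
                mapping[name] = None
                fg_unset.add(name)
                continue
            spec = ColorSpec.from_hex(
                entry.get("fg"), entry.get("bg"), bool(entry.get("bold", False))
            )
            mapping[name] = spec
            if entry.get("fg") is None:
                fg_unset.add(name)
        return cls(
            name=doc.get("name", "unnamed"),
            mode=doc.get("mode", "default"),
            mapping=mapping,
            fg_unset=frozenset(fg_unset),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "Theme":
        import yaml

        return cls.from_dict(yaml.safe_load(text))


class Token(NamedTuple):
    """Half-open span ``[start, end)`` of one line carrying a style class."""

    start: int
    end: int
    cls: str


def validate_tokens(line_len: int, tokens) -> None:
    """Raise ValueError unless tokens are sorted, in-bounds, non-overlapping."""
    prev_end = 0
    for t in tokens:
        if not (0 <= t.start < t.end <= line_len):
            raise ValueError(f"token out of bounds: {t} for line length {line_len}")
        if t.start < prev_end:
            raise ValueError(f"tokens overlap or unsorted at {t}")
        prev_end = t.end


@dataclass(frozen=True)
class LexState:
    """Per-stream context carried between lines.

    ``in_header`` may flip true->false once (SAM/VCF) but never back;
    FASTQ ``record_phase`` cycles 0..3.
    """

    format: FormatId
    in_header: bool = True
    fasta_alphabet: str = "undetermined"  # nucleotide | aminoacid | undetermined
    record_phase: int = 0

    def with_(self, **kw) -> "LexState":
        return replace(self, **kw)
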