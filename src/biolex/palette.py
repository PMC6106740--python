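"""Colour science for nucleotide and amino-acid highlighting.

The nucleotide scheme maps the full 16-letter IUPAC ambiguity alphabet onto
colours by additive mixing: each ambiguous code is the channel-wise mean of
its member bases' primaries, darkened for the aMino/Keto pairs (M, K) and
lightened for three-base codes, with N (any base) fixed at white.  Primaries
are chosen so strong bases (G, C) read warm and weak bases (A, T) read cool,
making GC-content visible as overall warmth.

Also here: PHRED decoding, gradient binning, relative luminance, dichromacy
simulation (for the high-contrast theme), and the published amino-acid
colour schemes (Clustal, Taylor, Zappo, hydrophobicity).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Dict, FrozenSet, List, Mapping, Optional

import yaml

from .core import ColorSpec, Theme, IUPAC_CODES, QUALITY_BINS

__all__ = [
    "IUPAC_BASES",
    "iupac_bases",
    "mix_iupac_color",
    "validate_nucleotide_theme",
    "phred_score",
    "quality_bin",
    "relative_luminance",
    "simulate_dichromacy",
    "sequence_warmth",
    "amino_acid_color",
    "load_theme",
    "apply_aa_scheme",
    "AA_SCHEMES",
    "DICHROMACY_KINDS",
]

#: IUPAC ambiguity code -> set of denoted bases (U is the T slot).
IUPAC_BASES: Dict[str, FrozenSet[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: lightness adjustments for the "increasingly lighter tones" reading:
#: aMino/Keto two-base codes are darkened, three-base codes lightened.
DARKEN_MK = 0.75
LIGHTEN_3 = 0.35

AA_SCHEMES = ("clustal", "taylor", "zappo", "hydrophobicity")
DICHROMACY_KINDS = ("protanopia", "deuteranopia", "tritanopia")


def iupac_bases(code: str) -> FrozenSet[str]:
    """Base set denoted by one IUPAC nucleotide code (case-insensitive)."""
    try:
        return IUPAC_BASES[code.upper()]
    except (KeyError, AttributeError):
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def mix_iupac_color(code: str, primaries: Mapping[str, ColorSpec]) -> ColorSpec:
    """Additive colour for an IUPAC code from the four base primaries.

    Single-base codes (incl. U) return their primary unchanged; N is white.
    Two-base codes take the channel-wise mean, with M and K darkened by
    ``DARKEN_MK``; three-base codes are lightened toward white by
    ``LIGHTEN_3``.
    """
    for base in "ACGT":
        if base not in primaries:
            raise ValueError(f"primaries missing base {base}")
    bases = iupac_bases(code)
    code = code.upper()
    if len(bases) == 1:
        return primaries[next(iter(bases))]
    if code == "N":
        return ColorSpec(255, 255, 255)
    members = [primaries[b] for b in sorted(bases)]
    n = len(members)
    r = sum(m.r for m in members) / n
    g = sum(m.g for m in members) / n
    b = sum(m.b for m in members) / n
    if n == 2 and code in ("M", "K"):
        r, g, b = r * DARKEN_MK, g * DARKEN_MK, b * DARKEN_MK
    elif n == 3:
        r = r + LIGHTEN_3 * (255 - r)
        g = g + LIGHTEN_3 * (255 - g)
        b = b + LIGHTEN_3 * (255 - b)
    return ColorSpec(int(round(r)), int(round(g)), int(round(b)))


def warmth(c: ColorSpec) -> float:
    """Warm/cool axis in [-1, 1]: red-heavy positive, blue-heavy negative."""
    return (c.r - c.b) / 255.0


def relative_luminance(c: ColorSpec) -> float:
    """sRGB-weighted luminance in [0, 1] (linearization deliberately omitted)."""
    return (0.2126 * c.r + 0.7152 * c.g + 0.0722 * c.b) / 255.0


def validate_nucleotide_theme(theme: Theme) -> List[str]:
    """Check a theme's nucleotide entries against the palette contract.

    Returns a list of human-readable violations (empty = valid):
    (i) N is white; (ii) G and C warm, A and T cool; (iii) M and K darker
    than the mean of their parent primaries; (iv) all 16 codes pairwise
    distinct in RGB.
    """
    violations: List[str] = []
    colors = {c: theme.color(f"nucleotide.{c}") for c in IUPAC_CODES}
    for c, spec in colors.items():
        if spec is None:
            violations.append(f"nucleotide.{c} is unstyled")
    if any(v is None for v in colors.values()):
        return violations

    n = colors["N"]
    if (n.r, n.g, n.b) != (255, 255, 255):
        violations.append("(i) N is not white")
    for base in "GC":
        if warmth(colors[base]) <= 0:
            violations.append(f"(ii) {base} is not warm (r <= b)")
    for base in "AT":
        if warmth(colors[base]) >= 0:
            violations.append(f"(ii) {base} is not cool (r >= b)")
    for code, (p1, p2) in (("M", "AC"), ("K", "GT")):
        parent_mean = ColorSpec(
            (colors[p1].r + colors[p2].r) // 2,
            (colors[p1].g + colors[p2].g) // 2,
            (colors[p1].b + colors[p2].b) // 2,
        )
        if relative_luminance(colors[code]) >= relative_luminance(parent_mean):
            violations.append(f"(iii) {code} not darker than mean of {p1},{p2}")
    seen: Dict[tuple, str] = {}
    for c in IUPAC_CODES:
        rgb = (colors[c].r, colors[c].g, colors[c].b)
        if rgb in seen:
            violations.append(f"(iv) {seen[rgb]} and {c} share RGB {rgb}")
        else:
            seen[rgb] = c
    return violations


def phred_score(q: str, offset: int = 33) -> int:
    """Decode one quality character to its PHRED score."""
    if offset not in (33, 64):
        raise ValueError(f"unsupported PHRED offset: {offset}")
    score = ord(q) - offset
    if score < 0:
        raise ValueError(f"character {q!r} below PHRED offset {offset}")
    return score


def quality_bin(score_norm: float, k_bins: int = QUALITY_BINS) -> int:
    """Gradient bin index for a normalized score in [0, 1]."""
    if k_bins < 2:
        raise ValueError("k_bins must be >= 2")
    if not 0.0 <= score_norm <= 1.0:
        raise ValueError(f"normalized score out of [0, 1]: {score_norm}")
    return min(int(score_norm * k_bins), k_bins - 1)


@lru_cache(maxsize=1)
def _dichromacy_matrices() -> Dict[str, list]:
    text = resources.files("biolex.data").joinpath("dichromacy.yaml").read_text()
    return yaml.safe_load(text)


def simulate_dichromacy(c: ColorSpec, kind: str) -> ColorSpec:
    """Approximate a colour as seen under one form of dichromacy.

    Applies the configured 3x3 linear RGB transform and clamps to [0, 255].
    """
    matrices = _dichromacy_matrices()
    if kind not in matrices:
        raise ValueError(f"unknown dichromacy kind: {kind!r}")
    m = matrices[kind]
    vec = (c.r, c.g, c.b)
    out = []
    for row in m:
        v = sum(row[j] * vec[j] for j in range(3))
        out.append(max(0, min(255, int(round(v)))))
    return ColorSpec(out[0], out[1], out[2], bold=c.bold, bg=c.bg)


def sequence_warmth(seq: str, theme: Theme) -> float:
    """Mean warmth of a nucleotide sequence under a theme, in [-1, 1].

    High-GC sequences read warm (positive), high-AT cool (negative); N-runs
    sit at zero because white is warmth-neutral.
    """
    if not seq:
        raise ValueError("empty sequence")
    total = 0.0
    for ch in seq:
        code = ch.upper()
        if code not in IUPAC_BASES:
            raise ValueError(f"not an IUPAC code in sequence: {ch!r}")
        spec = theme.color(f"nucleotide.{code}")
        if spec is None:
            raise ValueError(f"theme has no colour for nucleotide.{code}")
        total += warmth(spec)
    return total / len(seq)


@lru_cache(maxsize=1)
def _aa_scheme_tables() -> Dict[str, Dict[str, str]]:
    text = resources.files("biolex.data").joinpath("aa_schemes.yaml").read_text()
    return yaml.safe_load(text)


_GAP_CHARS = frozenset("-.*")


def amino_acid_color(residue: str, scheme: str = "clustal") -> Optional[ColorSpec]:
    """Colour of one residue under a published amino-acid scheme.

    Gaps and the fully-ambiguous X are unstyled (None); B/Z fall back to
    unstyled when the scheme's table omits them.
    """
    tables = _aa_scheme_tables()
    if scheme not in tables:
        raise ValueError(f"unknown amino-acid scheme: {scheme!r}")
    if residue in _GAP_CHARS:
        return None
    res = residue.upper()
    if res == "X":
        return None
    table = tables[scheme]
    if res not in table:
        if res in ("B", "Z"):
            return None
        raise ValueError(f"not an amino-acid residue: {residue!r}")
    return ColorSpec.from_hex(table[res])


# ---------------------------------------------------------------------------
# Theme loading
# ---------------------------------------------------------------------------

_THEME_FILES = {"default": "default.yaml", "high-contrast": "high_contrast.yaml"}


@lru_cache(maxsize=None)
def load_theme(name: str = "default") -> Theme:
    """Load a shipped theme (``default`` or ``high-contrast``) from package data."""
    if name not in _THEME_FILES:
        raise ValueError(
            f"unknown theme {name!r}; shipped themes: {sorted(_THEME_FILES)}"
        )
    text = (
        resources.files("biolex.data.themes")
        .joinpath(_THEME_FILES[name])
        .read_text()
    )
    return Theme.from_yaml(text)


def apply_aa_scheme(theme: Theme, scheme: str) -> Theme:
    """Return a copy of *theme* with amino-acid classes recoloured by *scheme*."""
    tables = _aa_scheme_tables()
    if scheme not in tables:
        raise ValueError(f"unknown amino-acid scheme: {scheme!r}")
    mapping = dict(theme.mapping)
    for cls in list(mapping):
        if cls.startswith("aminoacid."):
            res = cls.split(".", 1)[1]
            mapping[cls] = amino_acid_color(res, scheme)
    return Theme(
        name=f"{theme.name}+{scheme}",
        mode=theme.mode,
        mapping=mapping,
        fg_unset=theme.fg_unset,
    )
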