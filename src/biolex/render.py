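"""Lossless rendering of (line, tokens, theme) to ANSI terminal text or HTML.

The contract: content bytes pass through unchanged and in order; stripping
the escapes (or tags) recovers the input line exactly.  Adjacent tokens of
the same class are coalesced into one escape region, and a single SGR reset
closes every styled line so pagers never bleed colour.
"""

from __future__ import annotations

import html as _html
import re
from typing import Dict, List, Sequence

from .core import ColorSpec, Theme, Token, validate_tokens

__all__ = ["render_ansi", "render_html", "strip_ansi"]

_RESET = "\x1b[0m"
_ANSI_RE = re.compile(r"\x1b\[[0-9;]*m")


def _sgr_prefix(theme: Theme, cls: str) -> str:
    """SGR escape for a style class; empty string means unstyled."""
    cache = theme.__dict__.setdefault("_sgr_cache", {})
    try:
        return cache[cls]
    except KeyError:
        pass
    spec = theme.color(cls)
    parts: List[str] = []
    if spec is not None:
        if spec.bold:
            parts.append("1")
        if theme.has_fg(cls):
            parts.append(f"38;5;{spec.ansi256}")
        if spec.bg is not None:
            parts.append(f"48;5;{spec.bg_ansi256}")
    prefix = f"\x1b[{';'.join(parts)}m" if parts else ""
    cache[cls] = prefix
    return prefix


def render_ansi(line: str, tokens: Sequence[Token], theme: Theme) -> str:
    """Insert SGR escapes at token boundaries; unstyled spans pass through."""
    if not tokens:
        return line
    validate_tokens(len(line), tokens)
    parts: List[str] = []
    pos = 0
    styled = False
    i = 0
    n = len(tokens)
    while i < n:
        t = tokens[i]
        # coalesce adjacent same-class runs
        end = t.end
        j = i + 1
        while j < n and tokens[j].cls == t.cls and tokens[j].start == end:
            end = tokens[j].end
            j += 1
        prefix = _sgr_prefix(theme, t.cls)
        if t.start > pos:
            parts.append(line[pos : t.start])
        if prefix:
            parts.append(prefix)
            parts.append(line[t.start : end])
            parts.append(_RESET)
            styled = True
        else:
            parts.append(line[t.start : end])
        pos = end
        i = j
    if pos < len(line):
        parts.append(line[pos:])
    out = "".join(parts)
    # guarantee a trailing reset on styled lines (pager safety)
    if styled and not out.endswith(_RESET):
        out += _RESET
    return out


def strip_ansi(s: str) -> str:
    """Remove all SGR escape sequences; idempotent."""
    return _ANSI_RE.sub("", s)


def _css(theme: Theme, cls: str) -> str:
    cache = theme.__dict__.setdefault("_css_cache", {})
    try:
        return cache[cls]
    except KeyError:
        pass
    spec = theme.color(cls)
    rules: List[str] = []
    if spec is not None:
        if theme.has_fg(cls):
            rules.append(f"color:{spec.hex}")
        if spec.bg is not None:
            r, g, b = spec.bg
            rules.append(f"background-color:#{r:02x}{g:02x}{b:02x}")
        if spec.bold:
            rules.append("font-weight:bold")
    css = ";".join(rules)
    cache[cls] = css
    return css


def render_html(line: str, tokens: Sequence[Token], theme: Theme) -> str:
    """HTML-escape the line and wrap styled tokens in inline-styled spans."""
    validate_tokens(len(line), tokens)
    parts: List[str] = []
    pos = 0
    i = 0
    n = len(tokens)
    while i < n:
        t = tokens[i]
        end = t.end
        j = i + 1
        while j < n and tokens[j].cls == t.cls and tokens[j].start == end:
            end = tokens[j].end
            j += 1
        if t.start > pos:
            parts.append(_html.escape(line[pos : t.start]))
        css = _css(theme, t.cls)
        body = _html.escape(line[t.start : end])
        if css:
            parts.append(f'<span style="{css}">{body}</span>')
        else:
            parts.append(body)
        pos = end
        i = j
    if pos < len(line):
        parts.append(_html.escape(line[pos:]))
    return "".join(parts)
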