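"""Degenerate consensus-pattern compiler and scanner.

Implements a PROSITE-flavoured pattern grammar — tokens separated by ``-``,
residue sets in brackets (``[RK]``), the wildcard ``x``, and repeat suffixes
``(m,n)`` or ``(m)`` — and an exhaustive scanner that reports every match of
every repeat expansion, overlapping matches included.  Presence of a motif in
a reference-anchored window is then tallied per taxonomic clade, the way
kinase consensus sites (PKA: R-x(1,2)-[ST]-x, PKG: [RK](2,3)-x-[ST]-x) and
the P450 heme/EXXR signatures are reported.

Coordinates of hits are 1-based, inclusive, ungapped per-sequence positions.
An unknown residue ``X`` in a sequence matches no token (unknown is not a
wildcard), keeping presence calls conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

from .io_formats import AMINO_ACIDS, Alignment, CladeTable
from .refmap import RefMap

MAX_REPEAT = 10

#: bundled default motifs: kinase consensus patterns and P450 signatures
DEFAULT_MOTIFS = (
    ("PKA", "R-x(1,2)-[ST]-x"),
    ("PKG", "[RK](2,3)-x-[ST]-x"),
    ("heme-cysteine", "F-G-F-G-P-R-[GASTN]-C-[AVLI]-G-[KR]"),
    ("EXXR", "E-x-x-R"),
)


class PatternError(ValueError):
    """Raised for a malformed pattern, with the offending position."""


@dataclass(frozen=True)
class Token:
    residues: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise PatternError("empty residue set")
        if not 1 <= self.min_repeat <= self.max_repeat <= MAX_REPEAT:
            raise PatternError(
                f"invalid repeat bounds ({self.min_repeat},{self.max_repeat})"
            )

    def text(self) -> str:
        if self.residues == frozenset(AMINO_ACIDS):
            base = "x"
        elif len(self.residues) == 1:
            base = next(iter(self.residues))
        else:
            base = "[" + "".join(sorted(self.residues)) + "]"
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return base
        if self.min_repeat == self.max_repeat:
            return f"{base}({self.min_repeat})"
        return f"{base}({self.min_repeat},{self.max_repeat})"


@dataclass(frozen=True)
class MotifPattern:
    name: str
    tokens: tuple[Token, ...]

    @property
    def min_length(self) -> int:
        return sum(t.min_repeat for t in self.tokens)

    @property
    def max_length(self) -> int:
        return sum(t.max_repeat for t in self.tokens)

    def text(self) -> str:
        return "-".join(t.text() for t in self.tokens)


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 1-based inclusive, ungapped coordinates
    end: int
    matched: str


def compile_pattern(text: str, name: str = "") -> MotifPattern:
    """Parse pattern text into a :class:`MotifPattern`; round-trips via .text()."""
    tokens: list[Token] = []
    for raw in text.split("-"):
        raw = raw.strip()
        if not raw:
            raise PatternError(f"empty token in pattern {text!r}")
        pos = 0
        if raw[pos] == "[":
            close = raw.find("]")
            if close < 0:
                raise PatternError(f"unclosed '[' at position {pos} in token {raw!r}")
            residues = raw[1:close].upper()
            if not residues:
                raise PatternError(f"empty residue set in token {raw!r}")
            bad = set(residues) - set(AMINO_ACIDS)
            if bad:
                raise PatternError(f"unknown residues {sorted(bad)} in token {raw!r}")
            res_set = frozenset(residues)
            pos = close + 1
        elif raw[pos] in ("x", "X"):
            res_set = frozenset(AMINO_ACIDS)
            pos += 1
        elif raw[pos].upper() in AMINO_ACIDS:
            res_set = frozenset(raw[pos].upper())
            pos += 1
        else:
            raise PatternError(f"unknown character {raw[pos]!r} at position {pos} in token {raw!r}")
        min_r = max_r = 1
        if pos < len(raw):
            if raw[pos] != "(" or not raw.endswith(")"):
                raise PatternError(f"malformed repeat suffix in token {raw!r}")
            body = raw[pos + 1 : -1]
            parts = body.split(",")
            try:
                if len(parts) == 1:
                    min_r = max_r = int(parts[0])
                elif len(parts) == 2:
                    min_r, max_r = int(parts[0]), int(parts[1])
                else:
                    raise ValueError
            except ValueError:
                raise PatternError(f"malformed repeat suffix in token {raw!r}") from None
        if not 1 <= min_r <= max_r <= MAX_REPEAT:
            raise PatternError(f"invalid repeat bounds ({min_r},{max_r}) in token {raw!r}")
        tokens.append(Token(res_set, min_r, max_r))
    return MotifPattern(name=name or text, tokens=tuple(tokens))


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _match_ends(tokens: Sequence[Token], seq: str, pos: int, ti: int) -> Iterator[int]:
    """Yield all end offsets (exclusive) of matches of tokens[ti:] at pos."""
    if ti == len(tokens):
        yield pos
        return
    tok = tokens[ti]
    count = 0
    # consume up to max_repeat residues of this token's set
    while count < tok.max_repeat and pos + count < len(seq) and seq[pos + count] in tok.residues:
        count += 1
        if count >= tok.min_repeat:
            yield from _match_ends(tokens, seq, pos + count, ti + 1)


def scan_sequence(pattern: MotifPattern, sequence: str, seq_id: str = "") -> list[MotifHit]:
    """All matches of all repeat expansions, overlapping allowed.

    ``sequence`` must be ungapped.  Hits are unique (start, end) spans sorted
    by (start, end); 'X' residues match no token.
    """
    seq = sequence.upper()
    if "-" in seq or "." in seq:
        raise ValueError("scan_sequence requires an ungapped sequence")
    spans: set[tuple[int, int]] = set()
    for start in range(len(seq)):
        for end in _match_ends(pattern.tokens, seq, start, 0):
            spans.add((start, end))
    return [
        MotifHit(seq_id=seq_id, start=s + 1, end=e, matched=seq[s:e])
        for s, e in sorted(spans)
    ]


# ---------------------------------------------------------------------------
# Reference-anchored per-clade presence
# ---------------------------------------------------------------------------

def _ungapped_window(seq: str, columns: Sequence[int]) -> tuple[int, int] | None:
    """Ungapped-coordinate span of alignment ``columns`` (1-based) in ``seq``.

    Returns None if the sequence is all-gap across the window.
    """
    # ungapped position of each column (position of the residue at or before it)
    positions = []
    for col in columns:
        if seq[col - 1] == "-":
            continue
        positions.append(sum(1 for ch in seq[:col] if ch != "-"))
    if not positions:
        return None
    return min(positions), max(positions)


def anchored_clade_presence(
    alignment: Alignment,
    clade_table: CladeTable,
    refmap: RefMap,
    pattern: MotifPattern,
    window: tuple[int, int],
) -> dict[str, tuple[float, int]]:
    """Fraction of each clade's sequences with a hit inside a reference window.

    ``window`` is a (start, end) reference-residue interval; a sequence counts
    as present when at least one hit lies entirely within the ungapped image
    of the window's alignment columns in that sequence.  Returns
    clade -> (fraction, clade size); empty clades are omitted.
    """
    lo, hi = window
    columns = [refmap.res_to_col[r] for r in range(lo, hi + 1) if r in refmap.res_to_col]
    if not columns:
        raise ValueError(f"window {lo}-{hi} maps to no alignment columns")
    out: dict[str, tuple[float, int]] = {}
    for clade in clade_table.labels:
        members = [sid for sid in alignment.ids if clade_table.mapping.get(sid) == clade]
        if not members:
            continue
        n_present = 0
        for sid in members:
            seq = alignment.sequence(sid)
            span = _ungapped_window(seq, columns)
            if span is None:
                continue
            ungapped = seq.replace("-", "")
            hits = scan_sequence(pattern, ungapped, seq_id=sid)
            if any(h.start >= span[0] and h.end <= span[1] for h in hits):
                n_present += 1
        out[clade] = (n_present / len(members), len(members))
    return out
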