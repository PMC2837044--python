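"""PROSITE/PHI-BLAST-style pattern grammar with bounded variable-length gaps.

Patterns are strings such as ``xCxWx(2,35)Cx(5,15)Hx(2,5)Hx`` — the query
grammar used by pattern-constrained homology search.  A pattern is an ordered
list of elements: *literals* (a single residue letter or a residue class such
as ``[KR]`` / ``(K/R)``) and *gaps* (``x`` for one arbitrary residue,
``x(m)`` for exactly *m*, ``x(m,n)`` for *m* to *n*).

Matching semantics are fully defined rather than heuristic: ``match_pattern``
enumerates every distinct tuple of literal anchor positions that satisfies
the pattern (backtracking with memoisation over (element, position) states),
and a ``nonoverlapping`` mode reduces that set greedily left to right.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue codes allowed inside a pattern literal (standard plus unknown X).
LITERAL_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}


class PatternSyntaxError(ValueError):
    """Raised for a malformed pattern string; carries the 0-based offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class PatternElement:
    """One token of a motif pattern: a residue literal or a bounded gap."""

    kind: str  # "literal" | "gap"
    allowed: frozenset[str] = frozenset()  # literal only
    min: int = 1  # gap only
    max: int = 1  # gap only

    def __post_init__(self) -> None:
        if self.kind == "literal":
            if not self.allowed:
                raise ValueError("literal element with empty residue set")
            bad = set(self.allowed) - LITERAL_ALPHABET
            if bad:
                raise ValueError(f"non-residue letters in literal: {sorted(bad)}")
        elif self.kind == "gap":
            if not (1 <= self.min <= self.max):
                raise ValueError(f"gap bounds must satisfy 1 <= min <= max, got ({self.min},{self.max})")
        else:
            raise ValueError(f"unknown element kind {self.kind!r}")

    def render(self) -> str:
        if self.kind == "literal":
            if len(self.allowed) == 1:
                return next(iter(self.allowed))
            return "[" + "".join(sorted(self.allowed)) + "]"
        if (self.min, self.max) == (1, 1):
            return "x"
        if self.min == self.max:
            return f"x({self.min})"
        return f"x({self.min},{self.max})"


def literal(residues: str) -> PatternElement:
    return PatternElement(kind="literal", allowed=frozenset(residues))


def gap(lo: int, hi: int | None = None) -> PatternElement:
    return PatternElement(kind="gap", min=lo, max=lo if hi is None else hi)


@dataclass(frozen=True)
class MotifPattern:
    """A parsed bounded-gap motif pattern."""

    source_text: str
    elements: tuple[PatternElement, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern has no elements")

    @property
    def literals(self) -> tuple[PatternElement, ...]:
        return tuple(e for e in self.elements if e.kind == "literal")

    @property
    def min_length(self) -> int:
        return sum(1 if e.kind == "literal" else e.min for e in self.elements)

    def render(self) -> str:
        """Normalised source text; ``parse(render())`` is a fixed point."""
        return "".join(e.render() for e in self.elements)


@dataclass(frozen=True, order=True)
class PatternMatch:
    """One pattern placement: half-open 0-based span plus literal anchors."""

    start: int
    anchors: tuple[int, ...]
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


_INT_RE = re.compile(r"\d+")


def parse_phi_pattern(text: str) -> MotifPattern:
    """Parse a PHI-BLAST/PROSITE-style pattern string.

    Accepted tokens: uppercase residue letters, residue classes ``[KR]`` and
    ``(K/R)``, and gaps ``x`` / ``x(m)`` / ``x(m,n)``.  ``x(m)`` normalises
    to a gap of exactly *m* residues.
    """
    if not text:
        raise PatternSyntaxError("empty pattern", 0)
    elements: list[PatternElement] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == "x":
            if i + 1 < n and text[i + 1] == "(":
                j = text.find(")", i + 2)
                if j < 0:
                    raise PatternSyntaxError("unclosed '(' in gap repeat", i + 2)
                body = text[i + 2 : j]
                parts = body.split(",")
                if not all(_INT_RE.fullmatch(p) for p in parts) or len(parts) not in (1, 2):
                    raise PatternSyntaxError(f"malformed gap repeat {body!r}", i + 2)
                lo = int(parts[0])
                hi = int(parts[-1])
                if not (1 <= lo <= hi):
                    raise PatternSyntaxError(f"gap bounds ({lo},{hi}) violate 1 <= min <= max", i + 2)
                elements.append(gap(lo, hi))
                i = j + 1
            else:
                elements.append(gap(1, 1))
                i += 1
        elif c == "[":
            j = text.find("]", i + 1)
            if j < 0:
                raise PatternSyntaxError("unclosed '['", i)
            residues = text[i + 1 : j]
            if not residues or any(r not in LITERAL_ALPHABET for r in residues):
                raise PatternSyntaxError(f"malformed residue class {residues!r}", i + 1)
            elements.append(literal(residues))
            i = j + 1
        elif c == "(":
            # "(K/R)"-style class, as printed in e.g. TGE(K/R)P
            j = text.find(")", i + 1)
            if j < 0:
                raise PatternSyntaxError("unclosed '('", i)
            residues = text[i + 1 : j].split("/")
            if not residues or any(len(r) != 1 or r not in LITERAL_ALPHABET for r in residues):
                raise PatternSyntaxError(f"malformed residue class {text[i:j+1]!r}", i + 1)
            elements.append(literal("".join(residues)))
            i = j + 1
        elif c in LITERAL_ALPHABET:
            elements.append(literal(c))
            i += 1
        else:
            raise PatternSyntaxError(f"unexpected character {c!r}", i)
    return MotifPattern(source_text=text, elements=tuple(elements))


def _literal_matches(elem: PatternElement, residue: str) -> bool:
    # X in the subject is an unknown residue and is treated permissively.
    return residue in elem.allowed or residue == "X"


def _enumerate_anchor_tuples(pattern: MotifPattern, seq: str) -> set[tuple[int, ...]]:
    """All distinct literal-anchor tuples satisfying the pattern in seq."""
    elements = pattern.elements
    n = len(seq)
    n_el = len(elements)
    memo: dict[tuple[int, int], frozenset[tuple[int, ...]]] = {}

    def rec(ei: int, pos: int) -> frozenset[tuple[int, ...]]:
        if ei == n_el:
            return frozenset({()})
        key = (ei, pos)
        cached = memo.get(key)
        if cached is not None:
            return cached
        elem = elements[ei]
        out: set[tuple[int, ...]] = set()
        if elem.kind == "literal":
            if pos < n and _literal_matches(elem, seq[pos]):
                for tail in rec(ei + 1, pos + 1):
                    out.add((pos,) + tail)
        else:
            hi = min(elem.max, n - pos)
            for k in range(elem.min, hi + 1):
                out |= rec(ei + 1, pos + k)
        result = frozenset(out)
        memo[key] = result
        return result

    anchors: set[tuple[int, ...]] = set()
    for start in range(n + 1):
        anchors |= rec(0, start)
    return anchors


def _canonical_match(pattern: MotifPattern, anchors: tuple[int, ...]) -> PatternMatch:
    """Span for an anchor tuple: flanking gaps take their minimum lengths."""
    elements = pattern.elements
    first_lit = next(i for i, e in enumerate(elements) if e.kind == "literal")
    last_lit = max(i for i, e in enumerate(elements) if e.kind == "literal")
    lead = sum(e.min for e in elements[:first_lit])
    trail = sum(e.min for e in elements[last_lit + 1 :])
    return PatternMatch(start=anchors[0] - lead, anchors=anchors, end=anchors[-1] + 1 + trail)


def match_pattern(pattern: MotifPattern, seq: str, mode: str = "all") -> list[PatternMatch]:
    """Match a parsed pattern against an uppercase residue string.

    mode="all" returns every distinct anchor tuple, ordered by
    (span start, anchor tuple).  mode="nonoverlapping" greedily selects
    span-disjoint matches left to right, preferring at each start the
    lexicographically smallest anchor tuple.
    """
    if mode not in ("all", "nonoverlapping"):
        raise ValueError(f"unknown mode {mode!r}")
    if not any(e.kind == "literal" for e in pattern.elements):
        # Degenerate all-gap pattern: matches are identified by placement.
        lo = pattern.min_length
        matches = [
            PatternMatch(start=s, anchors=(), end=s + lo)
            for s in range(len(seq) - lo + 1)
        ]
    else:
        anchor_sets = _enumerate_anchor_tuples(pattern, seq)
        matches = sorted(_canonical_match(pattern, a) for a in anchor_sets)
    if mode == "all":
        return matches
    chosen: list[PatternMatch] = []
    cursor = 0
    for m in matches:  # sorted => smallest anchor tuple first at each start
        if m.start >= cursor:
            chosen.append(m)
            cursor = m.end
    return chosen


def iter_matches_tsv(seq_id: str, matches: list[PatternMatch]) -> Iterator[str]:
    """Render matches as TSV rows with 1-based inclusive coordinates."""
    for m in matches:
        anchors = ",".join(str(a + 1) for a in m.anchors)
        yield f"{seq_id}\t{m.start + 1}\t{m.end}\t{anchors}"
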