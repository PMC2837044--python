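"""C2H2 zinc-finger detection and tandem-CWCH2 (tCWCH2) annotation.

A C2H2 zinc finger is the compact ``Cys-Xn-Cys-Xn-His-Xn-His`` unit; a
CWCH2 finger additionally carries a tryptophan two residues after the first
cysteine (``Cys-X-Trp-...``).  Two adjacent CWCH2 fingers whose linker (the
residues strictly between the last histidine of the first finger and the
first cysteine of the second) falls within configured bounds form a tandem
CWCH2 motif, the structural unit in which the two tryptophans share a
hydrophobic core.

Spacing presets mirror the bounded-gap search patterns used to survey the
motif: the strict preset encodes
``xCxWx(2,35)Cx(5,15)Hx(2,5)Hx(5,25)CxWx(1,3)Cx(5,17)Hx(2,5)Hx``
and the loose preset the widened variant
``xCxWx(1,35)Cx(5,15)Hx(2,5)Hx(5,42)CxWx(1,6)Cx(5,31)Hx(2,5)Hx``.
Bounds are stored as counts of residues strictly between the two anchors,
so e.g. ``C·x·W·x(2,35)·C`` becomes a c1->c2 between-count of 4..37.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .grammar import AMINO_ACIDS

VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

_TGEKP_RE = re.compile(r"TGE[KR]P")

#: Typical number of residues between the two cysteines of a CWCH2 finger
#: (x + W + 2 arbitrary); insertions beyond this count as "extra sequence".
INTRA_CYS_BASELINE = 4


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(f"record {self.id!r} has invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class Bounds:
    """Inclusive min/max count of residues strictly between two anchors."""

    min: int
    max: int

    def __contains__(self, k: int) -> bool:
        return self.min <= k <= self.max


@dataclass(frozen=True)
class SpacingConfig:
    """Anchor-spacing bounds for finger detection and tandem pairing.

    ``zf1_*``/``zf2_*`` hold the role-specific bounds applied when pairing
    fingers into a tandem; single-finger detection uses the union of the two
    roles' bounds so that a finger legal in either role is reported.
    """

    zf1_cc: Bounds
    zf1_ch: Bounds
    zf1_hh: Bounds
    linker: Bounds
    zf2_cc: Bounds
    zf2_ch: Bounds
    zf2_hh: Bounds

    @classmethod
    def strict(cls, **overrides) -> "SpacingConfig":
        cfg = cls(
            zf1_cc=Bounds(4, 37), zf1_ch=Bounds(5, 15), zf1_hh=Bounds(2, 5),
            linker=Bounds(5, 25),
            zf2_cc=Bounds(3, 5), zf2_ch=Bounds(5, 17), zf2_hh=Bounds(2, 5),
        )
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def loose(cls, **overrides) -> "SpacingConfig":
        cfg = cls(
            zf1_cc=Bounds(3, 37), zf1_ch=Bounds(5, 15), zf1_hh=Bounds(2, 5),
            linker=Bounds(5, 42),
            zf2_cc=Bounds(3, 8), zf2_ch=Bounds(5, 31), zf2_hh=Bounds(2, 5),
        )
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def preset(cls, name: str, **overrides) -> "SpacingConfig":
        try:
            return {"strict": cls.strict, "loose": cls.loose}[name](**overrides)
        except KeyError:
            raise ValueError(f"unknown spacing preset {name!r}") from None

    # union bounds used for role-agnostic single-finger scanning
    @property
    def cc(self) -> Bounds:
        return Bounds(min(self.zf1_cc.min, self.zf2_cc.min), max(self.zf1_cc.max, self.zf2_cc.max))

    @property
    def ch(self) -> Bounds:
        return Bounds(min(self.zf1_ch.min, self.zf2_ch.min), max(self.zf1_ch.max, self.zf2_ch.max))

    @property
    def hh(self) -> Bounds:
        return Bounds(min(self.zf1_hh.min, self.zf2_hh.min), max(self.zf1_hh.max, self.zf2_hh.max))


@dataclass(frozen=True)
class ZincFinger:
    """One C2H2 unit; anchor positions are 0-based."""

    c1: int
    c2: int
    h1: int
    h2: int
    is_cwch2: bool

    @property
    def span(self) -> tuple[int, int]:
        return (self.c1, self.h2 + 1)

    @property
    def anchors(self) -> tuple[int, int, int, int]:
        return (self.c1, self.c2, self.h1, self.h2)

    @property
    def intra_cys_count(self) -> int:
        return self.c2 - self.c1 - 1


@dataclass(frozen=True)
class TandemCWCH2:
    """A paired CWCH2-CWCH2 unit with its derived sequence features."""

    zf1: ZincFinger
    zf2: ZincFinger
    linker_seq: str
    phi1: str
    phi2: str
    extra1: int
    extra2: int
    has_tgekp: bool

    @property
    def linker_len(self) -> int:
        return len(self.linker_seq)

    @property
    def anchors(self) -> tuple[int, ...]:
        return self.zf1.anchors + self.zf2.anchors

    @property
    def pattern_anchors(self) -> tuple[int, ...]:
        """Anchor tuple in survey-pattern order (C,W,C,H,H twice): the C/H
        zinc anchors plus each finger's tryptophan at c1+2."""
        out: list[int] = []
        for zf in (self.zf1, self.zf2):
            out.extend((zf.c1, zf.c1 + 2, zf.c2, zf.h1, zf.h2))
        return tuple(out)


def has_tgekp(segment: str) -> bool:
    """True iff the canonical TGE(K/R)P linker pentamer occurs in segment."""
    return _TGEKP_RE.search(segment) is not None


def _finger_at(seq: str, c1: int, cfg: SpacingConfig) -> ZincFinger | None:
    """Smallest feasible (c2, h1, h2) assignment for a finger starting at c1."""
    n = len(seq)
    cc, ch, hh = cfg.cc, cfg.ch, cfg.hh
    for c2 in range(c1 + 1 + cc.min, min(c1 + 1 + cc.max, n - 1) + 1):
        if seq[c2] != "C":
            continue
        for h1 in range(c2 + 1 + ch.min, min(c2 + 1 + ch.max, n - 1) + 1):
            if seq[h1] != "H":
                continue
            for h2 in range(h1 + 1 + hh.min, min(h1 + 1 + hh.max, n - 1) + 1):
                if seq[h2] != "H":
                    continue
                w = c1 + 2
                return ZincFinger(
                    c1=c1, c2=c2, h1=h1, h2=h2,
                    is_cwch2=(w < c2 and seq[w] == "W"),
                )
    return None


def find_c2h2(record: ProteinRecord, cfg: SpacingConfig | None = None) -> list[ZincFinger]:
    """Left-to-right greedy scan for non-overlapping C2H2 fingers.

    At each candidate first cysteine the lexicographically smallest feasible
    (c2, h1, h2) triple is taken; the scan resumes after the finger's span.
    """
    cfg = cfg or SpacingConfig.strict()
    seq = record.sequence
    fingers: list[ZincFinger] = []
    i = 0
    while i < len(seq):
        if seq[i] == "C":
            zf = _finger_at(seq, i, cfg)
            if zf is not None:
                fingers.append(zf)
                i = zf.h2 + 1
                continue
        i += 1
    return fingers


def _role_ok(zf: ZincFinger, cc: Bounds, ch: Bounds, hh: Bounds) -> bool:
    return (
        zf.c2 - zf.c1 - 1 in cc
        and zf.h1 - zf.c2 - 1 in ch
        and zf.h2 - zf.h1 - 1 in hh
    )


def annotate_tandems(
    record: ProteinRecord,
    cfg: SpacingConfig | None = None,
    require_w: bool = True,
) -> list[TandemCWCH2]:
    """Pair adjacent CWCH2 fingers into tandem motifs.

    A pair (i, i+1) qualifies when finger i satisfies the first-finger
    bounds, finger i+1 the second-finger bounds, both carry the CWCH2
    tryptophan (unless ``require_w=False``, used when scoring tryptophan
    conservation across a family), and the linker length is within bounds.
    Each finger joins at most one tandem, resolved left to right.
    """
    cfg = cfg or SpacingConfig.strict()
    seq = record.sequence
    fingers = find_c2h2(record, cfg)
    tandems: list[TandemCWCH2] = []
    i = 0
    while i + 1 < len(fingers):
        f1, f2 = fingers[i], fingers[i + 1]
        linker_len = f2.c1 - f1.h2 - 1
        ok = (
            (not require_w or (f1.is_cwch2 and f2.is_cwch2))
            and _role_ok(f1, cfg.zf1_cc, cfg.zf1_ch, cfg.zf1_hh)
            and _role_ok(f2, cfg.zf2_cc, cfg.zf2_ch, cfg.zf2_hh)
            and linker_len in cfg.linker
        )
        if ok:
            linker_seq = seq[f1.h2 + 1 : f2.c1]
            tandems.append(
                TandemCWCH2(
                    zf1=f1, zf2=f2,
                    linker_seq=linker_seq,
                    phi1=seq[f1.h1 + 1],
                    phi2=seq[f2.h1 + 1],
                    extra1=max(0, f1.intra_cys_count - INTRA_CYS_BASELINE),
                    extra2=max(0, f2.intra_cys_count - INTRA_CYS_BASELINE),
                    has_tgekp=has_tgekp(linker_seq),
                )
            )
            i += 2
        else:
            i += 1
    return tandems


def linker_from_segment_headers(
    segments: Sequence[tuple[int, int]],
    max_len: int = 41,
    convention: str = "between",
) -> list[int]:
    """Linker lengths from ordered aligned-segment coordinates (1-based,
    inclusive), as used for PDOC00028-style ``NAME/start-end`` headers.

    convention="between" (default) counts residues strictly between two
    consecutive segments (next.start - prev.end - 1); convention="subtract"
    is the literal start-minus-end difference.  Lengths above ``max_len``
    are excluded (excessively long gaps are taken to separate independent
    finger arrays, not to be linkers); negative lengths are discarded with
    a warning.
    """
    if convention not in ("between", "subtract"):
        raise ValueError(f"unknown convention {convention!r}")
    offset = 1 if convention == "between" else 0
    for (s1, _e1), (s2, _e2) in zip(segments, segments[1:]):
        if s2 < s1:
            raise ValueError(f"segments not sorted by start: {s1} then {s2}")
    lengths: list[int] = []
    for (s1, e1), (s2, e2) in zip(segments, segments[1:]):
        length = s2 - e1 - offset
        if length < 0:
            warnings.warn(f"negative linker length {length} between ({s1},{e1}) and ({s2},{e2}); discarded")
            continue
        if length > max_len:
            continue
        lengths.append(length)
    return lengths


def parse_segment_id(header: str) -> tuple[str, int, int]:
    """Split a ``NAME/start-end`` aligned-segment identifier."""
    m = re.fullmatch(r"(.+)/(\d+)-(\d+)", header)
    if not m:
        raise ValueError(f"not a NAME/start-end segment id: {header!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


def linkers_from_segment_ids(headers: Iterable[str], max_len: int = 41, convention: str = "between") -> list[int]:
    """Group ``NAME/start-end`` ids by name and pool per-protein linker lengths."""
    by_name: dict[str, list[tuple[int, int]]] = {}
    for h in headers:
        name, start, end = parse_segment_id(h)
        by_name.setdefault(name, []).append((start, end))
    lengths: list[int] = []
    for segs in by_name.values():
        segs.sort()
        lengths.extend(linker_from_segment_headers(segs, max_len=max_len, convention=convention))
    return lengths
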