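"""Independent brute-force oracle for bounded-gap pattern matching.

Enumerates every placement of a pattern explicitly: the Cartesian product
of all gap-length choices at every start position, checking literals
directly against the sequence.  Deliberately naive and structurally
unrelated to the memoised matcher it cross-checks.
"""

from itertools import product

from tcwch2.grammar import MotifPattern


def brute_force_anchor_tuples(pattern: MotifPattern, seq: str) -> set[tuple[int, ...]]:
    gaps = [(e.min, e.max) for e in pattern.elements if e.kind == "gap"]
    results: set[tuple[int, ...]] = set()
    for start in range(len(seq) + 1):
        for lengths in product(*(range(lo, hi + 1) for lo, hi in gaps)):
            it = iter(lengths)
            pos = start
            anchors: list[int] = []
            ok = True
            for elem in pattern.elements:
                if elem.kind == "gap":
                    pos += next(it)
                    if pos > len(seq):
                        ok = False
                        break
                else:
                    if pos >= len(seq) or (seq[pos] not in elem.allowed and seq[pos] != "X"):
                        ok = False
                        break
                    anchors.append(pos)
                    pos += 1
            if ok:
                results.add(tuple(anchors))
    return results
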