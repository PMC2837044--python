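"""Consensus derivation from multiple alignments.

The procedure mirrors the standard three-step recipe for building a motif
consensus from an aligned family: (1) align (done upstream — alignments are
inputs here, so results do not depend on a bundled aligner), (2) drop
columns in which the gap character '-' occurs in more than half the rows,
(3) take the most frequent amino acid in each remaining column.  Per-column
residue frequencies (including the gap share) are exposed for logo tools.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .stats import FrequencyTable

GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """An equal-width multiple alignment over residues plus '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    source_columns: tuple[int, ...] | None = None  # indices into an unfiltered parent

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows have unequal width")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass(frozen=True)
class ConsensusResult:
    consensus: str
    kept_columns: tuple[int, ...]
    column_freqs: tuple[FrequencyTable, ...]


def filter_gap_columns(aln: Alignment, threshold: float = 0.5) -> Alignment:
    """Remove columns whose gap fraction is strictly greater than threshold.

    The retained columns' original indices are recorded on the result, so
    consensus positions can be mapped back to alignment coordinates.
    Idempotent: filtering an already-filtered alignment changes nothing.
    """
    n = aln.n_rows
    kept = [j for j in range(aln.width) if aln.column(j).count(GAP) / n <= threshold]
    parent = aln.source_columns
    source = tuple(parent[j] for j in kept) if parent is not None else tuple(kept)
    return Alignment(
        ids=aln.ids,
        rows=tuple("".join(row[j] for j in kept) for row in aln.rows),
        source_columns=source,
    )


def column_frequencies(aln: Alignment) -> list[FrequencyTable]:
    """Per-column symbol proportions, with '-' counted as a category."""
    return [FrequencyTable.from_residues(aln.column(j)) for j in range(aln.width)]


def modal_consensus(aln: Alignment, gap_threshold: float | None = None) -> ConsensusResult:
    """Most-frequent-residue consensus of a (gap-filtered) alignment.

    Gaps are never chosen as consensus symbols, though they appear in the
    reported column frequencies; ties between residues break to the
    lexicographically smallest.  Pass ``gap_threshold`` to apply
    :func:`filter_gap_columns` internally first.
    """
    if gap_threshold is not None:
        aln = filter_gap_columns(aln, gap_threshold)
    freqs = column_frequencies(aln)
    letters: list[str] = []
    for j, table in enumerate(freqs):
        residue_counts = {r: c for r, c in table.counts.items() if r != GAP}
        if not residue_counts:
            raise ValueError(f"column {j} contains only gaps; filter gap columns first")
        best = max(residue_counts.values())
        letters.append(min(r for r, c in residue_counts.items() if c == best))
    kept = aln.source_columns if aln.source_columns is not None else tuple(range(aln.width))
    return ConsensusResult(consensus="".join(letters), kept_columns=kept, column_freqs=tuple(freqs))


def frequency_matrix_tsv(result: ConsensusResult, alphabet: str | None = None) -> str:
    """Tab-separated per-column frequency matrix (rows = columns of the
    alignment), consumable by sequence-logo tools."""
    symbols = list(alphabet) if alphabet else sorted(
        {s for t in result.column_freqs for s in t.counts}
    )
    lines = ["column\tconsensus\t" + "\t".join(symbols)]
    for i, (col, letter, table) in enumerate(
        zip(result.kept_columns, result.consensus, result.column_freqs)
    ):
        f = table.freq
        lines.append(
            f"{col + 1}\t{letter}\t" + "\t".join(f"{f.get(s, 0.0):.4f}" for s in symbols)
        )
    return "\n".join(lines) + "\n"
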