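"""File formats: FASTA records, Clustal/aligned-FASTA alignments, TSV and
JSON reports, background-frequency tables and flat key=value configs.

Sequence parsing is delegated to Biopython (Bio.SeqIO / Bio.AlignIO); this
module adds the package's validation and normalisation rules on top
(uppercasing, '*' stripping, duplicate-id suffixing, ragged-row errors).
All emitted coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import ProteinRecord, TandemCWCH2
from .consensus import Alignment
from .simulate import SyntheticTruth
from .stats import FrequencyTable

#: TSV column order for tandem annotation reports (format v1).
TANDEM_TSV_COLUMNS = (
    "record_id",
    "zf1_c1", "zf1_c2", "zf1_h1", "zf1_h2",
    "zf2_c1", "zf2_c2", "zf2_h1", "zf2_h2",
    "linker_len", "linker_seq", "phi1", "phi2",
    "extra1", "extra2", "has_tgekp",
)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA.

    Sequences are uppercased; '*' stop characters are stripped with a
    warning; duplicate ids get a numeric suffix with a warning.  An empty
    file or a file not starting with a '>' header is an error naming the
    offending line.
    """
    path = Path(path)
    first_content_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first_content_line = (lineno, line)
                break
    if first_content_line is None:
        raise ValueError(f"{path}: empty FASTA file")
    lineno, line = first_content_line
    if not line.startswith(">"):
        raise ValueError(f"{path}: line {lineno}: expected a '>' FASTA header, got {line.strip()!r}")

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            warnings.warn(f"{path}: record {rec.id!r}: stripped '*' stop character(s)")
            seq = seq.replace("*", "")
        rec_id = rec.id
        if rec_id in seen:
            seen[rec_id] += 1
            new_id = f"{rec_id}.{seen[rec_id]}"
            warnings.warn(f"{path}: duplicate id {rec_id!r} renamed to {new_id!r}")
            rec_id = new_id
        else:
            seen[rec_id] = 1
        records.append(ProteinRecord(id=rec_id, sequence=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read a multiple alignment in aligned-FASTA or Clustal format.

    The format is sniffed from the first line when not given.  Clustal
    conservation lines are ignored by the parser; ragged rows are an error.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            head = fh.readline()
        fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unknown alignment format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"{path}: not a valid {fmt} alignment (ragged rows?): {exc}") from exc
    return Alignment(
        ids=tuple(rec.id for rec in msa),
        rows=tuple(str(rec.seq).upper() for rec in msa),
    )


def tandems_tsv(annotated: Sequence[tuple[str, TandemCWCH2]]) -> str:
    """Tandem annotations as TSV (coordinates 1-based inclusive)."""
    lines = ["# tcwch2 tandem report v1", "\t".join(TANDEM_TSV_COLUMNS)]
    for rec_id, t in annotated:
        row = (
            rec_id,
            *(a + 1 for a in t.zf1.anchors),
            *(a + 1 for a in t.zf2.anchors),
            t.linker_len, t.linker_seq, t.phi1, t.phi2,
            t.extra1, t.extra2, int(t.has_tgekp),
        )
        lines.append("\t".join(str(v) for v in row))
    return "\n".join(lines) + "\n"


def tandems_json(annotated: Sequence[tuple[str, TandemCWCH2]]) -> str:
    out = []
    for rec_id, t in annotated:
        out.append(
            {
                "record_id": rec_id,
                "zf1": {k: v + 1 for k, v in zip(("c1", "c2", "h1", "h2"), t.zf1.anchors)},
                "zf2": {k: v + 1 for k, v in zip(("c1", "c2", "h1", "h2"), t.zf2.anchors)},
                "linker_len": t.linker_len,
                "linker_seq": t.linker_seq,
                "phi1": t.phi1,
                "phi2": t.phi2,
                "extra1": t.extra1,
                "extra2": t.extra2,
                "has_tgekp": t.has_tgekp,
            }
        )
    return json.dumps({"format": "tcwch2-tandems-v1", "coordinates": "1-based inclusive", "tandems": out}, indent=2)


def read_tandems_tsv(path: str | Path) -> list[dict]:
    """Parse a tandem TSV report back into plain dicts (1-based coords)."""
    rows: list[dict] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            vals = line.split("\t")
            row = dict(zip(header, vals))
            for k in row:
                if k.startswith(("zf1_", "zf2_")) or k in ("linker_len", "extra1", "extra2", "has_tgekp"):
                    row[k] = int(row[k])
            row["has_tgekp"] = bool(row["has_tgekp"])
            rows.append(row)
    if header is None:
        raise ValueError(f"{path}: empty annotation file")
    return rows


def truths_tsv(truths: Sequence[SyntheticTruth]) -> str:
    lines = [
        "# tcwch2 synthetic truth v1",
        "record_id\tdecoy\tzf1_anchors\tzf2_anchors\tlinker_len\tphi1\tphi2\thas_tgekp",
    ]
    for t in truths:
        za = ",".join(str(a + 1) for a in t.zf1_anchors) if t.zf1_anchors else "-"
        zb = ",".join(str(a + 1) for a in t.zf2_anchors) if t.zf2_anchors else "-"
        lines.append(
            "\t".join(
                [
                    t.record_id, t.decoy, za, zb,
                    str(t.linker_len) if t.linker_len is not None else "-",
                    t.phi1 or "-", t.phi2 or "-", str(int(t.has_tgekp)),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_background_freqs(path: str | Path) -> FrequencyTable:
    """Two-column residue/frequency text file -> background FrequencyTable.

    Frequencies are renormalised (with a warning) if they do not sum to 1.
    """
    freqs: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'RESIDUE FREQ', got {line!r}")
            residue, value = parts[0], float(parts[1])
            if len(residue) != 1:
                raise ValueError(f"{path}: line {lineno}: residue must be one letter, got {residue!r}")
            freqs[residue.upper()] = value
    if not freqs:
        raise ValueError(f"{path}: no frequencies found")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        warnings.warn(f"{path}: frequencies sum to {total:.4f}; renormalising")
        freqs = {r: v / total for r, v in freqs.items()}
    return FrequencyTable.from_freqs(freqs)


def read_config(path: str | Path) -> dict:
    """Flat key=value config file; values parsed as int, float or string."""
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            for cast in (int, float):
                try:
                    out[key] = cast(value)
                    break
                except ValueError:
                    continue
            else:
                out[key] = value
    return out


def write_text(text: str, path: str | Path | TextIO) -> None:
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)
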