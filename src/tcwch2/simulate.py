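"""Seeded synthetic ZF-protein datasets with ground truth.

The generator emulates the statistical structure reported for the tandem
CWCH2 motif versus general C2H2 fingers, so every pipeline stage is
testable without database downloads:

* tCWCH2 linkers: discretised truncated normal, 11.8 +/- 4.4 aa on [5, 37];
* general-C2H2 (background) linkers: 8.1 +/- 5.0 aa on [1, 41];
* phi1/phi2 residues sampled from the published position-frequency tables
  (V/L/I = 34.1/22.0/35.3% at phi1; V/L/I/M = 14.3/14.3/39.1/24.2% at
  phi2; the unprinted remainder is spread uniformly over the other
  residues);
* the canonical TGE(K/R)P pentamer inserted into background linkers at a
  configurable rate (65% by default);
* "extra sequence" insertions between the first finger's cysteines;
* decoy records with broken anchors: the W->G tryptophan mutation that
  abolishes the tandem in vivo, spacing violations, and single fingers.

Every record is rescanned after generation with the preset's promised
spacing configuration and resampled (bounded retries) if the planted motif
is not recovered exactly, so the ground truth is recoverable by
construction.  All sampling flows from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .annotate import (
    Bounds,
    ProteinRecord,
    SpacingConfig,
    ZincFinger,
    annotate_tandems,
    find_c2h2,
    has_tgekp,
)
from .consensus import Alignment
from .grammar import AMINO_ACIDS

#: Filler alphabet for flanks, spacers and linkers: no C or H, so random
#: filler cannot create unintended zinc-finger anchors.
FILLER_ALPHABET = "".join(sorted(set(AMINO_ACIDS) - set("CH")))

DECOY_KINDS = ("w_to_g", "spacing_violation", "single_finger")


def _spread_table(stated: dict[str, float], exclude: str = "") -> dict[str, float]:
    """Complete a partially printed frequency table: the unstated mass is
    spread uniformly over the remaining standard residues."""
    rest = [a for a in AMINO_ACIDS if a not in stated and a not in exclude]
    remainder = 1.0 - sum(stated.values())
    if remainder < -1e-9:
        raise ValueError("stated frequencies exceed 1")
    out = dict(stated)
    for a in rest:
        out[a] = remainder / len(rest)
    return out


#: phi-position residue frequencies for tCWCH2 (printed V/L/I/M shares).
PHI1_TCWCH2_FREQS = _spread_table({"V": 0.341, "L": 0.220, "I": 0.353})
PHI2_TCWCH2_FREQS = _spread_table({"V": 0.143, "L": 0.143, "I": 0.391, "M": 0.242})
#: Background (general C2H2, PDOC00028-style) phi-position frequencies.
PHI_BACKGROUND_FREQS = _spread_table({"V": 0.042, "L": 0.095, "I": 0.053, "M": 0.078})


@dataclass(frozen=True)
class LinkerModel:
    """Discretised truncated normal over integer linker lengths [min, max]."""

    mean: float
    sd: float
    min: int
    max: int

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError(f"linker bounds min {self.min} > max {self.max}")
        if self.sd <= 0:
            raise ValueError("linker sd must be positive")

    @classmethod
    def preset(cls, name: str) -> "LinkerModel":
        presets = {
            "tcwch2": cls(11.8, 4.4, 5, 37),
            "background": cls(8.1, 5.0, 1, 41),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValueError(f"unknown linker preset {name!r}") from None

    def _pmf(self, lo: int | None = None, hi: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        lo = self.min if lo is None else max(lo, self.min)
        hi = self.max if hi is None else min(hi, self.max)
        k = np.arange(lo, hi + 1)
        p = norm.cdf(k + 0.5, self.mean, self.sd) - norm.cdf(k - 0.5, self.mean, self.sd)
        return k, p / p.sum()

    def expected_mean(self, lo: int | None = None, hi: int | None = None) -> float:
        """Analytic mean of the discretised truncated model (optionally
        further truncated to [lo, hi]); the generator's recovery truth."""
        k, p = self._pmf(lo, hi)
        return float((k * p).sum())

    def expected_sd(self, lo: int | None = None, hi: int | None = None) -> float:
        k, p = self._pmf(lo, hi)
        m = (k * p).sum()
        return float(math.sqrt((k * k * p).sum() - m * m))

    def sample(self, rng: np.random.Generator, lo: int | None = None, hi: int | None = None) -> int:
        """One draw: round a normal variate, rejecting out-of-bounds values."""
        lo = self.min if lo is None else max(lo, self.min)
        hi = self.max if hi is None else min(hi, self.max)
        while True:
            k = int(round(rng.normal(self.mean, self.sd)))
            if lo <= k <= hi:
                return k


#: Extra-sequence length distribution between the first finger's cysteines:
#: mostly no insertion, geometric tail, capped so the strict c1->c2 bound holds.
DEFAULT_EXTRA_PROBS: tuple[float, ...] = (0.8,) + tuple(
    0.2 * 0.55**k * 0.45 for k in range(30)
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_records: int
    linker_model: LinkerModel
    phi1_freqs: dict[str, float]
    phi2_freqs: dict[str, float]
    tgekp_rate: float = 0.0
    extra_probs: tuple[float, ...] = DEFAULT_EXTRA_PROBS
    decoy_fractions: dict[str, float] = field(default_factory=dict)
    flank_len: tuple[int, int] = (3, 10)
    scan_config: SpacingConfig = field(default_factory=SpacingConfig.strict)
    name: str = "tcwch2"
    max_retries: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.tgekp_rate <= 1.0:
            raise ValueError("tgekp_rate must be in [0,1]")
        if sum(self.decoy_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("decoy fractions sum above 1")
        unknown = set(self.decoy_fractions) - set(DECOY_KINDS)
        if unknown:
            raise ValueError(f"unknown decoy kinds {sorted(unknown)}")
        lo, hi = self.effective_linker_bounds
        if lo > hi:
            raise ValueError("linker model incompatible with the scan configuration")

    @classmethod
    def tcwch2(cls, seed: int, n_records: int, **overrides) -> "GeneratorConfig":
        cfg = cls(
            seed=seed, n_records=n_records,
            linker_model=LinkerModel.preset("tcwch2"),
            phi1_freqs=PHI1_TCWCH2_FREQS, phi2_freqs=PHI2_TCWCH2_FREQS,
            tgekp_rate=0.0, name="tcwch2",
        )
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def background(cls, seed: int, n_records: int, **overrides) -> "GeneratorConfig":
        cfg = cls(
            seed=seed, n_records=n_records,
            linker_model=LinkerModel.preset("background"),
            phi1_freqs=PHI_BACKGROUND_FREQS, phi2_freqs=PHI_BACKGROUND_FREQS,
            tgekp_rate=0.65,
            scan_config=SpacingConfig.strict(linker=Bounds(1, 41)),
            name="background",
        )
        return replace(cfg, **overrides) if overrides else cfg

    @property
    def effective_linker_bounds(self) -> tuple[int, int]:
        """Intersection of the linker model's range with the scan config's
        linker bounds — the range within which planted motifs are promised
        to be recoverable."""
        return (
            max(self.linker_model.min, self.scan_config.linker.min),
            min(self.linker_model.max, self.scan_config.linker.max),
        )

    def expected_linker_mean(self) -> float:
        lo, hi = self.effective_linker_bounds
        return self.linker_model.expected_mean(lo, hi)


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-record ground truth: what was planted and how it was perturbed."""

    record_id: str
    zf1_anchors: tuple[int, int, int, int] | None
    zf2_anchors: tuple[int, int, int, int] | None
    linker_len: int | None
    phi1: str | None
    phi2: str | None
    decoy: str = "none"
    has_tgekp: bool = False

    @property
    def anchors(self) -> tuple[int, ...]:
        out: tuple[int, ...] = ()
        if self.zf1_anchors:
            out += self.zf1_anchors
        if self.zf2_anchors:
            out += self.zf2_anchors
        return out


def _filler(rng: np.random.Generator, k: int) -> str:
    if k <= 0:
        return ""
    idx = rng.integers(0, len(FILLER_ALPHABET), size=k)
    return "".join(FILLER_ALPHABET[i] for i in idx)


def _sample_from_table(rng: np.random.Generator, table: dict[str, float]) -> str:
    residues = sorted(table)
    probs = np.array([table[r] for r in residues])
    return residues[int(rng.choice(len(residues), p=probs / probs.sum()))]


def _sample_extra(rng: np.random.Generator, probs: Sequence[float]) -> int:
    p = np.asarray(probs, dtype=float)
    return int(rng.choice(len(p), p=p / p.sum()))


def _build_finger(rng: np.random.Generator, phi: str, intra_count: int, spacer_len: int) -> tuple[str, tuple[int, int, int, int]]:
    """One CWCH2 finger; returns (sequence, (c1,c2,h1,h2) relative anchors).

    Layout: C x W <filler> C <spacer with central F> H phi x x H — the
    central phenylalanine mirrors the conserved hydrophobic position of the
    classical C2H2 consensus.
    """
    if intra_count < 2:
        raise ValueError("intra-cysteine count must be >= 2 to hold the tryptophan")
    spacer = list(_filler(rng, spacer_len))
    spacer[spacer_len // 2] = "F"
    seq = (
        "C" + _filler(rng, 1) + "W" + _filler(rng, intra_count - 2)
        + "C" + "".join(spacer) + "H" + phi + _filler(rng, 2) + "H"
    )
    c1 = 0
    c2 = intra_count + 1
    h1 = c2 + spacer_len + 1
    h2 = h1 + 4
    return seq, (c1, c2, h1, h2)


def _build_record(cfg: GeneratorConfig, rng: np.random.Generator, rec_id: str) -> tuple[ProteinRecord, SyntheticTruth]:
    lo, hi = cfg.effective_linker_bounds
    flank1 = _filler(rng, int(rng.integers(cfg.flank_len[0], cfg.flank_len[1] + 1)))
    extra1 = _sample_extra(rng, cfg.extra_probs)
    phi1 = _sample_from_table(rng, cfg.phi1_freqs)
    phi2 = _sample_from_table(rng, cfg.phi2_freqs)
    zf1_seq, zf1_rel = _build_finger(
        rng, phi1, intra_count=4 + extra1, spacer_len=int(rng.integers(5, 16))
    )
    linker_len = cfg.linker_model.sample(rng, lo, hi)
    linker = _filler(rng, linker_len)
    carries_tgekp = False
    if cfg.tgekp_rate > 0 and linker_len >= 5 and rng.random() < cfg.tgekp_rate:
        pent = "TGE" + ("K" if rng.random() < 0.5 else "R") + "P"
        linker = pent + linker[5:]
        carries_tgekp = True
    zf2_seq, zf2_rel = _build_finger(
        rng, phi2, intra_count=int(rng.integers(3, 6)), spacer_len=int(rng.integers(5, 16))
    )
    flank2 = _filler(rng, int(rng.integers(cfg.flank_len[0], cfg.flank_len[1] + 1)))

    off1 = len(flank1)
    off2 = off1 + len(zf1_seq) + linker_len
    seq = flank1 + zf1_seq + linker + zf2_seq + flank2
    truth = SyntheticTruth(
        record_id=rec_id,
        zf1_anchors=tuple(a + off1 for a in zf1_rel),
        zf2_anchors=tuple(a + off2 for a in zf2_rel),
        linker_len=linker_len,
        phi1=phi1, phi2=phi2,
        decoy="none",
        has_tgekp=carries_tgekp,
    )
    return ProteinRecord(id=rec_id, sequence=seq), truth


def mutate_decoy(
    record: ProteinRecord,
    truth: SyntheticTruth,
    kind: str,
    rng: np.random.Generator | None = None,
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Perturb a planted tandem into a decoy.

    * ``w_to_g`` — replace the first finger's tryptophan with glycine (the
      anchor-breaking mutation); fingers remain detectable, the tandem not.
    * ``spacing_violation`` — force the linker to 40 residues: outside the
      strict linker bound, inside the loose one.
    * ``single_finger`` — truncate the protein after the first finger.
    """
    if truth.zf1_anchors is None or truth.zf2_anchors is None:
        raise ValueError("record does not carry a planted tandem")
    rng = rng if rng is not None else np.random.default_rng(0)
    seq = record.sequence
    c1 = truth.zf1_anchors[0]
    if kind == "w_to_g":
        w = c1 + 2
        seq = seq[:w] + "G" + seq[w + 1 :]
        new_truth = replace(truth, decoy=kind)
    elif kind == "spacing_violation":
        target = 40
        h2 = truth.zf1_anchors[3]
        zf2_c1 = truth.zf2_anchors[0]
        old_len = truth.linker_len or (zf2_c1 - h2 - 1)
        if old_len > target:
            seq = seq[: h2 + 1] + seq[h2 + 1 + (old_len - target) :]
        else:
            seq = seq[: h2 + 1] + _filler(rng, target - old_len) + seq[h2 + 1 :]
        shift = target - old_len
        new_truth = replace(
            truth,
            decoy=kind,
            linker_len=target,
            zf2_anchors=tuple(a + shift for a in truth.zf2_anchors),
        )
    elif kind == "single_finger":
        h2 = truth.zf1_anchors[3]
        seq = seq[: h2 + 1] + _filler(rng, 3)
        new_truth = replace(truth, decoy=kind, zf2_anchors=None, linker_len=None, phi2=None)
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    return ProteinRecord(id=record.id, sequence=seq, description=record.description), new_truth


def _self_check(record: ProteinRecord, truth: SyntheticTruth, cfg: GeneratorConfig) -> bool:
    """Rescan a generated record: is exactly the planted structure found?"""
    scan = cfg.scan_config
    if truth.decoy == "none":
        tandems = annotate_tandems(record, scan)
        if len(tandems) != 1:
            return False
        t = tandems[0]
        return (
            t.anchors == truth.anchors
            and t.linker_len == truth.linker_len
            and t.phi1 == truth.phi1
            and t.phi2 == truth.phi2
            and t.has_tgekp == truth.has_tgekp
        )
    if truth.decoy == "w_to_g":
        return (
            len(find_c2h2(record, scan)) == 2
            and not annotate_tandems(record, scan)
        )
    if truth.decoy == "spacing_violation":
        loose = annotate_tandems(record, SpacingConfig.loose())
        return (
            not annotate_tandems(record, SpacingConfig.strict())
            and len(loose) == 1
            and loose[0].anchors == truth.anchors
        )
    if truth.decoy == "single_finger":
        return (
            len(find_c2h2(record, scan)) == 1
            and not annotate_tandems(record, scan)
        )
    raise ValueError(f"unknown decoy kind {truth.decoy!r}")


def generate_dataset(cfg: GeneratorConfig) -> tuple[list[ProteinRecord], list[SyntheticTruth]]:
    """Generate ``cfg.n_records`` seeded records plus ground truth.

    Deterministic given ``cfg.seed``.  Each record passes the post-build
    self-check (exact recovery of the planted structure, or the defined
    decoy behaviour) or is resampled, up to ``cfg.max_retries`` draws.
    """
    rng = np.random.default_rng(cfg.seed)
    kinds = list(cfg.decoy_fractions)
    fractions = np.array([cfg.decoy_fractions[k] for k in kinds])
    records: list[ProteinRecord] = []
    truths: list[SyntheticTruth] = []
    for i in range(cfg.n_records):
        u = rng.random()
        kind = "none"
        acc = 0.0
        for k, f in zip(kinds, fractions):
            acc += f
            if u < acc:
                kind = k
                break
        rec_id = f"{cfg.name}_{i:05d}"
        for _attempt in range(cfg.max_retries):
            record, truth = _build_record(cfg, rng, rec_id)
            if kind != "none":
                record, truth = mutate_decoy(record, truth, kind, rng)
            if _self_check(record, truth, cfg):
                break
        else:
            raise RuntimeError(f"retry budget exhausted generating record {rec_id}")
        records.append(record)
        truths.append(truth)
    return records, truths


def sample_background_linkers(
    n: int,
    seed: int | np.random.Generator,
    model: LinkerModel | None = None,
    tgekp_rate: float = 0.65,
) -> list[str]:
    """Sample a collection of general-C2H2 linker sequences directly.

    Each linker carries the TGE(K/R)P pentamer with probability exactly
    ``tgekp_rate``: carrier lengths are resampled until they can hold the
    pentamer (>= 5 aa), emulating an alignment-derived linker collection in
    which the stated share of sequences contains the canonical linker.
    """
    model = model or LinkerModel.preset("background")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    linkers: list[str] = []
    for _ in range(n):
        carrier = rng.random() < tgekp_rate
        length = model.sample(rng, lo=5 if carrier else None)
        seq = _filler(rng, length)
        if carrier:
            seq = "TGE" + ("K" if rng.random() < 0.5 else "R") + "P" + seq[5:]
        linkers.append(seq)
    return linkers


def perturbed_alignment(
    template: str,
    n_rows: int = 200,
    sub_rate: float = 0.1,
    seed: int = 0,
    gappy_col_fraction: float = 0.3,
    max_gap_fraction: float = 0.4,
    n_decoy_columns: int = 10,
) -> tuple[Alignment, dict]:
    """Synthesize a multiple alignment around a template consensus.

    Rows are the template with ``sub_rate`` random substitutions; a random
    subset of template columns receives gaps in at most ``max_gap_fraction``
    of rows (kept by the >50% filter), and ``n_decoy_columns`` majority-gap
    columns are interleaved (removed by the filter).  Gap counts are placed
    exactly, so the filter's keep/drop decisions are deterministic.
    Returns the alignment and an info dict with the decoy column indices.
    """
    if not template:
        raise ValueError("empty template")
    rng = np.random.default_rng(seed)
    residues = list(AMINO_ACIDS)
    columns: list[list[str]] = []
    is_decoy: list[bool] = []
    for ch in template:
        col = [ch if rng.random() >= sub_rate else residues[int(rng.integers(20))] for _ in range(n_rows)]
        if rng.random() < gappy_col_fraction:
            n_gaps = int(rng.integers(1, int(max_gap_fraction * n_rows) + 1))
            for r in rng.choice(n_rows, size=n_gaps, replace=False):
                col[r] = "-"
        columns.append(col)
        is_decoy.append(False)
    for _ in range(n_decoy_columns):
        n_gaps = int(rng.integers(n_rows // 2 + 1, int(0.9 * n_rows)))
        col = [residues[int(rng.integers(20))] for _ in range(n_rows)]
        for r in rng.choice(n_rows, size=n_gaps, replace=False):
            col[r] = "-"
        pos = int(rng.integers(0, len(columns) + 1))
        columns.insert(pos, col)
        is_decoy.insert(pos, True)
    rows = tuple("".join(col[r] for col in columns) for r in range(n_rows))
    ids = tuple(f"row{r:04d}" for r in range(n_rows))
    info = {"decoy_columns": tuple(j for j, d in enumerate(is_decoy) if d)}
    return Alignment(ids=ids, rows=rows), info
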