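"""Summary statistics and hypothesis tests for annotated tCWCH2 motifs.

Covers the quantities used to characterise the motif against general C2H2
fingers: linker-length summaries (mean +/- SD), the Mann-Whitney U test for
a location shift between linker populations, the F test for unequal linker
variance, the chi-square test of hydrophobic enrichment at the phi1/phi2
positions against a background residue distribution, per-position residue
frequency tables, and tryptophan-conservation percentages across a gene
family.

Distribution computations (U-test p-values, F and chi-square tails) are
delegated to scipy.stats; sample SDs use the n-1 denominator throughout.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .annotate import ProteinRecord, SpacingConfig, TandemCWCH2, annotate_tandems
from .grammar import AMINO_ACIDS

#: Residues summed as "hydrophobic" at each phi position.
PHI1_HYDROPHOBIC = frozenset("VLI")
PHI2_HYDROPHOBIC = frozenset("VLIM")


@dataclass(frozen=True)
class FrequencyTable:
    """Residue counts and proportions at one position (or column)."""

    counts: Mapping[str, int]
    n: int

    @classmethod
    def from_residues(cls, residues: Iterable[str]) -> "FrequencyTable":
        counts = Counter(residues)
        return cls(counts=dict(counts), n=sum(counts.values()))

    @classmethod
    def from_freqs(cls, freqs: Mapping[str, float], n: int = 0) -> "FrequencyTable":
        """A table carrying proportions only (n=0), e.g. a published background."""
        total = sum(freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"frequencies sum to {total}, not 1")
        obj = cls(counts={}, n=n)
        object.__setattr__(obj, "_freqs", dict(freqs))
        return obj

    @property
    def freq(self) -> dict[str, float]:
        fixed = getattr(self, "_freqs", None)
        if fixed is not None:
            return dict(fixed)
        if self.n == 0:
            return {}
        return {r: c / self.n for r, c in self.counts.items()}

    def freq_of(self, residue: str) -> float:
        return self.freq.get(residue, 0.0)

    def mass(self, residues: Iterable[str]) -> float:
        f = self.freq
        return sum(f.get(r, 0.0) for r in residues)


@dataclass(frozen=True)
class LinkerStats:
    n: int
    mean: float
    sd: float | None
    min: int
    max: int


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    extras: dict = field(default_factory=dict)

    @property
    def p_display(self) -> str:
        """Printable p-value; underflowed values render as '< 1e-300'."""
        if self.p_value == 0.0 or self.p_value < 1e-300:
            return "< 1e-300"
        return format(self.p_value, ".3g")


@dataclass(frozen=True)
class ConservationReport:
    family: str
    n: int
    conserved: int

    @property
    def percent(self) -> float:
        return 100.0 * self.conserved / self.n


def linker_summary(lengths: Sequence[int]) -> LinkerStats:
    """Mean, sample SD (n-1), min and max of linker lengths in residues."""
    if len(lengths) == 0:
        raise ValueError("no linker lengths supplied")
    if any(x < 0 for x in lengths):
        raise ValueError("linker lengths must be non-negative")
    arr = np.asarray(lengths, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return LinkerStats(
        n=len(arr), mean=float(arr.mean()), sd=sd,
        min=int(arr.min()), max=int(arr.max()),
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test for a location shift between samples.

    The null distribution of U is enumerated exactly for small tie-free
    samples (n_a + n_b <= 12); otherwise the normal approximation with tie
    and continuity corrections is used.  The reported statistic is U for
    sample ``a``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = list(a) + list(b)
    no_ties = len(set(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(a) + len(b) <= 12) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    u_a = float(res.statistic)
    return TestResult(
        method=f"mann-whitney ({method})",
        statistic=u_a,
        p_value=min(1.0, float(res.pvalue)),
        extras={"U_a": u_a, "U_b": len(a) * len(b) - u_a, "approximation": method},
    )


def f_variance_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided F test of equal variances, F = var(a)/var(b) (sample variances)."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if vb == 0.0:
        raise ValueError("zero variance in denominator sample")
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    return TestResult(
        method="f-variance",
        statistic=f,
        p_value=p,
        extras={"df": (dfa, dfb), "var_a": va, "var_b": vb},
    )


def chi2_vs_background(
    observed: FrequencyTable,
    background: FrequencyTable,
    hydrophobic_set: Iterable[str],
) -> TestResult:
    """Chi-square goodness of fit of observed counts against a background.

    Primary statistic: the 2-category (df=1) test on counts inside versus
    outside ``hydrophobic_set``, with expected counts from the background
    proportions scaled to the observed total.  The full per-residue
    goodness-of-fit statistic is returned in ``extras``.
    """
    if observed.n == 0:
        raise ValueError("observed table is empty")
    hydro = frozenset(hydrophobic_set)
    bg = background.freq
    uncovered = [r for r, c in observed.counts.items() if c > 0 and bg.get(r, 0.0) == 0.0]
    if uncovered:
        raise ValueError(f"background does not cover observed residues {sorted(uncovered)}")
    n = observed.n
    obs_in = sum(c for r, c in observed.counts.items() if r in hydro)
    p_in = background.mass(hydro)
    exp_in, exp_out = n * p_in, n * (1.0 - p_in)
    if exp_in == 0.0 or exp_out == 0.0:
        raise ValueError("expected count of zero in a category")
    stat, p = sps.chisquare([obs_in, n - obs_in], f_exp=[exp_in, exp_out])

    # secondary: per-residue table over the background support
    support = sorted(r for r, f in bg.items() if f > 0)
    obs_vec = np.array([observed.counts.get(r, 0) for r in support], dtype=float)
    exp_vec = np.array([n * bg[r] for r in support])
    full_stat, full_p = sps.chisquare(obs_vec, f_exp=exp_vec * (obs_vec.sum() / exp_vec.sum()))
    return TestResult(
        method="chi2 (2-category)",
        statistic=float(stat),
        p_value=min(1.0, float(p)),
        extras={
            "df": 1,
            "observed_in": obs_in,
            "expected_in": exp_in,
            "per_residue_stat": float(full_stat),
            "per_residue_p": float(full_p),
            "per_residue_df": len(support) - 1,
        },
    )


def phi_frequency(tandems: Sequence[TandemCWCH2]) -> tuple[FrequencyTable, FrequencyTable]:
    """Residue frequency tables at the phi1 and phi2 positions."""
    if len(tandems) == 0:
        raise ValueError("no tandem motifs supplied")
    return (
        FrequencyTable.from_residues(t.phi1 for t in tandems),
        FrequencyTable.from_residues(t.phi2 for t in tandems),
    )


def tryptophan_conservation(
    family: str,
    records: Sequence[ProteinRecord],
    cfg: SpacingConfig | None = None,
    tandem_index: int = 0,
) -> ConservationReport:
    """Share of family members with tryptophan at both CWCH2 W positions.

    The finger pair is located with the tryptophan requirement relaxed so
    that W-mutant members are still positioned; a record in which no pair
    can be located is counted as non-conserved with a warning.
    ``tandem_index`` selects the scored pair in proteins carrying more than
    one tandem (e.g. ZF1-2 versus ZF3-4 arrays).
    """
    if len(records) == 0:
        raise ValueError("no records supplied")
    cfg = cfg or SpacingConfig.strict()
    conserved = 0
    for rec in records:
        tandems = annotate_tandems(rec, cfg, require_w=False)
        if len(tandems) <= tandem_index:
            warnings.warn(f"{family}: no locatable finger pair in record {rec.id!r}; counted as non-conserved")
            continue
        t = tandems[tandem_index]
        seq = rec.sequence
        if seq[t.zf1.c1 + 2] == "W" and seq[t.zf2.c1 + 2] == "W":
            conserved += 1
    return ConservationReport(family=family, n=len(records), conserved=conserved)


def frequency_table_tsv(table: FrequencyTable, label: str = "") -> str:
    """Two-column residue/frequency text block, highest frequency first."""
    rows = sorted(table.freq.items(), key=lambda kv: (-kv[1], kv[0]))
    header = f"# residue frequencies{' - ' + label if label else ''} (n={table.n})\n"
    return header + "".join(f"{r}\t{f:.4f}\n" for r, f in rows)
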