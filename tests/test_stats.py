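"""Statistical summaries and hypothesis tests."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from tcwch2 import (
    FrequencyTable,
    GeneratorConfig,
    chi2_vs_background,
    f_variance_test,
    generate_dataset,
    linker_summary,
    mann_whitney,
    mutate_decoy,
    phi_frequency,
    tryptophan_conservation,
)
from tcwch2.annotate import SpacingConfig, annotate_tandems
from tcwch2.simulate import PHI_BACKGROUND_FREQS, PHI1_TCWCH2_FREQS
from tcwch2.stats import PHI1_HYDROPHOBIC, PHI2_HYDROPHOBIC


class TestLinkerSummary:
    def test_single_value_has_no_sd(self):
        s = linker_summary([8])
        assert (s.n, s.mean, s.sd, s.min, s.max) == (1, 8.0, None, 8, 8)

    def test_closed_form(self):
        s = linker_summary([6, 8, 10])
        assert s.mean == 8.0
        assert s.sd == pytest.approx(2.0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            linker_summary([])


def exact_two_sided_p(a, b):
    """Independent oracle: enumerate all rank assignments of the pooled
    sample and count U values at least as extreme as observed."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a, n_b = len(a), len(b)

    def u_of(idx_set):
        r = sum(ranks[pooled[i - 1]] for i in idx_set)
        return r - n_a * (n_a + 1) / 2

    u_obs = u_of_sample = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    mid = n_a * n_b / 2
    count = 0
    total = 0
    for idx in combinations(range(1, n_a + n_b + 1), n_a):
        u = u_of(idx)
        total += 1
        if abs(u - mid) >= abs(u_obs - mid):
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_are_symmetric(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_exact_separated_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(exact_two_sided_p([1, 2, 3], [4, 5, 6]))

    def test_swap_symmetry(self):
        a, b = [1.0, 5.0, 7.0, 9.0], [2.0, 3.0, 8.0]
        r1, r2 = mann_whitney(a, b), mann_whitney(b, a)
        assert r2.statistic == pytest.approx(len(a) * len(b) - r1.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_exact_vs_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            pool = rng.permutation(20)[:9].tolist()
            a, b = pool[:4], pool[4:]
            assert mann_whitney(a, b).p_value == pytest.approx(exact_two_sided_p(a, b))

    def test_exact_approx_agreement_at_boundary(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pool = rng.permutation(100)[:12].tolist()
            a, b = pool[:6], pool[6:]
            p_exact = mann_whitney(a, b).p_value
            p_approx = float(
                sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            )
            assert abs(p_exact - p_approx) <= 0.02

    def test_tie_relabelling_invariance(self):
        a, b = [1, 2, 2, 5], [2, 3, 4]
        a2, b2 = [10, 20, 20, 50], [20, 30, 40]
        assert mann_whitney(a, b).statistic == mann_whitney(a2, b2).statistic
        assert mann_whitney(a, b).p_value == pytest.approx(mann_whitney(a2, b2).p_value)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1])


class TestFVarianceTest:
    def test_equal_samples(self):
        res = f_variance_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_variance_ratio(self):
        b = [0.0, 1.0, 2.0, 3.0, 4.0]
        a = [2 * x for x in b]
        assert f_variance_test(a, b).statistic == pytest.approx(4.0)

    def test_zero_denominator_variance(self):
        with pytest.raises(ValueError):
            f_variance_test([1, 2, 3], [5, 5, 5])

    def test_p_uniform_under_null(self):
        rng = np.random.default_rng(3)
        ps = [
            f_variance_test(rng.normal(size=20), rng.normal(size=20)).p_value
            for _ in range(1000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 1e-3


class TestChi2VsBackground:
    def test_matching_background_gives_zero(self):
        bg = FrequencyTable.from_freqs({"V": 0.25, "L": 0.25, "A": 0.5})
        obs = FrequencyTable.from_residues(["V"] * 25 + ["L"] * 25 + ["A"] * 50)
        res = chi2_vs_background(obs, bg, {"V", "L"})
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # 91/100 hydrophobic against a background hydrophobic rate of 0.268
        bg = FrequencyTable.from_freqs({"V": 0.268, "A": 0.732})
        obs = FrequencyTable.from_residues(["V"] * 91 + ["A"] * 9)
        expected = (91 - 26.8) ** 2 / 26.8 + (9 - 73.2) ** 2 / 73.2
        res = chi2_vs_background(obs, bg, {"V"})
        assert res.statistic == pytest.approx(expected)
        assert res.extras["df"] == 1

    def test_uncovered_residue_is_an_error(self):
        bg = FrequencyTable.from_freqs({"V": 1.0})
        obs = FrequencyTable.from_residues(["V", "W"])
        with pytest.raises(ValueError, match="cover"):
            chi2_vs_background(obs, bg, {"V"})

    def test_phi1_enrichment_is_detected(self):
        rng = np.random.default_rng(4)
        residues = sorted(PHI1_TCWCH2_FREQS)
        probs = np.array([PHI1_TCWCH2_FREQS[r] for r in residues])
        draws = rng.choice(residues, size=10_000, p=probs / probs.sum())
        obs = FrequencyTable.from_residues(draws)
        bg = FrequencyTable.from_freqs(PHI_BACKGROUND_FREQS)
        res = chi2_vs_background(obs, bg, PHI1_HYDROPHOBIC)
        assert res.p_value < 1e-10
        assert res.extras["observed_in"] > res.extras["expected_in"]  # enrichment, not depletion

    def test_underflowed_p_is_displayed_as_bound(self):
        bg = FrequencyTable.from_freqs({"V": 0.01, "A": 0.99})
        obs = FrequencyTable.from_residues(["V"] * 9_000 + ["A"] * 1_000)
        res = chi2_vs_background(obs, bg, {"V"})
        assert res.p_value == 0.0
        assert res.p_display == "< 1e-300"


class TestPhiFrequency:
    def test_two_tandem_split(self, consensus_record):
        t1 = annotate_tandems(consensus_record)[0]
        t2 = t1.__class__(**{**t1.__dict__, "phi1": "I"})
        phi1, _ = phi_frequency([t1, t2])
        assert phi1.freq == {"V": 0.5, "I": 0.5}

    def test_worked_example_frequencies(self, consensus_record):
        phi1, phi2 = phi_frequency(annotate_tandems(consensus_record))
        assert phi1.freq == {"V": 1.0}
        assert phi2.freq == {"I": 1.0}

    def test_proportions_sum_to_one(self):
        records, _ = generate_dataset(GeneratorConfig.tcwch2(seed=5, n_records=100))
        tandems = [t for r in records for t in annotate_tandems(r)]
        phi1, phi2 = phi_frequency(tandems)
        for table in (phi1, phi2):
            assert math.isclose(sum(table.freq.values()), 1.0, abs_tol=1e-9)
            assert sum(table.counts.values()) == table.n

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            phi_frequency([])


def _family(seed: int, n: int, n_mutant: int):
    records, truths = generate_dataset(GeneratorConfig.tcwch2(seed=seed, n_records=n))
    rng = np.random.default_rng(seed + 1)
    out = []
    for i, (rec, truth) in enumerate(zip(records, truths)):
        if i < n_mutant:
            rec, _ = mutate_decoy(rec, truth, "w_to_g", rng)
        out.append(rec)
    return out


class TestTryptophanConservation:
    def test_family_percentages(self):
        # 14 of 16 conserved -> 87.5%; 37 of 40 -> 92.5%
        rep = tryptophan_conservation("famA", _family(seed=6, n=16, n_mutant=2))
        assert (rep.n, rep.percent) == (16, 87.5)
        rep = tryptophan_conservation("famB", _family(seed=7, n=40, n_mutant=3))
        assert (rep.n, rep.percent) == (40, 92.5)

    def test_fully_conserved_family(self):
        rep = tryptophan_conservation("famC", _family(seed=8, n=10, n_mutant=0))
        assert rep.percent == 100.0

    def test_unlocatable_record_counts_against_with_warning(self):
        from tcwch2 import ProteinRecord

        family = _family(seed=9, n=3, n_mutant=0) + [ProteinRecord(id="bare", sequence="AAAA")]
        with pytest.warns(UserWarning, match="no locatable"):
            rep = tryptophan_conservation("famD", family)
        assert (rep.n, rep.conserved) == (4, 3)

    def test_matches_brute_force_per_record_check(self, strict_cfg):
        family = _family(seed=10, n=30, n_mutant=7)
        rep = tryptophan_conservation("famE", family)
        brute = 0
        for rec in family:
            tandems = annotate_tandems(rec, strict_cfg, require_w=False)
            if tandems:
                t = tandems[0]
                s = rec.sequence
                brute += s[t.zf1.c1 + 2] == "W" == s[t.zf2.c1 + 2]
        assert rep.conserved == brute == 23
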