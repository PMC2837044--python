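"""Synthetic-data generator: determinism, ground-truth recovery, and the
statistical structure of the emulated datasets."""

import numpy as np
import pytest

from tcwch2 import (
    GeneratorConfig,
    LinkerModel,
    ProteinRecord,
    SpacingConfig,
    annotate_tandems,
    find_c2h2,
    generate_dataset,
    has_tgekp,
    linker_summary,
    mutate_decoy,
    phi_frequency,
    sample_background_linkers,
)
from tcwch2.simulate import FILLER_ALPHABET, PHI1_TCWCH2_FREQS, PHI2_TCWCH2_FREQS


class TestDeterminism:
    def test_same_seed_identical_output(self):
        a, ta = generate_dataset(GeneratorConfig.tcwch2(seed=21, n_records=50))
        b, tb = generate_dataset(GeneratorConfig.tcwch2(seed=21, n_records=50))
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert ta == tb

    def test_different_seed_differs(self):
        a, _ = generate_dataset(GeneratorConfig.tcwch2(seed=21, n_records=10))
        b, _ = generate_dataset(GeneratorConfig.tcwch2(seed=22, n_records=10))
        assert [r.sequence for r in a] != [r.sequence for r in b]


class TestGroundTruthRoundTrip:
    def test_planted_tandems_recovered_exactly(self, strict_cfg):
        records, truths = generate_dataset(GeneratorConfig.tcwch2(seed=23, n_records=300))
        for rec, truth in zip(records, truths):
            (t,) = annotate_tandems(rec, strict_cfg)
            assert t.anchors == truth.anchors
            assert t.linker_len == truth.linker_len
            assert (t.phi1, t.phi2) == (truth.phi1, truth.phi2)

    def test_filler_has_no_zinc_anchors(self):
        assert not set("CH") & set(FILLER_ALPHABET)

    def test_all_w_to_g_decoys_yield_zero_tandems(self, strict_cfg):
        records, truths = generate_dataset(
            GeneratorConfig.tcwch2(seed=24, n_records=50, decoy_fractions={"w_to_g": 1.0})
        )
        assert all(t.decoy == "w_to_g" for t in truths)
        assert all(annotate_tandems(r, strict_cfg) == [] for r in records)

    def test_mixed_decoys_follow_their_contracts(self, strict_cfg, loose_cfg):
        records, truths = generate_dataset(
            GeneratorConfig.tcwch2(
                seed=25, n_records=120,
                decoy_fractions={"w_to_g": 0.2, "spacing_violation": 0.2, "single_finger": 0.2},
            )
        )
        kinds = {t.decoy for t in truths}
        assert kinds == {"none", "w_to_g", "spacing_violation", "single_finger"}
        for rec, truth in zip(records, truths):
            n_strict = len(annotate_tandems(rec, strict_cfg))
            if truth.decoy == "none":
                assert n_strict == 1
            else:
                assert n_strict == 0
            if truth.decoy == "spacing_violation":
                assert len(annotate_tandems(rec, loose_cfg)) == 1
            if truth.decoy == "single_finger":
                assert len(find_c2h2(rec, strict_cfg)) == 1


class TestMutateDecoy:
    def test_unknown_kind_is_an_error(self):
        (rec,), (truth,) = generate_dataset(GeneratorConfig.tcwch2(seed=26, n_records=1))
        with pytest.raises(ValueError, match="unknown decoy kind"):
            mutate_decoy(rec, truth, "frameshift")

    def test_single_finger_requires_planted_tandem(self):
        (rec,), (truth,) = generate_dataset(GeneratorConfig.tcwch2(seed=27, n_records=1))
        cut, t2 = mutate_decoy(rec, truth, "single_finger")
        assert t2.zf2_anchors is None
        with pytest.raises(ValueError, match="planted tandem"):
            mutate_decoy(cut, t2, "w_to_g")


class TestStatisticalStructure:
    def test_linker_moments_match_model(self, strict_cfg):
        cfg = GeneratorConfig.tcwch2(seed=28, n_records=5000)
        records, _ = generate_dataset(cfg)
        lengths = [annotate_tandems(r, strict_cfg)[0].linker_len for r in records]
        s = linker_summary(lengths)
        lo, hi = cfg.effective_linker_bounds
        se = cfg.linker_model.expected_sd(lo, hi) / np.sqrt(len(lengths))
        assert abs(s.mean - cfg.expected_linker_mean()) <= 3 * se
        assert lo <= s.min and s.max <= hi

    def test_phi_frequencies_match_tables(self, strict_cfg):
        records, _ = generate_dataset(GeneratorConfig.tcwch2(seed=29, n_records=5000))
        tandems = [annotate_tandems(r, strict_cfg)[0] for r in records]
        phi1, phi2 = phi_frequency(tandems)
        n = len(tandems)
        for table, ref in ((phi1, PHI1_TCWCH2_FREQS), (phi2, PHI2_TCWCH2_FREQS)):
            for residue in "VLIM":
                p = ref[residue]
                se = np.sqrt(p * (1 - p) / n)
                assert abs(table.freq_of(residue) - p) <= 3 * se + 1e-12

    def test_background_tgekp_rate_exact_by_construction(self):
        linkers = sample_background_linkers(3000, seed=30)
        rate = np.mean([has_tgekp(s) for s in linkers])
        se = np.sqrt(0.65 * 0.35 / 3000)
        assert abs(rate - 0.65) <= 3 * se
        assert all(len(s) >= 5 for s in linkers if has_tgekp(s))

    def test_background_records_carry_pentamer_only_in_linker(self, strict_cfg):
        cfg = GeneratorConfig.background(seed=31, n_records=300)
        records, truths = generate_dataset(cfg)
        for rec, truth in zip(records, truths):
            (t,) = annotate_tandems(rec, cfg.scan_config)
            assert t.has_tgekp == truth.has_tgekp
            if truth.has_tgekp:
                assert has_tgekp(t.linker_seq)


class TestConfigValidation:
    def test_bad_linker_bounds(self):
        with pytest.raises(ValueError, match="min.*max"):
            LinkerModel(10.0, 2.0, 20, 10)

    def test_unsatisfiable_scan_intersection(self):
        with pytest.raises(ValueError, match="incompatible"):
            GeneratorConfig.tcwch2(seed=1, n_records=1, linker_model=LinkerModel(30.0, 2.0, 28, 37))

    def test_decoy_fractions_validated(self):
        with pytest.raises(ValueError, match="decoy"):
            GeneratorConfig.tcwch2(seed=1, n_records=1, decoy_fractions={"bogus": 0.5})
        with pytest.raises(ValueError, match="sum"):
            GeneratorConfig.tcwch2(seed=1, n_records=1, decoy_fractions={"w_to_g": 0.7, "single_finger": 0.7})

    def test_record_sequences_are_valid_proteins(self):
        records, _ = generate_dataset(GeneratorConfig.background(seed=32, n_records=20))
        for r in records:
            assert isinstance(r, ProteinRecord)  # constructor validates the alphabet
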