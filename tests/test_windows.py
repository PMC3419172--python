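from fractions import Fraction

import numpy as np
import pytest

from winhap import (
    GenotypeMatrix,
    PhasingSolution,
    apply_window,
    compatible_pairs,
    find_long_gaps,
    long_gap_correction,
    sweep_windows,
    uneven_block_fixture,
    window_frequencies,
)


@pytest.fixture(scope="module")
def block():
    pool, G, truth = uneven_block_fixture()
    return pool, G, truth


class TestWindowFrequencies:
    def test_identical_rows_single_segment(self):
        sol = PhasingSolution.from_hap_strings(["010", "010", "010", "010"])
        assert window_frequencies(sol, (0, 3)) == {"010": 4}

    def test_uneven_block_counts(self, block):
        # the fixture drops one unpaired chromosome of the most common type
        _, _, truth = block
        assert window_frequencies(truth, (0, 5)) == {
            "00000": 65, "01001": 24, "11110": 10, "01000": 6,
            "11000": 1, "11011": 1, "00001": 1,
        }

    def test_segments_with_missing_excluded(self):
        sol = PhasingSolution.from_hap_strings(["0?", "00"])
        assert window_frequencies(sol, (0, 2)) == {"00": 1}

    def test_window_out_of_range(self):
        sol = PhasingSolution.from_hap_strings(["00", "00"])
        with pytest.raises(ValueError, match="out of range"):
            window_frequencies(sol, (1, 2))


class TestCompatiblePairs:
    def test_worked_example_two_pairs(self, block):
        pool, _, _ = block
        table = compatible_pairs("02002", dict(pool))
        assert [(p.hap_a, p.hap_b) for p in table.pairs] == [
            ("00000", "01001"), ("00001", "01000"),
        ]
        assert table.s == 2

    def test_worked_example_weight_is_99_percent(self, block):
        pool, _, _ = block
        table = compatible_pairs("02002", dict(pool))
        top = table.pairs[0]
        assert (top.freq_a * top.freq_b) == 66 * 24
        assert top.weight == pytest.approx(float(Fraction(1584, 1590)))
        assert round(top.weight * 100) in (99, 100)  # printed as "99%"
        assert table.pairs[1].weight == pytest.approx(float(Fraction(6, 1590)))

    def test_double_het_uniform_pairs(self):
        freqs = {"00": 1, "11": 1, "01": 1, "10": 1}
        table = compatible_pairs("22", freqs)
        assert {(p.hap_a, p.hap_b) for p in table.pairs} == {("00", "11"), ("01", "10")}
        assert all(p.weight == pytest.approx(0.5) for p in table.pairs)

    def test_weights_sum_to_one(self, block):
        pool, _, _ = block
        for segment in ("02002", "22220", "2?0?2"):
            table = compatible_pairs(segment, dict(pool))
            if table.s:
                assert sum(p.weight for p in table.pairs) == pytest.approx(1.0)

    def test_empty_pair_list_allowed(self):
        assert compatible_pairs("22", {"00": 3}).pairs == []

    def test_missing_matches_anything(self):
        table = compatible_pairs("?2", {"00": 2, "01": 1, "10": 1})
        assert {(p.hap_a, p.hap_b) for p in table.pairs} == {
            ("00", "01"), ("01", "10"),
        }


class TestApplyWindow:
    def _corrupted(self, block):
        _, G, truth = block
        sol = truth.copy()
        # individual 11 is truly (00000, 01001); mis-phase it
        sol.haplotypes[22] = np.array([0, 1, 0, 0, 0], dtype=np.int8)
        sol.haplotypes[23] = np.array([0, 0, 0, 0, 1], dtype=np.int8)
        return G, truth, sol, 11

    def test_replacement_fires_above_threshold(self, block):
        G, truth, sol, i = self._corrupted(block)
        assert G.to_strings()[i] == "02002"
        changed = apply_window(sol, i, (0, 5), tau=0.70)
        assert changed
        got = {tuple(sol.haplotypes[2 * i]), tuple(sol.haplotypes[2 * i + 1])}
        assert got == {(0, 0, 0, 0, 0), (0, 1, 0, 0, 1)}

    def test_threshold_not_met_keeps_phasing(self):
        sol = PhasingSolution.from_hap_strings(["01", "10"])
        # cis pair product 6, trans product 4 -> top weight 0.6 < 0.70
        freqs = {"00": 3, "11": 2, "01": 2, "10": 2}
        assert not apply_window(sol, 0, (0, 2), tau=0.70, freqs=freqs)
        assert sol.to_strings() == ["01", "10"]

    def test_all_homozygous_segment_untouched(self):
        sol = PhasingSolution.from_hap_strings(["00", "00", "01", "01"])
        assert not apply_window(sol, 0, (0, 2), tau=0.70)

    def test_tau_validated(self):
        sol = PhasingSolution.from_hap_strings(["01", "10"])
        with pytest.raises(ValueError):
            apply_window(sol, 0, (0, 2), tau=0.0)


class TestSweepWindows:
    def test_too_few_sites_unchanged(self):
        sol = PhasingSolution.from_hap_strings(["01", "10"])
        before = sol.haplotypes.copy()
        sweep_windows(sol, l_min=3, l_max=10)
        assert np.array_equal(sol.haplotypes, before)

    def test_identical_population_is_fixed_point(self):
        rows = ["01011", "00110"] * 10
        sol = PhasingSolution.from_hap_strings(rows)
        before = sol.haplotypes.copy()
        sweep_windows(sol)
        assert np.array_equal(sol.haplotypes, before)

    def test_sweep_corrects_minority_phasing(self, block):
        _, G, truth = block
        sol = truth.copy()
        sol.haplotypes[22] = np.array([0, 1, 0, 0, 0], dtype=np.int8)
        sol.haplotypes[23] = np.array([0, 0, 0, 0, 1], dtype=np.int8)
        sweep_windows(sol)
        got = {tuple(sol.haplotypes[22]), tuple(sol.haplotypes[23])}
        assert got == {(0, 0, 0, 0, 0), (0, 1, 0, 0, 1)}

    def test_sweep_idempotent_after_fix(self, block):
        _, G, truth = block
        sol = truth.copy()
        sol.haplotypes[22] = np.array([0, 1, 0, 0, 0], dtype=np.int8)
        sol.haplotypes[23] = np.array([0, 0, 0, 0, 1], dtype=np.int8)
        sweep_windows(sol)
        once = sol.haplotypes.copy()
        sweep_windows(sol)
        assert np.array_equal(sol.haplotypes, once)

    def test_bad_lengths_rejected(self):
        sol = PhasingSolution.from_hap_strings(["01", "10"])
        with pytest.raises(ValueError):
            sweep_windows(sol, l_min=5, l_max=3)


class TestLongGapCorrection:
    def _population(self, rows, genos):
        return PhasingSolution.from_hap_strings(
            rows, GenotypeMatrix.from_strings(genos))

    def test_gap_detection(self):
        g = "2" + "0" * 12 + "2"
        sol = PhasingSolution.from_hap_strings(
            ["0" * 14, "1" + "0" * 12 + "1"],
            GenotypeMatrix.from_strings([g]))
        assert find_long_gaps(sol, l_max=10) == [(0, 0, 13)]
        assert find_long_gaps(sol, l_max=13) == []

    def test_missing_trans_class_enforces_cis(self):
        # no other haplotype is 01 or 10 at the endpoints -> w_trans = +inf
        geno = ["2" + "0" * 12 + "2", "0" * 14, "1" * 14]
        rows = [
            "0" * 13 + "1",            # currently trans (0...1)
            "1" + "0" * 12 + "0",      # currently trans (1...0)
            "0" * 14, "0" * 14,        # class 00
            "1" * 14, "1" * 14,        # class 11
        ]
        sol = self._population(rows, geno)
        assert long_gap_correction(sol, 0, 0, 13)
        h1, h2 = sol.pair(0)
        assert h1[0] == h1[13] and h2[0] == h2[13]  # cis enforced

    def test_zero_distance_cis_wins(self):
        geno = ["2" + "0" * 12 + "2", "0" * 14, "1" + "0" * 12 + "1"]
        rows = [
            "0" * 14, "1" + "0" * 12 + "1",   # already cis
            "0" * 14, "0" * 14,               # class 00, distance 0
            "1" + "0" * 12 + "1", "1" + "0" * 12 + "1",  # class 11, distance 0
        ]
        sol = self._population(rows, geno)
        assert not long_gap_correction(sol, 0, 0, 13)  # w_cis = 0, keep

    def test_hand_computed_distances_pick_smaller_product(self):
        # interior genotype of individual 0 is 000000000000 (12 sites);
        # voters: class 00 distances {1}, class 11 {2}  -> w_cis = 2
        #         class 01 distances {0}, class 10 {3}  -> w_trans = 0
        # trans wins, individual 0 is currently cis -> suffix flip at p_e
        geno = ["2" + "0" * 12 + "2", "?" * 14, "?" * 14]
        rows = [
            "0" * 14,                      # cis rows of individual 0
            "1" + "0" * 12 + "1",
            "0" + "100000000000" + "0",    # class 00, d=1
            "1" + "110000000000" + "1",    # class 11, d=2
            "0" + "000000000000" + "1",    # class 01, d=0
            "1" + "111000000000" + "0",    # class 10, d=3
        ]
        sol = self._population(rows, geno)
        assert long_gap_correction(sol, 0, 0, 13)
        h1, h2 = sol.pair(0)
        assert h1[0] != h1[13]  # now trans
        assert h2[0] != h2[13]

    def test_both_classes_empty_keeps_current(self):
        geno = ["2" + "0" * 12 + "2"]
        rows = ["0" * 13 + "1", "1" + "0" * 12 + "0"]
        sol = self._population(rows, geno)
        assert not long_gap_correction(sol, 0, 0, 13)


class TestOracleEquivalence:
    def test_pairs_match_exhaustive_enumeration(self, pair_oracle):
        rng = np.random.default_rng(91)
        for _ in range(200):
            l = int(rng.integers(1, 7))
            segment = "".join(rng.choice(list("0122?"), size=l))
            if segment.count("2") > 3:
                continue
            freqs = {
                "".join(rng.choice(list("01"), size=l)): int(rng.integers(1, 9))
                for _ in range(int(rng.integers(0, 9)))
            }
            got = {(p.hap_a, p.hap_b)
                   for p in compatible_pairs(segment, freqs).pairs}
            assert got == pair_oracle(segment, freqs)
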