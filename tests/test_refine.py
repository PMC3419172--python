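import numpy as np
import pytest

from winhap import (
    MISSING,
    GenotypeMatrix,
    PhasingSolution,
    impute_missing,
    is_compatible,
    parsimony_refine,
    recombine_at,
)
from conftest import random_genotype_matrix
from winhap import phase_genotype_initial


def sol_from(rows, genos=None):
    G = GenotypeMatrix.from_strings(genos) if genos else None
    return PhasingSolution.from_hap_strings(rows, G)


class TestImputeMissing:
    def test_perfect_match_votes_zero(self):
        # the identical rows carry 1 at the column (distance 0); the
        # 0-carriers sit at distance 1, so allele 1 wins
        sol = sol_from(
            ["010?0", "010?0", "01010", "01010", "00000", "00000"],
            ["010?0", "01010", "00000"],
        )
        out = impute_missing(sol)
        assert out.haplotypes[0, 3] == 1

    def test_empty_allele_class_falls_back(self):
        # no other row carries 1 at the column -> allele 0
        sol = sol_from(["1?1", "1?1", "101", "101"], ["1?1", "101"])
        out = impute_missing(sol)
        assert out.haplotypes[0, 1] == 0

    def test_minority_class_with_smaller_distance_wins(self):
        # class-0 voters are far (distances 4 and 4 -> w0 = 8), the class-1
        # voters are near (1 each -> w1 = 2): the minority allele 1 is chosen
        rows = [
            "1111?1111", "0000?0000",   # individual with the missing cell
            "000001111", "111100000",   # both carry 0 at the column
            "111111110", "111111110",   # both carry 1 at the column
        ]
        genos = ["2222?2222", "222202222", "111111110"]
        sol = sol_from(rows, genos)
        out = impute_missing(sol)
        assert out.haplotypes[0, 4] == 1

    def test_removes_every_missing_and_keeps_rest(self):
        rng = np.random.default_rng(5)
        G = random_genotype_matrix(rng, 10, 20, missing_rate=0.15)
        sol = phase_genotype_initial(G)
        out = impute_missing(sol)
        assert not out.has_missing()
        known = sol.haplotypes != MISSING
        assert np.array_equal(out.haplotypes[known], sol.haplotypes[known])
        assert is_compatible(out)

    def test_no_voters_anywhere_gives_major_allele(self):
        sol = sol_from(["??", "??"], ["??"])
        out = impute_missing(sol)
        assert out.haplotypes.tolist() == [[0, 0], [0, 0]]


class TestRecombineAt:
    def test_suffix_exchange_example(self):
        assert recombine_at("11010010", "01100101", 3) == (
            "11000101", "01110010",
        )

    def test_switch_at_first_site_swaps_rows(self):
        assert recombine_at("0101", "1010", 0) == ("1010", "0101")

    def test_homozygous_site_rejected(self):
        with pytest.raises(ValueError, match="heterozygous"):
            recombine_at("0101", "0001", 0)

    def test_involution(self):
        a, b = recombine_at("11010010", "01100101", 3)
        assert recombine_at(a, b, 3) == ("11010010", "01100101")

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            recombine_at("01", "10", 5)


class TestParsimonyRefine:
    def test_identical_rows_unchanged(self):
        sol = sol_from(["0101", "0101", "0101", "0101"])
        out = parsimony_refine(sol)
        assert np.array_equal(out.haplotypes, sol.haplotypes)

    def test_accepts_merge(self):
        # switching individual 0 at site 1 turns {01,10,00,11} into {00,11}
        sol = sol_from(["01", "10", "00", "11"])
        moves = []
        out = parsimony_refine(sol, record=moves)
        assert out.distinct_haplotype_count() == 2
        assert moves[0].individual == 0 and moves[0].site == 1
        assert moves[0].delta < 0

    def test_no_improving_switch_is_fixed_point(self):
        sol = sol_from(["01", "10"])
        out = parsimony_refine(sol)
        assert np.array_equal(out.haplotypes, sol.haplotypes)

    def test_requires_imputed_solution(self):
        sol = sol_from(["0?", "01"])
        with pytest.raises(ValueError, match="imputed"):
            parsimony_refine(sol)

    def test_monotone_and_every_move_verified_by_recount(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            G = random_genotype_matrix(rng, 12, 12, p_het=0.4)
            sol = phase_genotype_initial(G)
            moves = []
            out = parsimony_refine(sol, record=moves)
            assert is_compatible(out)
            # replay: recount distinct haplotypes after each accepted move
            H = sol.haplotypes.copy()
            count = len({r.tobytes() for r in H})
            for mv in moves:
                r1, r2 = H[2 * mv.individual], H[2 * mv.individual + 1]
                tail = r1[mv.site:].copy()
                r1[mv.site:] = r2[mv.site:]
                r2[mv.site:] = tail
                new_count = len({r.tobytes() for r in H})
                assert new_count == count + mv.delta
                assert new_count < count
                count = new_count
            assert count == out.distinct_haplotype_count()
            assert np.array_equal(H, out.haplotypes)
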