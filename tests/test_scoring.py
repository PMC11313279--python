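"""Elimination rules and the normalized difference score."""

import numpy as np
import pytest

from polytg.errors import DegenerateObservationError, NoMatchingGenotypeError
from polytg.model import SearchSpace, expected_pattern, parse_genotype
from polytg.scoring import (
    LENGTH_BONUS_SCALE,
    difference_score,
    is_compatible,
    rank_genotypes,
)

from conftest import observed_from_profile, profile_from_rows


def hom_profile(m=11, n=7, flank5="CCACCA", flank3="AACAGC"):
    """Noiseless homozygous tract with clean flanks, as a bare profile."""
    rows = list(flank5) + list("TG" * m + "T" * n) + list(flank3)
    return profile_from_rows(rows), len(flank5), 2 * m + n


def observed_pair(profile, start, length):
    obs_f = observed_from_profile(profile, start, length, "forward")
    obs_r = observed_from_profile(profile, start, length, "reverse")
    return obs_f, obs_r


class TestElimination:
    def test_expected_base_with_absent_signal_eliminates(self, cfg):
        profile, start, length = hom_profile(11, 7)
        obs_f, obs_r = observed_pair(profile, start, length)
        # (TG)10T9 has T where the observation shows the 11th TG's G
        g = parse_genotype("(TG)10T9/(TG)10T9")
        assert not is_compatible(obs_f, obs_r, g)

    def test_union_position_satisfied_by_either_base(self, cfg):
        profile, start, length = hom_profile(11, 7)
        obs_f, obs_r = observed_pair(profile, start, length)
        # het pattern expects {T,G} at position 22 where only T is observed
        g = parse_genotype("(TG)11T7/(TG)12T5")
        assert is_compatible(obs_f, obs_r, g)

    def test_observed_beyond_expected_never_eliminates(self, cfg):
        """Extra observed thymine past the expected pattern's end is a
        mismatch to be scored, not grounds for elimination."""
        longer, start9, _ = hom_profile(11, 9)
        obs_f = observed_from_profile(longer, start9, 31, "forward")
        exact, start7, _ = hom_profile(11, 7)
        obs_r = observed_from_profile(exact, start7, 29, "reverse")
        g = parse_genotype("(TG)11T7/(TG)11T7")
        assert is_compatible(obs_f, obs_r, g)

    def test_expected_beyond_observed_window_checks_the_profile(self, cfg):
        """A pattern longer than the true tract is contradicted by the
        signal-free flank just past the window."""
        profile, start, length = hom_profile(11, 7)
        obs_f, obs_r = observed_pair(profile, start, length)
        longer = parse_genotype("(TG)11T8/(TG)11T8")
        assert not is_compatible(obs_f, obs_r, longer)


class TestDifferenceScore:
    def test_perfect_match_closed_form(self):
        profile, start, length = hom_profile(11, 7)  # L = 29
        obs_f, obs_r = observed_pair(profile, start, length)
        g = parse_genotype("(TG)11T7/(TG)11T7")
        d = difference_score(obs_f, obs_r, expected_pattern(g, "forward"),
                             expected_pattern(g, "reverse"))
        assert d == pytest.approx((100 - 58) / LENGTH_BONUS_SCALE, abs=1e-15)

    def test_longer_expected_pattern_gets_smaller_offset_term(self):
        """Scoring the same 29-long observation against a 31-long pattern:
        offset term drops to (100-62)/1e5 while the het pattern's junction
        mismatch adds 0.5 to the numerator."""
        profile, start, length = hom_profile(11, 7)
        obs_f, obs_r = observed_pair(profile, start, length)
        g = parse_genotype("(TG)11T7/(TG)11T9")
        d = difference_score(obs_f, obs_r, expected_pattern(g, "forward"),
                             expected_pattern(g, "reverse"))
        assert d == pytest.approx(0.5 / (2 * 58) + (100 - 62) / LENGTH_BONUS_SCALE, abs=1e-12)

    def test_unexpected_peak_beyond_expected_length_penalized(self):
        """One observed pure-T position past the expected pattern adds a
        full unit to the numerator (E = 0 there)."""
        profile, start, _ = hom_profile(11, 8)  # observation runs one T longer
        obs_f = observed_from_profile(profile, start, 30, "forward")
        obs_r = observed_from_profile(profile, start, 29, "reverse")
        g = parse_genotype("(TG)11T7/(TG)11T7")
        d = difference_score(obs_f, obs_r, expected_pattern(g, "forward"),
                             expected_pattern(g, "reverse"))
        # forward: unexpected pure T at position 29 contributes exactly 1.0;
        # the 29-long reverse window right-aligns onto the pattern exactly
        expected = 1.0 / (2 * (30 + 29)) + (100 - 58) / LENGTH_BONUS_SCALE
        assert d == pytest.approx(expected, abs=1e-12)

    def test_uninformative_positions_kept_in_denominator(self):
        profile, start, length = hom_profile(11, 7)
        profile.informative[start + 5] = False
        profile.rel[start + 5] = 0.0
        obs_f, obs_r = observed_pair(profile, start, length)
        g = parse_genotype("(TG)11T7/(TG)11T7")
        d = difference_score(obs_f, obs_r, expected_pattern(g, "forward"),
                             expected_pattern(g, "reverse"))
        # masked position contributes nothing, nF/nR still 29 each
        assert d == pytest.approx((100 - 58) / LENGTH_BONUS_SCALE, abs=1e-15)

    def test_empty_windows_degenerate(self):
        profile, start, _ = hom_profile(11, 7)
        obs_f = observed_from_profile(profile, start, 0, "forward")
        obs_r = observed_from_profile(profile, start, 0, "reverse")
        g = parse_genotype("(TG)11T7/(TG)11T7")
        with pytest.raises(DegenerateObservationError):
            difference_score(obs_f, obs_r, expected_pattern(g, "forward"),
                             expected_pattern(g, "reverse"))

    def test_monotonicity_injected_error_never_decreases_d(self):
        profile, start, length = hom_profile(11, 7)
        obs_f, obs_r = observed_pair(profile, start, length)
        g = parse_genotype("(TG)11T7/(TG)11T7")
        exp_f, exp_r = expected_pattern(g, "forward"), expected_pattern(g, "reverse")
        base = difference_score(obs_f, obs_r, exp_f, exp_r)
        rng = np.random.default_rng(1)
        for _ in range(20):
            i = int(rng.integers(0, length))
            bumped_f = observed_from_profile(profile, start, length, "forward")
            # push the observed point one unit of squared error away
            bumped_f.ot[i] = 1.0 - bumped_f.ot[i]
            d = difference_score(bumped_f, obs_r, exp_f, exp_r)
            assert d >= base


class TestRanking:
    def test_ranks_are_contiguous_and_sorted(self, pipeline):
        tract_f, tract_r, _, _ = pipeline("(TG)12T5/(TG)11T9")
        scores = rank_genotypes(tract_f, tract_r)
        survivors = [s for s in scores if not s.eliminated]
        assert [s.rank for s in survivors] == list(range(1, len(survivors) + 1))
        ds = [s.d for s in survivors]
        assert ds == sorted(ds)
        assert all(s.d is None and s.rank is None for s in scores if s.eliminated)

    def test_vectorized_engine_matches_scalar_reference(self, pipeline):
        """Internal consistency: the numpy ranking engine must agree with
        the scalar is_compatible/difference_score path."""
        tract_f, tract_r, _, _ = pipeline("(TG)12T5/(TG)11T9", noise_sd=35.0, seed=9)
        space = SearchSpace(min_t=5, max_t=9, min_tg=10, max_tg=13)
        scores = rank_genotypes(tract_f, tract_r, space)
        for s in scores:
            pats = (expected_pattern(s.genotype, "forward"),
                    expected_pattern(s.genotype, "reverse"))
            assert is_compatible(tract_f, tract_r, s.genotype, pats) != s.eliminated
            if not s.eliminated:
                assert s.d == pytest.approx(
                    difference_score(tract_f, tract_r, *pats), abs=1e-12
                )

    def test_all_eliminated_raises(self, pipeline):
        tract_f, tract_r, _, _ = pipeline("(TG)11T7/(TG)11T7")
        space = SearchSpace(min_t=3, max_t=3, min_tg=8, max_tg=8)
        with pytest.raises(NoMatchingGenotypeError):
            rank_genotypes(tract_f, tract_r, space)

    def test_rank_one_recovers_simulated_truth(self, pipeline):
        for label in ("(TG)11T7/(TG)11T7", "(TG)12T5/(TG)11T9", "(TG)13T5/(TG)10T9"):
            tract_f, tract_r, _, _ = pipeline(label)
            scores = rank_genotypes(tract_f, tract_r)
            assert scores[0].genotype == parse_genotype(label)
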