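import itertools
import math

import numpy as np
import pytest

from crackle.detect import DeletionSite
from crackle.motif import (
    ALPHABET,
    BindingSite,
    SeedPWM,
    affinity_weights,
    build_seed_pwm,
    enumerate_null_scores,
    extract_windows,
    high_confidence_filter,
    null_threshold,
    null_threshold_sampled,
    score_window,
    score_windows,
    weighted_logo,
)
from crackle.simulate import default_planted_pwm


def dsite(pos, contig="chr1", strand="+", del_by_rep=(2, 1), cov_by_rep=(4, 4)):
    return DeletionSite(
        contig=contig, pos=pos, strand=strand,
        del_by_rep=del_by_rep, cov_by_rep=cov_by_rep,
        del_total=float(sum(del_by_rep)), cov_total=sum(cov_by_rep),
    )


def bsite(score=1.0, del_by_rep=(2, 1), cov_by_rep=(3, 3), seq="CUUUCUU",
          affinity=None, intensity=None):
    del_total = float(sum(del_by_rep))
    return BindingSite(
        contig="chr1", pos=10, strand="+", window_seq=seq, score=score,
        intensity=del_total if intensity is None else intensity,
        del_by_rep=del_by_rep, cov_by_rep=cov_by_rep,
        del_total=del_total, cov_total=sum(cov_by_rep), affinity=affinity,
    )


def uniform_pwm():
    return SeedPWM(freq=np.full((4, 7), 0.25), background=np.full(4, 0.25),
                   pseudocount=0.0, n_seed=1)


class TestExtractWindows:
    #            0123456789012345
    GENOME = {"chr1": "AAAACTTTCCAAAAAA"}

    def test_plus_strand_window(self):
        kept, windows = extract_windows([dsite(7)], self.GENOME)
        assert windows == ["CTTTCCA".replace("T", "U")]
        assert kept[0].pos == 7

    def test_minus_strand_reverse_complement(self):
        _, windows = extract_windows([dsite(7, strand="-")], self.GENOME)
        assert windows == ["UGGAAAG"]

    def test_underflow_dropped(self):
        kept, windows = extract_windows([dsite(1)], self.GENOME)
        assert kept == [] and windows == []

    def test_overflow_dropped(self):
        kept, _ = extract_windows([dsite(14)], self.GENOME)
        assert kept == []

    def test_missing_contig_is_hard_error(self):
        with pytest.raises(KeyError):
            extract_windows([dsite(10, contig="chrX")], self.GENOME)

    def test_t_transliterated_to_u(self):
        _, windows = extract_windows([dsite(3, contig="c")], {"c": "TTTTTTTT"})
        assert windows == ["UUUUUUU"]


class TestBuildSeedPwm:
    def test_pseudocount_frequency(self):
        pwm = build_seed_pwm(["CUUUAAA", "CUUUCCC", "CUUUGGG"], pseudocount=1.0)
        assert pwm.freq[ALPHABET.index("C"), 0] == pytest.approx(4 / 7)
        assert pwm.n_seed == 3

    def test_columns_sum_to_one(self):
        pwm = build_seed_pwm(["CUUUAAA", "GGGGGGG"], pseudocount=0.7)
        assert np.allclose(pwm.freq.sum(axis=0), 1.0, atol=1e-9)

    def test_single_window_zero_pseudocount_indicator(self):
        pwm = build_seed_pwm(["CUUUAAA"], pseudocount=0.0)
        assert pwm.freq[ALPHABET.index("C"), 0] == 1.0
        assert pwm.freq[:, 0].sum() == 1.0

    def test_identical_windows_consensus_is_max(self):
        pwm = build_seed_pwm(["CUUUAAA"] * 5, pseudocount=0.0)
        consensus = score_window(pwm, "CUUUAAA")
        others = [score_window(pwm, "".join(h))
                  for h in itertools.islice(itertools.product(ALPHABET, repeat=7), 200)]
        assert consensus >= max(others)

    def test_empty_input_is_hard_error(self):
        with pytest.raises(ValueError):
            build_seed_pwm([])

    def test_n_windows_excluded(self):
        pwm = build_seed_pwm(["CUUUAAA", "CUUNAAA"], pseudocount=0.0)
        assert pwm.n_seed == 1


class TestScoreWindow:
    def test_uniform_pwm_scores_zero(self):
        pwm = uniform_pwm()
        assert score_window(pwm, "ACGUACG") == pytest.approx(0.0)
        assert score_window(pwm, "UUUUUUU") == pytest.approx(0.0)

    def test_single_window_match(self):
        pwm = build_seed_pwm(["CUUUUUU"], pseudocount=1.0)
        assert score_window(pwm, "CUUUUUU") == pytest.approx(7 * math.log2(0.4 / 0.25), abs=1e-3)

    def test_single_window_mismatch(self):
        pwm = build_seed_pwm(["CUUUUUU"], pseudocount=1.0)
        assert score_window(pwm, "AAAAAAA") == pytest.approx(7 * math.log2(0.2 / 0.25), abs=1e-3)

    def test_bad_length_is_hard_error(self):
        with pytest.raises(ValueError):
            score_window(uniform_pwm(), "ACGU")

    def test_n_is_hard_error(self):
        with pytest.raises(ValueError):
            score_window(uniform_pwm(), "ACGUNCA")

    def test_matches_brute_force_lookup_on_all_heptamers(self):
        pwm = build_seed_pwm(["CUUUCUU", "CUUUAAA", "GUUUCUU"], pseudocount=1.0)
        scores = score_windows(
            pwm, ["".join(h) for h in itertools.product(ALPHABET, repeat=7)]
        )
        for i, heptamer in enumerate(itertools.product(ALPHABET, repeat=7)):
            expected = sum(
                pwm.logodds[ALPHABET.index(base), j] for j, base in enumerate(heptamer)
            )
            assert scores[i] == pytest.approx(expected, abs=1e-12)


class TestNullThreshold:
    def test_uniform_pwm_threshold_zero(self):
        assert null_threshold(uniform_pwm()) == pytest.approx(0.0)

    def test_threshold_within_score_range(self, rng):
        freq = rng.dirichlet(np.ones(4), size=7).T
        pwm = SeedPWM(freq=freq, background=np.full(4, 0.25), pseudocount=0, n_seed=1)
        scores, _ = enumerate_null_scores(pwm)
        tau = null_threshold(pwm)
        assert scores.min() <= tau <= scores.max()

    def test_peaked_pwm_at_most_five_percent_above(self):
        pwm = build_seed_pwm(["CUUUCUU"] * 100, pseudocount=0.5)
        tau = null_threshold(pwm)
        scores, _ = enumerate_null_scores(pwm)
        assert (scores > tau).mean() <= 0.05

    def test_matches_nearest_rank_oracle(self):
        pwm = build_seed_pwm(["CUUUCUU", "AUUUGUU"], pseudocount=1.0)
        scores, _ = enumerate_null_scores(pwm)
        ordered = sorted(scores.tolist())
        rank = math.ceil(0.95 * len(ordered)) - 1
        assert null_threshold(pwm) == ordered[rank]

    def test_deterministic_across_runs(self):
        pwm = build_seed_pwm(["CUUUCUU", "AUUUGUU", "CUAUCUU"], pseudocount=1.0)
        assert null_threshold(pwm) == null_threshold(pwm)

    def test_sampled_mode_close_to_exhaustive(self):
        pwm = build_seed_pwm(["CUUUCUU"] * 20, pseudocount=1.0)
        exact = null_threshold(pwm)
        sampled = null_threshold_sampled(pwm, n=200_000, seed=3)
        assert sampled == pytest.approx(exact, abs=0.3)


class TestHighConfidenceFilter:
    def test_boundary_passing_site(self):
        [s] = high_confidence_filter([bsite(score=1.0)], threshold=0.5)
        assert s.passes_filters

    def test_replicate_without_deletion_fails(self):
        [s] = high_confidence_filter(
            [bsite(score=1.0, del_by_rep=(3, 0), cov_by_rep=(4, 4))], threshold=0.5
        )
        assert not s.passes_filters

    def test_score_at_threshold_fails(self):
        [s] = high_confidence_filter([bsite(score=0.5)], threshold=0.5)
        assert not s.passes_filters

    def test_low_total_coverage_fails(self):
        [s] = high_confidence_filter(
            [bsite(score=1.0, cov_by_rep=(3, 2))], threshold=0.5
        )
        assert not s.passes_filters

    def test_monotone_in_counts(self, rng):
        for _ in range(200):
            d = tuple(int(v) for v in rng.integers(0, 5, 2))
            c = tuple(int(v) for v in rng.integers(0, 7, 2))
            [base] = high_confidence_filter([bsite(score=1.0, del_by_rep=d, cov_by_rep=c)], 0.5)
            bigger_d = tuple(v + int(rng.integers(0, 3)) for v in d)
            bigger_c = tuple(v + int(rng.integers(0, 3)) for v in c)
            [more] = high_confidence_filter(
                [bsite(score=1.0, del_by_rep=bigger_d, cov_by_rep=bigger_c)], 0.5
            )
            if base.passes_filters:
                assert more.passes_filters


class TestAffinityWeights:
    def test_plain_division(self):
        s = bsite(intensity=12.0)
        s.transcript_id = "t1"
        [out] = affinity_weights([s], {"t1": 4.0})
        assert out.affinity == pytest.approx(3.0)

    def test_floor_applied(self):
        s = bsite(intensity=5.0)
        s.transcript_id = "t1"
        [out] = affinity_weights([s], {"t1": 0.0}, floor=0.1)
        assert out.affinity == pytest.approx(50.0)

    def test_missing_transcript_undefined(self):
        s = bsite()
        s.transcript_id = "absent"
        [out] = affinity_weights([s], {"t1": 4.0})
        assert out.affinity is None


class TestWeightedLogo:
    def test_hand_weighted_example(self):
        sites = [
            bsite(seq="AUUUUUU", affinity=1.0),
            bsite(seq="CUUUUUU", affinity=3.0),
        ]
        logo = weighted_logo(sites)
        assert logo[ALPHABET.index("C"), 0] == pytest.approx(0.75)
        assert logo[ALPHABET.index("A"), 0] == pytest.approx(0.25)
        assert logo[ALPHABET.index("U"), 1:].max() == pytest.approx(1.0)

    def test_single_site_indicator(self):
        logo = weighted_logo([bsite(seq="CUUUCUU", affinity=2.0)])
        for j, base in enumerate("CUUUCUU"):
            assert logo[ALPHABET.index(base), j] == pytest.approx(1.0)

    def test_scale_invariance(self):
        one = weighted_logo([bsite(seq="CUUUCUU", affinity=1.0)])
        two = weighted_logo([bsite(seq="CUUUCUU", affinity=5.0)] * 2)
        assert np.allclose(one, two)

    def test_empty_is_hard_error(self):
        with pytest.raises(ValueError):
            weighted_logo([bsite(affinity=None)])


def test_planted_pwm_recovery(rng):
    from crackle.simulate import _draw_heptamer

    planted = default_planted_pwm()
    windows = [_draw_heptamer(planted, rng) for _ in range(600)]
    pwm = build_seed_pwm(windows, pseudocount=1.0)
    tv = 0.5 * np.abs(pwm.freq - planted).sum(axis=0)
    assert tv.max() < 0.05
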