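"""Entropy weighting, profile construction, search scorer, E-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatcal import (
    PriorModel,
    build_profile,
    column_posterior,
    fit_evalue_model,
    fit_exponential_scale,
    fit_uniform_scale,
    relative_entropy,
    search,
    simulate_seed_alignment,
)
from repeatcal.profilecore import (
    _scaled_counts,
    average_relative_entropy,
    estimate_evalue,
)

UNIFORM = np.full(4, 0.25)
PRIOR = PriorModel()


def grid_search_scale(counts, prior, background, target, mode, step=1e-5):
    """Independent oracle: dense grid over the scale parameter."""
    grid = np.arange(0.0, 1.0 + step, step)
    vals = np.array([
        average_relative_entropy(counts, prior, background, s, mode)
        for s in grid
    ])
    return float(grid[np.argmin(np.abs(vals - target))])


class TestRelativeEntropy:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ([.25, .25, .25, .25], [.25, .25, .25, .25], 0.0),
            ([1, 0, 0, 0], [.25, .25, .25, .25], 2.0),
            ([.5, .5, 0, 0], [.25, .25, .25, .25], 1.0),
            ([.5, .25, .125, .125], [.25, .25, .25, .25],
             0.5 * 1 + 0.25 * 0 + 2 * 0.125 * -1),  # direct evaluation
        ],
    )
    def test_known_values(self, p, q, expected):
        assert relative_entropy(p, q) == pytest.approx(expected, abs=1e-12)

    def test_zero_background_component_rejected(self):
        with pytest.raises(ValueError):
            relative_entropy([1, 0, 0, 0], [0.5, 0.5, 0, 0])

    @given(st.lists(st.floats(0.01, 10), min_size=4, max_size=4))
    @settings(deadline=None, derandomize=True)
    def test_nonnegative_and_zero_iff_equal(self, raw):
        p = np.array(raw) / np.sum(raw)
        assert relative_entropy(p, UNIFORM) >= 0
        assert relative_entropy(p, p) == pytest.approx(0, abs=1e-12)


class TestColumnPosterior:
    def test_prior_only_limit(self):
        assert np.allclose(column_posterior([0, 0, 0, 0], PRIOR), UNIFORM)

    def test_data_dominated_limit(self):
        post = column_posterior([1e6, 0, 0, 0], PRIOR)
        assert post[0] > 0.999

    def test_hand_arithmetic(self):
        assert np.allclose(column_posterior([3, 1, 0, 0], PRIOR),
                           [4 / 8, 2 / 8, 1 / 8, 1 / 8])

    def test_scaling_counts_moves_toward_empirical(self):
        p1 = column_posterior([3, 1, 0, 0], PRIOR)
        p2 = column_posterior([30, 10, 0, 0], PRIOR)
        assert p2[0] > p1[0]  # monotone toward 0.75


class TestEntropyWeighting:
    def toy_counts(self):
        # three columns of different depths and compositions
        return np.array([
            [40.0, 2.0, 1.0, 1.0],
            [3.0, 3.0, 2.0, 2.0],
            [0.0, 300.0, 0.0, 0.0],
        ])

    def test_exponential_matches_grid_search(self):
        counts = self.toy_counts()
        s = fit_exponential_scale(counts, PRIOR, UNIFORM, 0.62)
        s_grid = grid_search_scale(counts, PRIOR, UNIFORM, 0.62, "exponential")
        assert abs(s - s_grid) <= 2e-5

    def test_uniform_matches_grid_search(self):
        counts = self.toy_counts()
        m = fit_uniform_scale(counts, PRIOR, UNIFORM, 0.62)
        m_grid = grid_search_scale(counts, PRIOR, UNIFORM, 0.62, "uniform")
        assert abs(m - m_grid) <= 2e-5

    def test_target_at_unweighted_re_gives_scale_one(self):
        counts = self.toy_counts()
        unweighted = average_relative_entropy(counts, PRIOR, UNIFORM, 1.0,
                                              "exponential")
        assert fit_exponential_scale(counts, PRIOR, UNIFORM, unweighted) == 1.0
        assert fit_uniform_scale(counts, PRIOR, UNIFORM, unweighted) == 1.0

    def test_uninformative_counts_need_no_weighting(self):
        # a uniform column sits below any positive target at s=1 already
        counts = np.array([[5.0, 5.0, 5.0, 5.0]])
        assert fit_exponential_scale(counts, PRIOR, UNIFORM, 0.62) == 1.0

    def test_target_below_floor_warns_and_returns_zero(self):
        # even at s=0 (scaled total 1) a pure column keeps RE ~ 0.078 bits;
        # a target below that floor cannot be reached
        counts = np.array([[1e6, 0.0, 0.0, 0.0]])
        floor = average_relative_entropy(counts, PRIOR, UNIFORM, 0.0,
                                         "exponential")
        with pytest.warns(UserWarning):
            s = fit_exponential_scale(counts, PRIOR, UNIFORM, floor / 2)
        assert s == 0.0

    def test_single_observation_column_invariant_under_s(self):
        col = np.array([[1.0, 0.0, 0.0, 0.0]])
        for s in (0.0, 0.3, 0.7, 1.0):
            assert _scaled_counts(col, s, "exponential").sum() == pytest.approx(1.0)

    def test_scaled_totals_between_one_and_k(self):
        counts = self.toy_counts()
        for s in (0.0, 0.25, 0.5, 0.75, 1.0):
            totals = _scaled_counts(counts, s, "exponential").sum(axis=1)
            k = counts.sum(axis=1)
            assert np.all(totals >= 1 - 1e-9)
            assert np.all(totals <= k + 1e-9)

    def test_avg_re_monotone_in_s(self):
        """Continuity/monotonicity basis for the bisection, checked
        numerically on random alignments."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            counts = rng.integers(0, 60, size=(20, 4)).astype(float)
            counts[counts.sum(axis=1) == 0, 0] = 1
            grid = np.linspace(0, 1, 41)
            vals = [average_relative_entropy(counts, PRIOR, UNIFORM, s,
                                             "exponential") for s in grid]
            assert np.all(np.diff(vals) >= -1e-9)

    def test_rank_order_of_effective_counts_preserved(self):
        counts = self.toy_counts()
        k = counts.sum(axis=1)
        for s in (0.2, 0.5, 0.8):
            scaled = _scaled_counts(counts, s, "exponential").sum(axis=1)
            assert np.all(np.argsort(scaled) == np.argsort(k))

    def test_uniform_depth_seeds_make_weighting_schemes_agree(self):
        """With equal column depth k, k^s and m*k can hit the same target,
        giving identical profiles at the fitted scales (within 1e-6)."""
        seed = simulate_seed_alignment(length=60, depth=50, identity=0.8,
                                       rng_seed=3)
        p_exp = build_profile(seed, weighting="exponential")
        p_uni = build_profile(seed, weighting="uniform")
        assert p_exp.avg_re == pytest.approx(p_uni.avg_re, abs=1e-3)
        assert np.allclose(p_exp.emissions, p_uni.emissions, atol=1e-6)

    def test_exponential_protects_shallow_columns(self):
        """At equal average RE, exponential weighting leaves a k=10 column
        with more effective observations than uniform weighting does."""
        counts = np.zeros((20, 4))
        counts[:10, 0] = 1000.0  # deep region
        counts[10:, 1] = 10.0    # shallow region
        target = 0.62
        s = fit_exponential_scale(counts, PRIOR, UNIFORM, target)
        m = fit_uniform_scale(counts, PRIOR, UNIFORM, target)
        re_exp = average_relative_entropy(counts, PRIOR, UNIFORM, s, "exponential")
        re_uni = average_relative_entropy(counts, PRIOR, UNIFORM, m, "uniform")
        assert re_exp == pytest.approx(re_uni, abs=5e-4)
        shallow_exp = 10.0 ** s
        shallow_uni = 10.0 * m
        assert shallow_exp > shallow_uni


class TestBuildProfile:
    def test_conserved_deep_alignment_reaches_default_target(self):
        seed = simulate_seed_alignment(length=100, depth=100, identity=1.0,
                                       rng_seed=5)
        prof = build_profile(seed)
        assert prof.avg_re == pytest.approx(0.62, abs=1e-3)

    def test_deep_diverged_alignment_reaches_default_target(self, deep_seed):
        prof = build_profile(deep_seed)
        assert prof.avg_re == pytest.approx(0.62, abs=1e-3)
        assert 0 <= prof.scale <= 1

    def test_single_sequence_prior_dominated(self):
        seed = simulate_seed_alignment(length=50, depth=1, identity=1.0,
                                       rng_seed=6)
        prof = build_profile(seed)
        assert prof.avg_re < 2.0

    def test_shallow_seed_below_target_unweighted(self):
        seed = simulate_seed_alignment(length=50, depth=1, identity=1.0,
                                       rng_seed=6)
        unweighted = build_profile(seed, weighting="none")
        prof = build_profile(seed)
        if unweighted.avg_re <= 0.62:
            assert prof.scale == 1.0
            assert prof.avg_re == pytest.approx(unweighted.avg_re, abs=1e-9)

    def test_all_gap_column_dropped_with_warning(self, deep_seed):
        members = [m[:10] + "-" + m[11:] for m in deep_seed.members]
        counts = deep_seed.column_counts.copy()
        counts[10] = 0
        seed = type(deep_seed)(
            family_id="gapfam", consensus=deep_seed.consensus,
            members=members, member_ids=deep_seed.member_ids,
            rf=deep_seed.rf, column_counts=counts,
        )
        with pytest.warns(UserWarning, match="dropped"):
            prof = build_profile(seed)
        assert prof.length == len(deep_seed.consensus) - 1

    def test_empty_seed_errors(self, deep_seed):
        empty = type(deep_seed)(
            family_id="e", consensus=deep_seed.consensus, members=[],
            member_ids=[], rf=deep_seed.rf,
            column_counts=np.zeros(len(deep_seed.consensus), dtype=int),
        )
        with pytest.raises(ValueError):
            build_profile(empty)


@pytest.fixture(scope="module")
def profile(deep_seed):
    return build_profile(deep_seed)


@pytest.fixture(scope="module")
def null_scores():
    return np.random.default_rng(8).gumbel(loc=18.0, scale=2.5, size=3000)


class TestSearch:
    def test_consensus_scores_analytic_maximum(self, profile):
        hits = search(profile, profile.consensus, strand_both=False)
        assert len(hits) == 1
        h = hits[0]
        assert (h.ali_from, h.ali_to) == (1, profile.length)
        assert h.score == pytest.approx(profile.max_score(), abs=1e-9)

    def test_background_sequence_no_hits_at_high_threshold(self, profile):
        rng = np.random.default_rng(1)
        bg = "".join(rng.choice(list("ACGT"), size=20000))
        assert search(profile, bg, min_score=60.0) == []

    def test_short_sequence_empty(self, profile):
        assert search(profile, "ACGTACGT") == []

    def test_planted_fragment_envelope(self, profile):
        """A planted half-length, lightly diverged fragment is recovered
        with its envelope within +/-5 bp of the planted truth."""
        rng = np.random.default_rng(2)
        frag = profile.consensus[75:225]  # 150 bp of the 300 bp model
        codes = list(frag)
        for i in range(len(codes)):
            if rng.random() < 0.05:
                codes[i] = "ACGT"[rng.integers(4)]
        left = "".join(rng.choice(list("ACGT"), size=3000))
        right = "".join(rng.choice(list("ACGT"), size=3000))
        seq = left + "".join(codes) + right
        hits = search(profile, seq, min_score=30.0)
        assert hits, "planted fragment not recovered"
        best = max(hits, key=lambda h: h.score)
        assert abs(best.ali_from - 3001) <= 5
        assert abs(best.ali_to - (3000 + len(frag))) <= 5

    def test_reverse_strand_recovery(self, profile):
        from repeatcal.profilecore import revcomp
        rng = np.random.default_rng(3)
        seq = ("".join(rng.choice(list("ACGT"), size=500))
               + revcomp(profile.consensus)
               + "".join(rng.choice(list("ACGT"), size=500)))
        hits = [h for h in search(profile, seq, min_score=50.0)
                if h.strand == "-"]
        assert hits
        best = max(hits, key=lambda h: h.score)
        assert best.score == pytest.approx(profile.max_score(), abs=1e-9)
        assert (best.ali_from, best.ali_to) == (501, 500 + profile.length)

    def test_deterministic_across_runs(self, profile):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=30000))
        h1 = search(profile, seq, min_score=20.0)
        h2 = search(profile, seq, min_score=20.0)
        key = lambda h: (h.model_id, h.ali_from, h.ali_to, h.strand, h.score)
        assert [key(h) for h in h1] == [key(h) for h in h2]


class TestEValues:
    def test_requires_enough_scores(self):
        with pytest.raises(ValueError):
            fit_evalue_model(np.ones(50) + np.random.default_rng(0).random(50))

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            fit_evalue_model(np.full(500, 12.0))

    def test_monotone_decreasing_in_score(self, null_scores):
        m = fit_evalue_model(null_scores, null_space=1e6)
        scores = np.linspace(10, 60, 50)
        evs = [m.evalue(s) for s in scores]
        assert np.all(np.diff(evs) <= 0)

    def test_order_statistic_sanity(self, null_scores):
        """E at the maximum null score is about 1/n (scaled).

        The scaled tail probability of a sample maximum is ~Exp(1)/n, so
        the band must be generous even before fit error."""
        m = fit_evalue_model(null_scores, null_space=1e6)
        e_max = m.evalue(null_scores.max(), search_space=1e6)
        n = len(null_scores)
        assert 1 / (30 * n) < e_max < 10 / n

    def test_tail_matches_empirical_within_twofold(self, null_scores):
        m = fit_evalue_model(null_scores, null_space=1e6)
        s99 = np.quantile(null_scores, 0.99)
        fitted = m.evalue(s99)  # tail probability at ratio 1
        empirical = (null_scores >= s99).mean()
        assert empirical / 2 <= fitted <= empirical * 2

    def test_score_at_evalue_inverts(self, null_scores):
        m = fit_evalue_model(null_scores, null_space=1e6)
        for e in (1e-4, 1e-2, 0.5):
            assert m.evalue(m.score_at_evalue(e)) == pytest.approx(e, rel=1e-6)

    def test_search_space_rescaling(self, null_scores):
        m = fit_evalue_model(null_scores, null_space=1e6)
        assert m.evalue(30.0, search_space=2e6) == pytest.approx(
            2 * m.evalue(30.0, search_space=1e6))

    def test_estimate_evalue_wrapper(self, null_scores, deep_seed):
        prof = build_profile(deep_seed)
        e = estimate_evalue(prof, null_scores, 30.0,
                            search_space=2e6, null_space=1e6)
        m = fit_evalue_model(null_scores, null_space=1e6)
        assert e == pytest.approx(m.evalue(30.0, search_space=2e6))
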