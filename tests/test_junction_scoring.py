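"""Junction-level aggregation, nulls, empirical p-values, and filters."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicecall import (
    aggregate_score,
    build_null,
    collapse_to_junctions,
    cumulative_score,
    empirical_p,
    sample_filters,
    score_junctions,
)
from splicecall.alignment_io import SpliceJunction, SplicedAlignmentRecord
from splicecall.junction_scoring import JunctionReadSet, log_odds

from conftest import random_seq


def _record(i, junction, align_start=None, seq=None, has_genomic=False):
    a = align_start or (junction.intron_start - 30)
    return SplicedAlignmentRecord(
        read_id=f"r{i}",
        sample_id="s",
        junction=junction,
        cigar=f"{junction.intron_start - a}M"
        f"{junction.intron_end - junction.intron_start + 1}N30M",
        align_start=a,
        hi=1,
        nh=1,
        nmm=0,
        as_raw=60,
        read_length=60,
        read_seq=seq or random_seq(60, seed=i),
        is_reverse=False,
        has_genomic_alignment=has_genomic,
    )


JUNC = SpliceJunction("chr1", 1000, 1200)


class TestAggregateScore:
    def test_single_read_identity(self):
        assert aggregate_score([0.7]) == pytest.approx(0.7, abs=1e-12)

    def test_all_half_symmetry(self):
        assert aggregate_score([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_two_confident_reads_worked_value(self):
        # 0.81 / (0.81 + 0.01)
        assert aggregate_score([0.9, 0.9]) == pytest.approx(0.81 / 0.82, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_score([])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1 - 1e-6), min_size=1, max_size=15)
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_ratio_form_oracle_and_permutation_invariance(self, p_hats):
        p = np.array(p_hats)
        ratio = p.prod() / (p.prod() + (1 - p).prod())
        got = aggregate_score(p)
        assert got == pytest.approx(ratio, abs=1e-9)
        assert aggregate_score(p[::-1]) == pytest.approx(got, abs=1e-12)

    def test_strictly_increasing_in_each_p_hat(self):
        base = np.array([0.3, 0.6, 0.8])
        for i in range(3):
            bumped = base.copy()
            bumped[i] += 0.05
            assert aggregate_score(bumped) > aggregate_score(base)

    def test_stable_for_extreme_scores(self):
        p = np.full(200, 1 - 1e-6)
        assert 0 < aggregate_score(p) <= 1
        p2 = np.full(200, 1e-6)
        assert 0 <= aggregate_score(p2) < 1


class TestCollapseToJunctions:
    def test_identical_coordinates_collapse(self):
        recs = [_record(0, JUNC), _record(1, JUNC)]
        (jrs,) = collapse_to_junctions(recs, [0.9, 0.8])
        assert jrs.N == 2

    def test_distinct_offsets_counted(self):
        recs = [
            _record(0, JUNC, align_start=JUNC.intron_start - 12),
            _record(1, JUNC, align_start=JUNC.intron_start - 12),
            _record(2, JUNC, align_start=JUNC.intron_start - 17),
        ]
        (jrs,) = collapse_to_junctions(recs, [0.5] * 3)
        assert jrs.n_distinct_offsets == 2

    def test_two_junction_read_feeds_both_junctions(self):
        j2 = SpliceJunction("chr1", 1400, 1600)
        rec_a = _record(0, JUNC)
        rec_b = _record(0, j2, align_start=1380)  # same read, second N
        out = collapse_to_junctions([rec_a, rec_b], [0.9, 0.9])
        assert [j.junction.key for j in out] == [JUNC.key, j2.key]
        assert all(j.N == 1 for j in out)

    def test_frac_genomic(self):
        recs = [
            _record(0, JUNC, has_genomic=True),
            _record(1, JUNC),
            _record(2, JUNC),
            _record(3, JUNC),
        ]
        (jrs,) = collapse_to_junctions(recs, [0.5] * 4)
        assert jrs.frac_genomic == pytest.approx(0.25)


class TestBuildNullAndCumulativeScore:
    def test_degenerate_pool_ties_give_half(self):
        pool = np.full(50, 0.6)
        null = build_null(pool, N=3, reps=1000, seed=0)
        assert null.kind == "empirical"
        assert np.allclose(null.null_scores, aggregate_score([0.6] * 3))
        assert cumulative_score([0.6] * 3, null) == pytest.approx(0.5)

    def test_boundary_regimes(self):
        pool = np.random.default_rng(0).uniform(0.1, 0.9, size=100)
        assert build_null(pool, N=15, seed=0).kind == "empirical"
        assert build_null(pool, N=16, seed=0).kind == "gaussian"

    def test_empirical_null_mean_matches_exhaustive_pairs(self):
        rng = np.random.default_rng(1)
        pool = rng.beta(2, 2, size=50)
        exact = np.array(
            [aggregate_score([a, b]) for a, b in itertools.product(pool, pool)]
        )
        null = build_null(pool, N=2, reps=10_000, seed=1)
        se = exact.std() / np.sqrt(null.reps)
        assert abs(null.null_scores.mean() - exact.mean()) <= 3 * se

    def test_observed_above_entire_null_scores_one(self):
        pool = np.random.default_rng(2).uniform(0.05, 0.4, size=200)
        null = build_null(pool, N=5, reps=10_000, seed=2)
        assert cumulative_score([1 - 1e-6] * 5, null) == pytest.approx(1.0)

    def test_gaussian_centered_sum_gives_half(self):
        pool = np.random.default_rng(3).beta(4, 4, size=500)
        null = build_null(pool, N=20, seed=3)
        # craft a read vector whose log-odds sum equals N * mu
        p_star = 1 / (1 + np.exp(null.mu))
        assert cumulative_score([p_star] * 20, null) == pytest.approx(0.5, abs=1e-9)

    def test_gaussian_zero_spread_sign_rule(self):
        from splicecall.junction_scoring import NullModel

        null = NullModel(kind="gaussian", N=20, mu=0.0, sigma=0.0)
        assert cumulative_score([0.9] * 20, null) == 1.0  # s < 0 = N*mu
        assert cumulative_score([0.1] * 20, null) == 0.0

    def test_single_read_pool_rejected(self):
        with pytest.raises(ValueError):
            build_null([0.5], N=2, seed=0)

    def test_empirical_p_cum_monotone_in_p(self):
        pool = np.random.default_rng(4).beta(3, 3, size=300)
        null = build_null(pool, N=4, reps=5000, seed=4)
        vals = [cumulative_score([p] * 4, null) for p in (0.2, 0.4, 0.6, 0.8)]
        assert vals == sorted(vals)

    def test_regime_agreement_across_boundary(self):
        """Empirical (N=14) and Gaussian (N=16) nulls on a smooth symmetric
        pool give close P_cum for matched observed log-odds sums."""
        pool = np.random.default_rng(5).beta(5, 5, size=2000)
        null_emp = build_null(pool, N=14, reps=10_000, seed=5)
        null_gau = build_null(pool, N=16, seed=5)
        for s_target in (-8.0, -3.0, 0.0, 3.0, 8.0):
            p14 = 1 / (1 + np.exp(s_target / 14))
            p16 = 1 / (1 + np.exp(s_target / 16))
            a = cumulative_score([p14] * 14, null_emp)
            b = cumulative_score([p16] * 16, null_gau)
            assert abs(a - b) < 0.05

    def test_null_is_seed_reproducible(self):
        pool = np.random.default_rng(6).uniform(0.1, 0.9, size=100)
        a = build_null(pool, N=5, seed=11).null_scores
        b = build_null(pool, N=5, seed=11).null_scores
        np.testing.assert_array_equal(a, b)


class TestEmpiricalP:
    def test_beats_entire_null(self):
        art = np.linspace(0.0, 0.9, 999)
        emp, fb = empirical_p(0.95, art)
        assert emp == pytest.approx(1 / 1000)
        assert fb is False

    def test_at_null_minimum_gives_one(self):
        art = np.linspace(0.1, 0.9, 9)
        emp, fb = empirical_p(0.1, art, min_artifact_null=5)
        assert emp == pytest.approx(1.0)

    def test_small_null_falls_back(self):
        emp, fb = empirical_p(0.8, np.array([0.1, 0.2]), min_artifact_null=50)
        assert fb is True
        assert emp == pytest.approx(0.2)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_and_positive(self, x, y):
        art = np.linspace(0, 1, 200)
        lo, hi = sorted((x, y))
        p_lo, _ = empirical_p(lo, art)
        p_hi, _ = empirical_p(hi, art)
        assert 0 < p_hi <= p_lo <= 1


class TestSampleFilters:
    def _jrs(self, **overrides):
        defaults = dict(
            junction=JUNC,
            sample_id="s",
            reads=[(None, 0.5)] * 3,
            frac_genomic=0.0,
            n_distinct_offsets=3,
            mean_longest_run=4.0,
            mean_entropy=4.0,
        )
        defaults.update(overrides)
        return JunctionReadSet(**defaults)

    def test_all_pass(self):
        assert all(sample_filters(self._jrs()).values())

    def test_homopolymer_threshold(self):
        assert not sample_filters(self._jrs(mean_longest_run=12.0))["homopolymer"]
        assert not sample_filters(self._jrs(mean_longest_run=11.0))["homopolymer"]
        assert sample_filters(self._jrs(mean_longest_run=10.9))["homopolymer"]

    def test_entropy_threshold(self):
        assert not sample_filters(self._jrs(mean_entropy=2.5))["entropy"]
        assert not sample_filters(self._jrs(mean_entropy=3.0))["entropy"]

    def test_offset_diversity_requires_two_offsets(self):
        assert not sample_filters(self._jrs(n_distinct_offsets=1))["offset_diversity"]

    def test_genomic_fraction_boundary(self):
        assert not sample_filters(self._jrs(frac_genomic=0.1))["genomic_fraction"]
        assert sample_filters(self._jrs(frac_genomic=0.09))["genomic_fraction"]

    def test_singleton_junction_ineligible(self):
        j2 = SpliceJunction("chr1", 3000, 3500)
        recs = [_record(0, JUNC), _record(1, j2)]
        scores = score_junctions(recs, [0.9, 0.8], min_artifact_null=0)
        # a lone read cannot show offset diversity
        for s in scores:
            assert s.filters_passed["offset_diversity"] is False
            assert s.eligible_for_median is False


class TestScoreJunctions:
    def test_every_junction_scored_with_emp_p(self):
        rng = np.random.default_rng(0)
        junctions = [
            SpliceJunction("chr1", 1000 + 500 * i, 1300 + 500 * i) for i in range(30)
        ]
        recs, p_hats = [], []
        for i, j in enumerate(junctions):
            genomic = i < 15  # half the junctions look artifactual
            for k in range(3):
                recs.append(
                    _record(
                        i * 10 + k,
                        j,
                        align_start=j.intron_start - 20 - k,
                        has_genomic=genomic,
                    )
                )
                p_hats.append(rng.uniform(0.2, 0.9))
        scores = score_junctions(recs, p_hats, min_artifact_null=5, seed=0)
        assert len(scores) == 30
        assert all(0 < s.emp_p <= 1 for s in scores)
        assert all(not s.fallback_flag for s in scores)
        assert {s.null_kind for s in scores} == {"empirical"}

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        recs = [
            _record(i, SpliceJunction("chr1", 1000 + 100 * (i // 4), 2000 + 100 * (i // 4)),
                    align_start=1000 + 100 * (i // 4) - 15 - i % 4,
                    has_genomic=(i % 5 == 0))
            for i in range(60)
        ]
        p = rng.uniform(0.1, 0.9, size=60)
        a = score_junctions(recs, p, min_artifact_null=2, seed=9)
        b = score_junctions(recs, p, min_artifact_null=2, seed=9)
        assert [(s.P, s.P_cum, s.emp_p) for s in a] == [
            (s.P, s.P_cum, s.emp_p) for s in b
        ]
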