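import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hsscreen.cassette import ValidationError
from hsscreen.scoring import (
    CompoundScore,
    adventitious_median_probability,
    aggregate_scores,
    chi,
    classify_druglikeness,
    compute_touchstones,
    gamma_distribution,
    gamma_from_values,
    interval_probability,
    phi,
    score_compound,
)
from hsscreen.survival import STANDARD_CELLS

from conftest import CONCS, TEMPS, make_pair, make_surface

bit = st.integers(min_value=0, max_value=1)
phi_matrix = st.lists(bit, min_size=6, max_size=6)
chi_bits = st.lists(bit, min_size=5, max_size=5)


def build_score(phi6, chi5):
    return aggregate_scores(
        dict(zip(STANDARD_CELLS, phi6)),
        chi_dc=dict(zip(TEMPS, chi5[:2])),
        chi_dt=dict(zip(CONCS, chi5[2:])),
    )


class TestTouchstones:
    def test_odd_count_median_is_middle_order_statistic(self):
        pool = [make_pair(f"r{i}", [v] * 6) for i, v in enumerate([0.8, 1.0, 1.2])]
        touch = compute_touchstones(pool)
        assert all(m == pytest.approx(1.0) for m in touch.sn_median.values())

    def test_even_count_median_averages_middle_pair(self):
        pool = [make_pair(f"r{i}", [v] * 6) for i, v in enumerate([1, 2, 3, 4])]
        touch = compute_touchstones(pool)
        assert all(m == pytest.approx(2.5) for m in touch.sn_median.values())

    def test_35_values_median_is_18th_order_statistic(self):
        rng = np.random.default_rng(7)
        values = rng.permutation(35) * 0.1 + 0.1  # distinct
        pool = [make_pair(f"r{i}", [v] * 6) for i, v in enumerate(values)]
        touch = compute_touchstones(pool)
        oracle = sorted(values)[17]  # brute-force sort, 18th order statistic
        assert all(m == pytest.approx(oracle) for m in touch.sn_median.values())

    def test_too_few_references_rejected(self):
        with pytest.raises(ValidationError, match="at least 3"):
            compute_touchstones([make_pair("r0", [1.0] * 6)])

    def test_empty_cell_named_in_error(self):
        from hsscreen.survival import derivative_set

        surfaces = [make_surface(f"r{i}", {(1e-6, 38.0): 1.0}) for i in range(3)]
        pool = [(s, derivative_set(s)) for s in surfaces]
        with pytest.raises(ValidationError, match="no reference values"):
            compute_touchstones(pool)


class TestBinaryFunctions:
    def test_phi_tie_scores_one(self):
        assert phi(0.90, 0.90) == 1
        assert phi(0.89, 0.90) == 0
        assert phi(1.20, 0.90) == 1

    def test_chi_tie_scores_zero(self):
        assert chi(1.0, 1.0) == 0
        assert chi(1.0 + 1e-9, 1.0) == 1
        assert chi(1.0 - 1e-9, 1.0) == 0


class TestAggregates:
    @pytest.mark.parametrize("triple,expected", [((0, 0, 1), 1), ((1, 1, 0), 2)])
    def test_worked_crossing_counts(self, triple, expected):
        score = build_score(
            [triple[0], 0, triple[1], 0, triple[2], 0], [0] * 5
        )
        # bits were laid out so that the 38 C cells carry the triple
        assert score.phi_sum_T(38.0) == expected

    def test_full_score_ranges(self):
        score = build_score([1] * 6, [1] * 5)
        assert score.psi_survival == 6
        assert score.psi_derivative == 5
        zero = build_score([0] * 6, [0] * 5)
        assert zero.psi_survival == 0
        assert zero.psi_derivative == 0

    @given(phi6=phi_matrix, chi5=chi_bits)
    def test_crossing_count_identities(self, phi6, chi5):
        score = build_score(phi6, chi5)
        assert score.psi_survival == sum(score.phi_sum_T(t) for t in TEMPS)
        assert score.psi_survival == sum(score.theta_sum_C(c) for c in CONCS)
        assert score.psi_derivative == score.phi_dT + score.theta_dC

    def test_exhaustive_triple_enumeration(self):
        triples = set(itertools.product((0, 1), repeat=3))
        assert len(triples) == 8
        phis = {sum(t) for t in triples}
        assert phis == {0, 1, 2, 3}
        pairs = set(itertools.product((0, 1), repeat=2))
        assert len(pairs) == 4
        assert {sum(p) for p in pairs} == {0, 1, 2}

    def test_incomplete_bits_flag_non_classifiable(self):
        score = CompoundScore("c", phi_bits={STANDARD_CELLS[0]: 1})
        assert score.psi_survival is None
        call = classify_druglikeness(score)
        assert call.survival_interval is None
        assert call.simultaneous_high is None


class TestDruglikeness:
    @pytest.mark.parametrize(
        "psi_s,psi_d,expected",
        [
            (5, 1, ("high", "high", True)),
            (3, 1, ("low", "high", False)),
            (4, 3, ("high", "low", False)),
            (6, 0, ("high", "high", True)),
            (0, 5, ("low", "low", False)),
        ],
    )
    def test_interval_boundaries(self, psi_s, psi_d, expected):
        phi6 = [1] * psi_s + [0] * (6 - psi_s)
        chi5 = [1] * psi_d + [0] * (5 - psi_d)
        call = classify_druglikeness(build_score(phi6, chi5))
        assert (call.survival_interval, call.derivative_interval, call.simultaneous_high) == expected


class TestGamma:
    def test_binary_split(self):
        dist, n = gamma_from_values([1, 1, 0, 0], range(2))
        assert n == 4
        assert dist == {0: 50.0, 1: 50.0}

    def test_all_ones(self):
        dist, _ = gamma_from_values([1, 1, 1], range(2))
        assert dist[1] == 100.0 and dist[0] == 0.0

    def test_none_excluded_from_denominator(self):
        dist, n = gamma_from_values([1, None, 0, 1], range(2))
        assert n == 3
        assert dist[1] == pytest.approx(100 * 2 / 3)

    def test_interval_sums_by_brute_force(self):
        scores = [build_score([1] * v + [0] * (6 - v), [0] * 5) for v in (0, 2, 4, 6)]
        dist, _ = gamma_distribution(scores, "psi_survival")
        # brute-force count: psi values {0,2,4,6}
        assert interval_probability(dist, (0, 3)) == pytest.approx(50.0)
        assert interval_probability(dist, (4, 6)) == pytest.approx(50.0)

    def test_complement_intervals_sum_to_100(self):
        rng = np.random.default_rng(3)
        scores = [
            build_score(rng.integers(0, 2, 6).tolist(), rng.integers(0, 2, 5).tolist())
            for _ in range(23)
        ]
        dist, _ = gamma_distribution(scores, "psi_survival")
        assert interval_probability(dist, (0, 3)) + interval_probability(dist, (4, 6)) == pytest.approx(100.0)
        ddist, _ = gamma_distribution(scores, "psi_derivative")
        assert interval_probability(ddist, (0, 2)) + interval_probability(ddist, (3, 5)) == pytest.approx(100.0)

    def test_out_of_range_interval_rejected(self):
        dist, _ = gamma_from_values([0, 1], range(2))
        with pytest.raises(ValidationError, match="outside"):
            interval_probability(dist, (0, 3))


class TestAdventitiousProbability:
    def test_six_conditions(self):
        assert adventitious_median_probability(6) == 0.015625

    def test_single_condition(self):
        assert adventitious_median_probability(1) == 0.5

    def test_three_conditions_by_enumeration(self):
        patterns = list(itertools.product((-1, 1), repeat=3))
        oracle = sum(all(s > 0 for s in p) for p in patterns) / len(patterns)
        assert adventitious_median_probability(3) == pytest.approx(oracle) == 0.125


class TestSelfScoring:
    def test_reference_pool_splits_at_ceil_half(self):
        """Scoring 35 distinct-valued references against their own medians
        puts ceil(35/2) = 18 of them at or above the median in every cell."""
        rng = np.random.default_rng(11)
        pool = []
        for i in range(35):
            values = rng.uniform(0.2, 2.0, size=6)
            pool.append(make_pair(f"r{i}", values))
        touch = compute_touchstones(pool)
        scores = [score_compound(s, d, touch) for s, d in pool]
        for cell in STANDARD_CELLS:
            dist, n = gamma_distribution(scores, "phi", cell)
            assert n == 35
            assert dist[1] == pytest.approx(100 * 18 / 35)

    @given(
        base=st.lists(st.floats(min_value=0.0, max_value=3.0), min_size=6, max_size=6),
        delta=st.floats(min_value=0.0, max_value=2.0),
    )
    def test_psi_survival_monotone_in_uniform_shift(self, base, delta):
        rng = np.random.default_rng(20260930)
        pool = [
            make_pair(f"ref{i}", 0.5 + rng.permutation(12)[:6] * 0.07 + i * 0.013)
            for i in range(7)
        ]
        touch = compute_touchstones(pool)
        lo_s, lo_d = make_pair("lo", base)
        hi_s, hi_d = make_pair("hi", [v + delta for v in base])
        lo = score_compound(lo_s, lo_d, touch)
        hi = score_compound(hi_s, hi_d, touch)
        assert hi.psi_survival >= lo.psi_survival
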