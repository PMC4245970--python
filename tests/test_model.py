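"""Likelihood evaluation and the decay-correction estimator.

The closed-form estimate is checked against an independent numeric
maximization of the same log-likelihood (conftest.numeric_mle_theta); the
worked L = 2 example's expected values were frozen from that oracle.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shapeseq import (
    DropoffModel,
    ReactivityModel,
    estimate_theta,
    loglikelihood,
    stop_distribution,
)
from conftest import numeric_mle_theta


class TestLoglikelihood:
    def test_point_mass_has_probability_one(self):
        L = 4
        theta = np.zeros(L)
        theta[-1] = 1.0
        model = DropoffModel(gamma=np.zeros(L), theta=theta, p_mod=1.0)
        plus = np.array([0, 0, 0, 0, 7])   # every molecule stops at k = L
        minus = np.array([5, 0, 0, 0, 0])  # every control reads through
        assert loglikelihood(model, plus, minus) == pytest.approx(0.0)

    def test_impossible_event_gives_minus_infinity(self):
        L = 3
        model = DropoffModel(gamma=np.zeros(L), theta=np.full(L, 1 / 3),
                             p_mod=0.0)
        plus = np.array([0, 1, 0, 0])  # a stop despite no stopping cause
        minus = np.array([1, 0, 0, 0])
        assert loglikelihood(model, plus, minus) == float("-inf")

    def test_single_minus_read_direct_evaluation(self):
        # stop at k=2: gamma_2 * (1 - gamma_3) = 0.2 * 0.9 = 0.18
        model = DropoffModel(gamma=np.array([0.1, 0.2, 0.1]),
                             theta=np.array([0.2, 0.3, 0.5]), p_mod=0.5)
        plus = np.zeros(4, dtype=int)
        minus = np.array([0, 0, 1, 0])
        assert loglikelihood(model, plus, minus) == pytest.approx(np.log(0.18))

    @pytest.mark.parametrize("channel", ["plus", "minus"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_stop_distribution_is_a_distribution(self, channel, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 12))
        theta = rng.dirichlet(np.ones(L))
        model = DropoffModel(gamma=rng.uniform(0, 0.3, L), theta=theta,
                             p_mod=float(rng.uniform(0, 1)))
        p = stop_distribution(model, channel)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestEstimator:
    def test_no_signal_gives_flagged_degenerate_profile(self):
        counts = np.array([50, 10, 20, 20])
        res = estimate_theta(counts, counts, exclude_3prime_terminal=False)
        assert res.degenerate
        assert np.all(res.theta == 0)

    def test_worked_l2_example_matches_numeric_mle(self):
        """minus=[90,0,10], plus=[40,20,40]: hazards give m=(1/3,1/3) and the
        survival product makes the MLE theta=(0.4,0.6) with p_mod=5/9 —
        values frozen from the numeric oracle."""
        minus = np.array([90, 0, 10])
        plus = np.array([40, 20, 40])
        res = estimate_theta(plus, minus, exclude_3prime_terminal=False)
        assert res.theta == pytest.approx([0.4, 0.6], abs=1e-12)
        assert res.p_mod == pytest.approx(5 / 9, abs=1e-12)
        oracle = numeric_mle_theta(plus, minus, n_restarts=30)
        assert res.theta == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_closed_form_equals_numeric_mle_small_instances(self, seed):
        from shapeseq import SimParams, TargetRNA, simulate_stop_counts

        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 5))
        target = TargetRNA(name="t",
                           sequence="".join(rng.choice(list("ACGU"), L)))
        model = DropoffModel(gamma=rng.uniform(0.0, 0.15, L),
                             theta=rng.dirichlet(np.full(L, 2.0)),
                             p_mod=0.5)
        plus, minus, _ = simulate_stop_counts(
            SimParams(target=target, model=model, n_plus=100, n_minus=100,
                      seed=seed + 1000))
        res = estimate_theta(plus, minus, exclude_3prime_terminal=False)
        if res.degenerate:
            return
        oracle = numeric_mle_theta(plus.counts, minus.counts, n_restarts=20,
                                   seed=seed)
        assert np.max(np.abs(res.theta - oracle)) < 1e-3

    def test_integer_scaling_of_both_channels_is_exact_invariance(self):
        rng = np.random.default_rng(5)
        plus = rng.integers(0, 50, size=9)
        minus = rng.integers(1, 50, size=9)
        base = estimate_theta(plus, minus)
        for c in (2, 7, 100):
            scaled = estimate_theta(c * plus, c * minus)
            assert np.array_equal(base.theta, scaled.theta)

    def test_increasing_plus_count_does_not_decrease_unnormalized_mass(self):
        rng = np.random.default_rng(11)
        plus = rng.integers(5, 50, size=8)
        minus = rng.integers(5, 50, size=8)
        k = 3
        last_u = -1.0
        for extra in (0, 5, 20, 80):
            x = plus.copy()
            x[k] += extra
            res = estimate_theta(x, minus, exclude_3prime_terminal=False)
            u_k = res.theta[k - 1] * res.p_mod  # pre-normalization mass
            assert u_k >= last_u - 1e-15
            last_u = u_k

    def test_unreached_positions_are_flagged_not_imputed(self):
        # no minus molecule ever reaches position 1 or 2
        minus = np.array([0, 0, 0, 40, 60])
        plus = np.array([10, 5, 5, 40, 40])
        res = estimate_theta(plus, minus, exclude_3prime_terminal=False)
        assert res.flags["unreached_minus"].loc[[1, 2]].all()
        assert res.theta[:2] == pytest.approx([0.0, 0.0])
        if not res.degenerate:
            assert res.theta.sum() == pytest.approx(1.0, abs=1e-9)

    def test_3prime_exclusion_shrinks_scored_range(self):
        plus = np.array([10, 5, 5, 9])
        minus = np.array([20, 2, 3, 4])
        on = estimate_theta(plus, minus, exclude_3prime_terminal=True)
        off = estimate_theta(plus, minus, exclude_3prime_terminal=False)
        assert on.scored_positions.tolist() == [1, 2]
        assert off.scored_positions.tolist() == [1, 2, 3]

    def test_counts_table_roundtrip_drives_model(self, tmp_path):
        from shapeseq import StopCountVector, write_counts_table

        plus = StopCountVector("t", "plus", np.array([30, 10, 20, 5]))
        minus = StopCountVector("t", "minus", np.array([50, 5, 8, 2]))
        path = tmp_path / "counts.tsv"
        write_counts_table(plus, minus, path)
        res = ReactivityModel.from_counts_table(path).fit()
        direct = estimate_theta(plus, minus)
        assert np.array_equal(res.theta, direct.theta)
        assert res.target_name == "t"


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    counts=st.lists(
        st.tuples(st.integers(0, 200), st.integers(0, 200)),
        min_size=3, max_size=12,
    )
)
def test_theta_sums_to_one_or_is_flagged_degenerate(counts):
    plus = np.array([c[0] for c in counts])
    minus = np.array([c[1] for c in counts])
    if plus.sum() == 0 or minus.sum() == 0:
        return
    res = estimate_theta(plus, minus, exclude_3prime_terminal=False)
    assert np.all(res.theta >= 0)
    if res.degenerate:
        assert np.all(res.theta == 0)
    else:
        assert abs(res.theta.sum() - 1.0) <= 1e-9


def test_summary_and_table_report_fit(tmp_path):
    rng = np.random.default_rng(2)
    plus = rng.integers(0, 80, size=12)
    minus = rng.integers(1, 80, size=12)
    res = estimate_theta(plus, minus)
    text = res.summary()
    assert "decay correction" in text and "p_mod" in text
    out = tmp_path / "react.tsv"
    res.write_reactivity_table(out)
    content = out.read_text()
    assert content.startswith("# target=")
    assert "theta\trho" in content.replace("nucleotide\t", "")
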