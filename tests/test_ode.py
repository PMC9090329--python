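"""Population dynamics: transition rates, conservation, equilibria."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from collective_rescue.ode import (
    PopulationParams,
    PopulationState,
    asocial_equilibrium_diff,
    classify_regime,
    integrate_to_equilibrium,
    ode_rhs,
    stable_equilibria_scan,
    transition_probs,
)


class TestTransitionProbs:
    def test_asocial_rates(self):
        params = PopulationParams(N=20, e=0.6, pl=0.2, ph=0.7, sigma=0.0, theta=3.0)
        state = PopulationState(4.0, 9.0, 7.0)
        assert transition_probs(state, params) == pytest.approx((0.7, 0.2, 0.2, 0.7))

    def test_balanced_population_gives_half_social_term(self):
        for theta in (-2.0, 0.0, 1.0, 5.0):
            params = PopulationParams(N=20, e=0.6, pl=0.2, ph=0.7, sigma=1.0, theta=theta)
            state = PopulationState(10.0, 5.0, 5.0)
            assert transition_probs(state, params) == pytest.approx((0.5, 0.5, 0.5, 0.5))

    def test_full_social_linear_conformity(self):
        params = PopulationParams(N=20, e=0.6, pl=0.2, ph=0.7, sigma=1.0, theta=1.0)
        state = PopulationState(5.0, 10.0, 5.0)  # NR=5, NS=15
        assert transition_probs(state, params) == pytest.approx((0.75, 0.25, 0.75, 0.25))

    def test_empty_population_rejected(self):
        params = PopulationParams(N=20, e=0.6, pl=0.2, ph=0.7, sigma=0.5, theta=1.0)
        with pytest.raises(ValueError):
            transition_probs(PopulationState(0.0, 0.0, 0.0), params)

    def test_rate_ordering_validation(self):
        with pytest.raises(ValueError):
            PopulationParams(N=20, e=0.5, pl=0.8, ph=0.7)


class TestOdeRhs:
    @given(
        nr=st.floats(0.1, 19.9),
        split=st.floats(0.0, 1.0),
        e=st.floats(0, 1),
        sigma=st.floats(0, 1),
        theta=st.floats(-5, 5),
        pl=st.floats(0, 1),
        ph_gap=st.floats(0, 1),
    )
    def test_conservation(self, nr, split, e, sigma, theta, pl, ph_gap):
        ph = pl + (1 - pl) * ph_gap
        params = PopulationParams(N=20, e=e, pl=pl, ph=ph, sigma=sigma, theta=theta)
        ns = 20 - nr
        state = PopulationState(nr, ns * split, ns * (1 - split))
        assert ode_rhs(state, params).sum() == pytest.approx(0.0, abs=1e-12)

    def test_hand_bookkeeping(self):
        # sigma=0, state (10, 5, 5), e=0.5, ph=0.7, pl=0.2:
        # dNR = 0.2*5 - 0.7*5 + 0.7*5 - 0.2*5 = 0
        # dNS- = -0.2*5 + 0.7*0.5*10 = 2.5; dNS+ = -0.7*5 + 0.2*0.5*10 = -2.5
        params = PopulationParams(N=20, e=0.5, pl=0.2, ph=0.7, sigma=0.0)
        d = ode_rhs(PopulationState(10.0, 5.0, 5.0), params)
        assert d == pytest.approx([0.0, 2.5, -2.5])

    def test_vanishes_at_asocial_equilibrium(self):
        ph, pl, e, N = 0.7, 0.2, 0.6, 20.0
        ratio = e * pl / ph + (1 - e) * ph / pl  # NS*:NR*
        nr = N / (1 + ratio)
        ns = N - nr
        # attitude split at equilibrium: dNS-/dt = 0 -> NS- = ph(1-e)NR/pl
        ns_minus = ph * (1 - e) * nr / pl
        ns_plus = ns - ns_minus
        params = PopulationParams(N=N, e=e, pl=pl, ph=ph, sigma=0.0)
        d = ode_rhs(PopulationState(nr, ns_minus, ns_plus), params)
        assert np.max(np.abs(d)) < 1e-9


class TestAsocialClosedForm:
    def test_neutral_risk_premium(self):
        ph, pl = 0.7, 0.2
        e = ph / (ph + pl)
        assert asocial_equilibrium_diff(ph, pl, e, 20) == pytest.approx(0.0, abs=1e-12)

    def test_equal_rates_neutral(self):
        assert asocial_equilibrium_diff(0.5, 0.5, 0.9, 20) == 0.0

    def test_printed_example(self):
        assert asocial_equilibrium_diff(0.7, 0.2, 0.5, 20) == pytest.approx(-6.17, abs=0.01)

    @given(
        pl=st.floats(0.05, 0.95),
        gap=st.floats(0.0, 1.0),
        e=st.floats(0.0, 1.0),
    )
    def test_consistent_with_ratio_form(self, pl, gap, e):
        ph = pl + (0.99 - pl) * gap
        n = 20.0
        ratio = e * pl / ph + (1 - e) * ph / pl
        nr = n / (1 + ratio)
        assert asocial_equilibrium_diff(ph, pl, e, n) == pytest.approx(
            nr - (n - nr), rel=1e-9, abs=1e-9
        )

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError):
            asocial_equilibrium_diff(0.0, 0.0, 0.5, 20)


class TestIntegration:
    def test_asocial_equilibrium_matches_closed_form(self, rng):
        for _ in range(20):
            pl = rng.uniform(0.05, 0.6)
            ph = rng.uniform(pl, 1.0)
            e = rng.uniform(0, 1)
            params = PopulationParams(N=20, e=e, pl=pl, ph=ph, sigma=0.0)
            state, ok = integrate_to_equilibrium(params, PopulationState(10, 5, 5))
            assert ok
            diff = state.NR - state.NS
            assert diff == pytest.approx(
                asocial_equilibrium_diff(ph, pl, e, 20), abs=1e-3 * 20
            )

    def test_equilibrium_input_returned_unchanged(self):
        params = PopulationParams(N=20, e=0.6, pl=0.2, ph=0.7, sigma=0.0)
        start, ok = integrate_to_equilibrium(params, PopulationState(10, 5, 5))
        assert ok
        again, ok2 = integrate_to_equilibrium(params, start)
        assert ok2
        assert again.as_array() == pytest.approx(start.as_array(), abs=1e-6)

    def test_conservation_and_nonnegativity_along_trajectory(self, rng):
        for _ in range(25):
            pl = rng.uniform(0.01, 0.6)
            ph = rng.uniform(pl, 1.0)
            params = PopulationParams(
                N=20, e=rng.uniform(0, 1), pl=pl, ph=ph,
                sigma=rng.uniform(0, 1), theta=rng.uniform(-3, 3),
            )
            nr0 = rng.uniform(0, 20)
            state, _ok = integrate_to_equilibrium(
                params, PopulationState(nr0, (20 - nr0) / 2, (20 - nr0) / 2), t_max=200
            )
            assert state.total == pytest.approx(20.0, abs=1e-9 * 20)
            assert min(state.NR, state.NS_minus, state.NS_plus) >= -1e-12

    def test_nonconvergence_is_flagged(self):
        params = PopulationParams(N=20, e=0.5, pl=0.2, ph=0.7, sigma=0.0)
        _state, ok = integrate_to_equilibrium(
            params, PopulationState(0.0, 10.0, 10.0), t_max=1e-3
        )
        assert not ok

    def test_mismatched_total_rejected(self):
        params = PopulationParams(N=20, e=0.5, pl=0.2, ph=0.7)
        with pytest.raises(ValueError):
            integrate_to_equilibrium(params, PopulationState(1.0, 1.0, 1.0))

    def test_low_risk_premium_never_risk_seeking(self):
        """e <= 1/2 cannot produce a risk-seeking equilibrium in the
        asocial system (any start) nor under modest social weight.

        Strong conformity (large sigma, theta > 1) can still sustain a
        risk-seeking herding equilibrium from a risky-majority start,
        which is the bistable-conformism branch, so it is excluded here.
        """
        for sigma, theta in [(0.0, 0.0), (0.0, 2.0), (0.2, 1.0), (0.4, 2.0)]:
            params = PopulationParams(N=20, e=0.4, pl=0.2, ph=0.7, sigma=sigma, theta=theta)
            for nr0 in (2.0, 10.0, 18.0):
                state, ok = integrate_to_equilibrium(
                    params, PopulationState(nr0, (20 - nr0) / 2, (20 - nr0) / 2)
                )
                assert ok
                assert state.NR < state.NS + 1e-6


class TestRegimesAndScan:
    def test_classify_examples(self):
        assert classify_regime(PopulationState(13, 3.5, 3.5), 20) == "risk_seeking"
        assert classify_regime(PopulationState(10, 5, 5), 20) == "neutral"
        assert classify_regime(PopulationState(5, 10, 5), 20) == "risk_averse"

    def test_asocial_risk_aversion_condition(self):
        # e < ph/(ph+pl) implies risk aversion at the asocial equilibrium
        ph, pl, e = 0.7, 0.2, 0.6  # ph/(ph+pl) = 0.778 > e
        params = PopulationParams(N=20, e=e, pl=pl, ph=ph, sigma=0.0)
        state, _ = integrate_to_equilibrium(params, PopulationState(10, 5, 5))
        assert classify_regime(state, 20) == "risk_averse"

    def test_asocial_column_has_unique_equilibrium(self):
        df = stable_equilibria_scan(
            N=20, e=0.65, pl=0.2, ph=0.7, theta=2.0, sigma_grid=[0.0],
            init_grid=np.arange(0.0, 21.0, 4.0),
        )
        assert df["n_stable"].tolist() == [1]

    def test_random_exploration_risky_shift_vanishes_at_full_copying(self):
        """theta = 0: the social term is pure random choice, so the
        risky-safe asymmetry disappears as sigma -> 1."""
        diffs = {}
        for sigma in (0.5, 0.99):
            params = PopulationParams(N=20, e=0.65, pl=0.2, ph=0.7, sigma=sigma, theta=0.0)
            state, ok = integrate_to_equilibrium(params, PopulationState(10, 5, 5))
            assert ok
            diffs[sigma] = state.NR - state.NS
        assert abs(diffs[0.99]) < 0.2
        assert abs(diffs[0.99]) < abs(diffs[0.5])
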