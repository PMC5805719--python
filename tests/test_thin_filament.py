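"""The regulatory-unit chain: rates, analytic oracle, protocols."""

import numpy as np
import pytest

from sarcokit.errors import InvalidSpecificationError, TimestepError
from sarcokit.fiber import ForcePCaDataset, fit_hill
from sarcokit.params import IsoformEffect, ThinFilamentParams, isoform_effect
from sarcokit.thin_filament import (
    Rates,
    ca_transient,
    effective_rates,
    force_pca_curve,
    integrate_shortening,
    simulate_chain,
    simulate_ktr,
    simulate_twitch,
    stable_dt,
    steady_state_single_unit,
)
from sarcokit.trace import Trace

NONE = isoform_effect("none")


class TestEffectiveRates:
    def test_no_activator_gives_zero_forward_rate(self):
        p = ThinFilamentParams()
        r = effective_rates(p, NONE, 0.0, 0.0)
        assert r.a == 0.0
        assert r.b == p.k_off
        assert (r.f, r.g) == (p.f_app, p.g_app)

    def test_saturating_fragment_adds_k_act(self):
        p = ThinFilamentParams()
        e = IsoformEffect("cardiac", k_act=3.0, drag=0.2, kd_frag=1e-8)
        r = effective_rates(p, e, 1.0, 0.0)  # 1 M >> kd: theta ~ 1
        assert r.a == pytest.approx(3.0, rel=1e-7)

    def test_half_occupancy_algebra(self):
        p = ThinFilamentParams(k_on_max=30.0)
        e = IsoformEffect("cardiac", k_act=4.0, drag=0.2, kd_frag=2e-7)
        r = effective_rates(p, e, e.kd_frag, p.ca50_tn)
        assert r.a == pytest.approx(30.0 / 2 + 4.0 / 2, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            effective_rates(ThinFilamentParams(), NONE, -1e-9, 0.0)


class TestSteadyStateSingleUnit:
    @pytest.mark.parametrize(
        "rates, expected",
        [
            (Rates(0, 1, 5, 2), (1, 0, 0)),            # blocked absorbing
            (Rates(1, 1, 1, 1), (1 / 3, 1 / 3, 1 / 3)),
            (Rates(10, 1, 5, 2), (1 / 36, 10 / 36, 25 / 36)),  # flux balance
        ],
    )
    def test_flux_balance_closed_form(self, rates, expected):
        assert steady_state_single_unit(rates) == pytest.approx(expected, rel=1e-12)

    def test_absorbing_states_not_errors(self):
        assert steady_state_single_unit(Rates(1, 1, 1, 0)) == (0, 0, 1)
        assert steady_state_single_unit(Rates(1, 0, 0, 1))[2] == 0.0


class TestSimulateChain:
    def test_no_pathway_out_of_blocked(self):
        trace, state = simulate_chain(
            ThinFilamentParams(n_units=10), NONE, 0.0, 0.0, 0.5, seed=3
        )
        assert np.all(trace.y == 0.0)
        assert np.all(state.unit_states == 0)

    def test_identical_seeds_identical_traces(self):
        p = ThinFilamentParams()
        a, sa = simulate_chain(p, NONE, 0.0, 1e-6, 1.0, seed=42)
        b, sb = simulate_chain(p, NONE, 0.0, 1e-6, 1.0, seed=42)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(sa.unit_states, sb.unit_states)
        c, _ = simulate_chain(p, NONE, 0.0, 1e-6, 1.0, seed=43)
        assert not np.array_equal(a.y, c.y)

    def test_occupancy_is_a_fraction(self):
        trace, _ = simulate_chain(ThinFilamentParams(), NONE, 0.0, 3e-6, 2.0, seed=0)
        assert np.all((trace.y >= 0) & (trace.y <= 1))

    def test_uncoupled_chain_matches_analytic_occupancy(self):
        """gamma=1 long-run time average agrees with the flux-balance oracle."""
        p = ThinFilamentParams(n_units=100, gamma=1.0)
        trace, _ = simulate_chain(p, NONE, 0.0, p.ca50_tn, 30.0, seed=5)
        tail = trace.y[trace.t > 10.0]
        expected = steady_state_single_unit(effective_rates(p, NONE, 0.0, p.ca50_tn))[2]
        # 3 x Monte-Carlo SE from batch means over the tail
        batches = np.array_split(tail, 20)
        se = np.std([b.mean() for b in batches], ddof=1) / np.sqrt(20)
        assert abs(tail.mean() - expected) < 3 * max(se, 1e-3)

    def test_dt_guard_reports_required_step(self):
        p = ThinFilamentParams(gamma=40.0)
        limit = stable_dt(p, NONE, 0.0, 1e-4)
        with pytest.raises(TimestepError) as exc:
            simulate_chain(p, NONE, 0.0, 1e-4, 0.1, dt=10 * limit, seed=0)
        assert exc.value.required_dt == pytest.approx(limit)


class TestForcePCaCurve:
    def test_relaxed_control_is_inactive(self):
        df = force_pca_curve(
            ThinFilamentParams(), NONE, 0.0, [9.0], duration=2.0, seed=1
        )
        assert df["pi_m"].iloc[0] < 0.02

    def test_normalized_curve_is_one_at_minimum_pca(self):
        df = force_pca_curve(
            ThinFilamentParams(n_units=50), NONE, 0.0, [4.5, 5.5, 6.5],
            duration=3.0, seed=1, normalized=True,
        )
        assert df.loc[df["pca"].idxmin(), "pi_m"] == pytest.approx(1.0)

    def test_fragment_activation_raises_pca50(self):
        """An added Ca-independent on-rate shifts the curve leftward."""
        grid = [5.5, 6.0, 6.4, 6.8, 7.2, 7.6, 8.0, 9.0]
        p = ThinFilamentParams(n_units=80)
        fits = {}
        for iso in ("none", "cardiac"):
            dfs = [
                force_pca_curve(p, isoform_effect(iso), 2.5e-7, grid,
                                duration=6.0, seed=s)
                for s in (1, 2, 3)
            ]
            pim = np.mean([d["pi_m"].to_numpy() for d in dfs], axis=0)
            fits[iso] = fit_hill(ForcePCaDataset(np.array(grid), pim))
        assert fits["cardiac"].pca50 > fits["none"].pca50

    def test_cooperativity_steepens_the_curve(self):
        """Fitted n_H is non-decreasing in gamma, up to the grid's resolving
        power (steeper-than-grid transitions are unidentifiable ties)."""
        grid = np.round(np.arange(5.0, 10.01, 0.5), 2)
        nh = []
        for gamma in (1.0, 40.0, 100.0):
            p = ThinFilamentParams(n_units=26, gamma=gamma)
            df = force_pca_curve(p, NONE, 0.0, list(grid), duration=6.0, seed=11)
            fit = fit_hill(ForcePCaDataset(df["pca"].to_numpy(), df["pi_m"].to_numpy()))
            nh.append(fit.n_h)
        resolution_cap = 2.0 / 0.5  # transitions sharper than this are ties
        clamped = np.minimum(nh, resolution_cap)
        assert np.all(np.diff(clamped) >= -1e-9), nh


class TestSimulateKtr:
    def test_release_detaches_every_crossbridge(self):
        tr = simulate_ktr(
            ThinFilamentParams(n_units=50), NONE, 0.0, 3e-5, 1.0, 2.0, seed=2
        )
        assert tr.t[0] == 0.0
        assert tr.y[0] == 0.0

    def test_recovery_plateau_matches_pre_release(self):
        tr = simulate_ktr(
            ThinFilamentParams(n_units=300), NONE, 0.0, 3e-5, 3.0, 7.0, seed=4
        )
        plateau_post = tr.y[tr.t > 2.0].mean()
        assert plateau_post == pytest.approx(tr.meta["pre_release_pi_m"], abs=0.03)


class TestCaTransient:
    def test_starts_at_diastolic_level(self):
        tr = ca_transient(np.arange(-0.2, 1.0, 1e-3), 7.0, 6.0)
        assert tr.y[0] == pytest.approx(1e-7)
        assert tr.y[np.searchsorted(tr.t, 0.0)] == pytest.approx(1e-7, rel=1e-6)

    def test_peak_equals_requested_concentration(self):
        tr = ca_transient(np.arange(0.0, 2.0, 1e-4), 7.0, 5.8)
        assert tr.y.max() == pytest.approx(10**-5.8, rel=1e-6)

    def test_degenerate_amplitude_gives_constant_trace(self):
        tr = ca_transient(np.arange(0.0, 1.0, 1e-3), 6.5, 6.5)
        assert np.all(tr.y == tr.y[0])

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            ca_transient(np.arange(0.0, 1.0, 1e-3), 7.0, 6.0, tau_rise=0.3, tau_decay=0.2)
        with pytest.raises(InvalidSpecificationError):
            ca_transient(np.arange(0.0, 1.0, 1e-3), 5.0, 7.0)


class TestShortening:
    def test_rectangular_occupancy_relaxes_at_k_restore(self):
        """Post-pulse SL recovery is a clean exponential with rate k_restore."""
        t = np.arange(0.0, 3.0, 1e-3)
        pm = np.where((t > 0.2) & (t < 0.7), 0.5, 0.0)
        sl = integrate_shortening(Trace(t, pm), sl_rest=1.8, v_eff=2.0, k_restore=5.0)
        rec = (t > 0.705) & (t < 2.0)
        slope = np.polyfit(t[rec], np.log(1.8 - sl.y[rec]), 1)[0]
        assert -slope == pytest.approx(5.0, rel=1e-6)

    def test_diastolic_transient_leaves_sl_at_rest(self):
        t = np.arange(-0.5, 1.0, 1e-3)
        trans = ca_transient(t, 9.0, 9.0)
        sl = simulate_twitch(
            ThinFilamentParams(n_units=30), NONE, 0.0, trans, seed=8
        )
        assert np.allclose(sl.y, 1.8, atol=1e-6)
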