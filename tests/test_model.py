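"""Simulator unit and property tests: prior sampling, passive RC oracle,
steady-state initialization, kinetics pinning, reproducibility, gate bounds,
dt convergence, and the repolarizing effect of the delayed-rectifier K
conductance."""

import numpy as np
import pytest

from neulink.model import (
    GATE_NAMES,
    PARAM_NAMES,
    PRIOR_HIGH,
    PRIOR_LOW,
    HHParameters,
    PhysConstants,
    PriorBox,
    StimulusProtocol,
    gate_rates,
    passive_closed_form,
    sample_prior,
    simulate,
    simulate_batch,
    steady_state_init,
)
from neulink.features import extract_features, transform_features

PASSIVE = np.array([1.0, 100.0, 10.0, 0, 0, 0, 0, 0, 0, -70.0, 1000.0, -60.0, 1.0])


class TestPrior:
    def test_support_and_mean(self):
        theta = sample_prior(100_000, seed=0)
        rng = PRIOR_HIGH - PRIOR_LOW
        assert np.all(theta.min(axis=0) <= PRIOR_LOW + 0.001 * rng)
        assert np.all(theta.max(axis=0) >= PRIOR_HIGH - 0.001 * rng)
        mid = (PRIOR_LOW + PRIOR_HIGH) / 2
        se = rng / np.sqrt(12 * 100_000)
        assert np.all(np.abs(theta.mean(axis=0) - mid) < 3 * se)

    def test_deterministic(self):
        a = sample_prior(3, seed=7)
        b = sample_prior(3, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_rejects_bad_n(self):
        with pytest.raises(ValueError):
            sample_prior(0)

    def test_box_override(self):
        box = PriorBox().replace(gbar_Na=(0.0, 1e-9))
        theta = sample_prior(100, box, seed=1)
        assert np.all(theta[:, PARAM_NAMES.index("gbar_Na")] <= 1e-9)


class TestKinetics:
    """Pin the transcribed rate formulas at a few voltages against direct
    hand evaluation (no Q10/r_SS scaling so the raw forms are visible)."""

    @pytest.mark.parametrize("V", [-60.0, -40.0, 0.0])
    def test_pinned_rates(self, V):
        c = PhysConstants(T_experiment=36.0, T_ref_kinetics=36.0)  # qt = 1
        cols = {"V_T": -60.0, "tau_max": 1000.0, "r_SS": 1.0}
        r = gate_rates(V, cols, c)
        u = V - cols["V_T"]

        def vt(num, den):  # x/(exp(x/den)-1) evaluated directly away from poles
            return num / (np.exp(num / den) - 1.0)

        assert r["m"][0] == pytest.approx(0.32 * vt(-(u - 13.0), 4.0), rel=1e-9)
        assert r["m"][1] == pytest.approx(0.28 * vt(u - 40.0, 5.0), rel=1e-9)
        assert r["h"][0] == pytest.approx(0.128 * np.exp(-(u - 17.0) / 18.0), rel=1e-12)
        assert r["h"][1] == pytest.approx(4.0 / (1 + np.exp(-(u - 40.0) / 5.0)), rel=1e-12)
        assert r["n"][0] == pytest.approx(0.032 * vt(-(u - 15.0), 5.0), rel=1e-9)
        assert r["n"][1] == pytest.approx(0.5 * np.exp(-(u - 10.0) / 40.0), rel=1e-12)
        p_inf = 1.0 / (1 + np.exp(-(V + 35.0) / 10.0))
        tau_p = 1000.0 / (3.3 * np.exp((V + 35.0) / 20.0) + np.exp(-(V + 35.0) / 20.0))
        assert r["p"][0] == pytest.approx(p_inf / tau_p, rel=1e-12)
        assert r["p"][1] == pytest.approx((1 - p_inf) / tau_p, rel=1e-12)
        assert r["mt"][0] == pytest.approx(0.182 * vt(-(V + 38.0), 6.0), rel=1e-9)
        assert r["mt"][1] == pytest.approx(0.124 * vt(V + 38.0, 6.0), rel=1e-9)
        assert r["ht"][0] == pytest.approx(0.015 * vt(V + 66.0, 6.0), rel=1e-9)
        assert r["ht"][1] == pytest.approx(0.015 * vt(-(V + 66.0), 6.0), rel=1e-9)
        v_inf = 1.0 / (1 + np.exp(-(V - 18.7) / 9.7))
        tau_v = 4.0 / (1 + np.exp(-(V + 46.56) / 44.14))
        assert r["v"][0] == pytest.approx(v_inf / tau_v, rel=1e-12)
        assert r["q"][0] == pytest.approx(0.055 * vt(-27.0 - V, 3.8), rel=1e-9)
        assert r["q"][1] == pytest.approx(0.94 * np.exp((-75.0 - V) / 17.0), rel=1e-12)
        assert r["r"][0] == pytest.approx(0.000457 * np.exp((-13.0 - V) / 50.0), rel=1e-12)
        assert r["r"][1] == pytest.approx(0.0065 / (np.exp((-15.0 - V) / 28.0) + 1), rel=1e-12)

    def test_rates_nonnegative_over_plausible_voltages(self):
        V = np.linspace(-130.0, 60.0, 381)
        cols = {"V_T": np.array([-90.0]), "tau_max": np.array([50.0]),
                "r_SS": np.array([0.1])}
        for VT in (-90.0, -35.0):
            cols["V_T"] = np.array([VT])
            r = gate_rates(V[:, None], cols, PhysConstants())
            for g, (a, b) in r.items():
                assert np.all(a >= 0) and np.all(b >= 0), g

    def test_rss_scales_only_na_kd_gates(self):
        c = PhysConstants()
        base = {"V_T": -60.0, "tau_max": 1000.0, "r_SS": 1.0}
        fast = dict(base, r_SS=2.0)
        r1, r2 = gate_rates(-40.0, base, c), gate_rates(-40.0, fast, c)
        for g in ("m", "h", "n"):
            assert r2[g][0] == pytest.approx(2 * r1[g][0])
            assert r2[g][1] == pytest.approx(2 * r1[g][1])
        for g in ("mt", "ht", "v", "p", "q", "r"):
            assert r2[g][0] == pytest.approx(r1[g][0])
            assert r2[g][1] == pytest.approx(r1[g][1])


class TestPassive:
    def test_rest_equals_leak_reversal(self):
        prot = StimulusProtocol(noise_enabled=False)
        c = PhysConstants(I_inj=0.0)
        tr = simulate(PASSIVE, prot, c)
        np.testing.assert_allclose(tr.vm, -70.0, atol=1e-9)

    def test_rc_closed_form(self):
        prot = StimulusProtocol(noise_enabled=False)
        tr = simulate(PASSIVE, prot)
        cf = passive_closed_form(PASSIVE, prot)
        step_amp = 100.0 * 300.0 * 1e-3  # R_input * I_inj in mV
        assert np.max(np.abs(tr.vm - cf.vm)) < 0.01 * step_amp

    def test_closed_form_tau_definition(self):
        prot = StimulusProtocol(noise_enabled=False)
        cf = passive_closed_form(PASSIVE, prot)
        i = int(round((prot.t_on + 10.0) / prot.dt))  # t_on + tau
        defl = cf.vm[i] - (-70.0)
        assert defl == pytest.approx((1 - 1 / np.e) * 30.0, rel=1e-6)
        # steady-state deflection R_input*I_inj = 30 mV
        i_end = int(round(prot.t_off / prot.dt)) - 1
        assert cf.vm[i_end] - (-70.0) == pytest.approx(30.0, abs=1e-3)

    def test_closed_form_rejects_noise(self):
        with pytest.raises(ValueError):
            passive_closed_form(PASSIVE, StimulusProtocol(noise_enabled=True))

    def test_random_passive_draws_match_oracle(self):
        """100 random passive parameter draws vs the analytic RC response."""
        box = PriorBox().replace(gbar_Nat=(0, 1e-12), gbar_Na=(0, 1e-12),
                                 gbar_Kd=(0, 1e-12), gbar_M=(0, 1e-12),
                                 gbar_Kv31=(0, 1e-12), gbar_L=(0, 1e-12))
        theta = sample_prior(100, box, seed=5)
        prot = StimulusProtocol(noise_enabled=False)
        c = PhysConstants()
        vm, div = simulate_batch(theta, prot, c)
        assert not div.any()
        for i in range(100):
            cf = passive_closed_form(theta[i], prot, c)
            step_amp = theta[i][1] * c.I_inj * 1e-3
            assert np.max(np.abs(vm[i] - cf.vm)) < 0.01 * step_amp


class TestSteadyState:
    def test_gates_bounded_and_deterministic(self):
        theta = sample_prior(50, seed=9)
        for row in theta[:5]:
            V0, g1 = steady_state_init(row)
            _, g2 = steady_state_init(row)
            assert V0 == row[PARAM_NAMES.index("E_leak")]
            for k in GATE_NAMES:
                assert 0.0 <= g1[k] <= 1.0
                assert g1[k] == g2[k]

    def test_rest_is_near_equilibrium(self):
        """Without stimulus or noise a passive or moderately active cell
        initialized at rest barely drifts; for arbitrary cells the drift
        matches a 10x-finer reference run (it is physiology, not an
        initialization artifact)."""
        prot = StimulusProtocol(t_total=100.0, t_on=0.0, t_off=100.0,
                                noise_enabled=False)
        c = PhysConstants(I_inj=0.0)
        passive = PASSIVE.copy()
        mild = PASSIVE.copy()
        mild[PARAM_NAMES.index("gbar_Nat")] = 50.0
        mild[PARAM_NAMES.index("gbar_Kd")] = 10.0
        for p in (passive, mild):
            vm, _ = simulate_batch(p[None, :], prot, c)
            assert np.max(np.abs(vm - p[PARAM_NAMES.index("E_leak")])) < 2.0
        # arbitrary draws: coarse and fine integrations agree on the drift
        theta = sample_prior(10, seed=12)
        vm, _ = simulate_batch(theta, prot, c)
        fine_prot = StimulusProtocol(t_total=100.0, t_on=0.0, t_off=100.0,
                                     noise_enabled=False, dt=0.005)
        vm_f, _ = simulate_batch(theta, fine_prot, c)
        e = theta[:, PARAM_NAMES.index("E_leak")][:, None]
        drift = np.max(np.abs(vm - e), axis=1)
        drift_f = np.max(np.abs(vm_f - e), axis=1)
        quiet = drift_f < 2.0  # cells that truly sit still
        assert np.all(drift[quiet] < 2.5)


class TestIntegration:
    def test_spiking_reference_crosses_zero(self):
        p = PASSIVE.copy()
        p[PARAM_NAMES.index("gbar_Nat")] = 150.0
        p[PARAM_NAMES.index("gbar_Kd")] = 20.0
        prot = StimulusProtocol(noise_enabled=False)
        tr = simulate(p, prot)
        stim = tr.vm[(tr.t >= 100) & (tr.t < 700)]
        assert np.any(stim > 0.0)
        # fine-step reference integration agrees on the spiking verdict
        fine = simulate(p, StimulusProtocol(noise_enabled=False, dt=0.005))
        assert np.any(fine.vm[(fine.t >= 100) & (fine.t < 700)] > 0.0)

    def test_bit_reproducible(self):
        theta = sample_prior(8, seed=3)
        prot = StimulusProtocol(noise_enabled=False)
        a, _ = simulate_batch(theta, prot)
        b, _ = simulate_batch(theta, prot)
        np.testing.assert_array_equal(a, b)
        prot_n = StimulusProtocol(seed=42)
        a, _ = simulate_batch(theta, prot_n)
        b, _ = simulate_batch(theta, prot_n)
        np.testing.assert_array_equal(a, b)

    def test_noise_batching_invariant(self):
        """Splitting a batch must not change any trace (counter-based noise)."""
        theta = sample_prior(6, seed=4)
        prot = StimulusProtocol(seed=9)
        whole, _ = simulate_batch(theta, prot, sim_indices=np.arange(6))
        parts = [simulate_batch(theta[i:i + 2], prot,
                                sim_indices=np.arange(i, i + 2))[0]
                 for i in (0, 2, 4)]
        np.testing.assert_array_equal(whole, np.vstack(parts))

    def test_gate_bounds_on_prior_draws(self):
        theta = sample_prior(1000, seed=21)
        _, _, grange = simulate_batch(theta, StimulusProtocol(seed=5),
                                      record_gate_range=True)
        for g, (lo, hi) in grange.items():
            assert lo >= 0.0 - 1e-12, g
            assert hi <= 1.0 + 1e-12, g

    def test_dt_convergence_of_features(self):
        """Halving dt leaves defined features nearly unchanged (noise off)."""
        theta = sample_prior(100, seed=31)
        rel_ok = 0
        n_def = 0
        for dt_pair in [(0.05, 0.025)]:
            f = []
            for dt in dt_pair:
                prot = StimulusProtocol(noise_enabled=False, dt=dt)
                vm, _ = simulate_batch(theta, prot)
                from neulink.features import extract_features_batch
                f.append(extract_features_batch(vm, prot))
            a, b = f
            both = np.isfinite(a) & np.isfinite(b)
            n_def = both.sum()
            denom = np.maximum(np.abs(a), np.abs(b))
            rel = np.where(both & (denom > 0), np.abs(a - b) / np.where(denom > 0, denom, 1), 0.0)
            rel_ok = (rel[both] < 0.02).mean()
        assert n_def > 0
        assert rel_ok > 0.9

    def test_kd_conductance_narrows_spikes(self):
        """More delayed-rectifier K never broadens the AP at half height."""
        p = PASSIVE.copy()
        p[PARAM_NAMES.index("gbar_Nat")] = 150.0
        prot = StimulusProtocol(noise_enabled=False)
        widths = []
        for gkd in [5.0, 10.0, 15.0, 20.0, 25.0]:
            q = p.copy()
            q[PARAM_NAMES.index("gbar_Kd")] = gkd
            tr = simulate(q, prot)
            w = extract_features(tr)[2]  # ap_width
            assert np.isfinite(w)
            widths.append(w)
        assert np.all(np.diff(widths) <= 1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HHParameters.from_array(np.zeros(13))  # C = 0 invalid
        hp = HHParameters.from_array(PASSIVE)
        np.testing.assert_array_equal(hp.to_array(), PASSIVE)
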