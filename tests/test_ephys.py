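"""Patch-clamp analysis: QC rules, blocker subtraction, density, G-V fits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from traffickit import ephys
from traffickit.errors import ConfigurationError, IntegrityError
from traffickit.models import boltzmann
from traffickit.simulate import GVTruth, SweepProtocol, simulate_sweeps


class TestQCRules:
    @pytest.mark.parametrize(
        "rseal, rs, expected",
        [
            (0.2, 5.0, True),    # comfortably inside
            (10.0, 10.0, False),  # Rseries boundary: strict <
            (0.1, 5.0, True),    # Rseal boundary: inclusive >=
            (0.05, 5.0, False),
        ],
    )
    def test_boundary_semantics(self, rseal, rs, expected):
        meta = pd.DataFrame([{"cell_id": "c", "rseal_GOhm": rseal, "rseries_MOhm": rs}])
        assert bool(ephys.qc_recordings(meta)["pass"].iloc[0]) is expected

    def test_missing_metadata_fails_with_reason(self):
        meta = pd.DataFrame([{"cell_id": "c", "rseal_GOhm": np.nan, "rseries_MOhm": 5.0}])
        out = ephys.qc_recordings(meta)
        assert not out["pass"].iloc[0]
        assert out["reasons"].iloc[0] == "metadata-absent"

    def test_matches_brute_force_enumeration(self):
        rseals = [0.05, 0.0999, 0.1, 0.5, 2.0]
        rss = [1.0, 9.999, 10.0, 15.0]
        meta = pd.DataFrame(
            [{"cell_id": f"c{i}", "rseal_GOhm": a, "rseries_MOhm": b}
             for i, (a, b) in enumerate(itertools.product(rseals, rss))]
        )
        out = ephys.qc_recordings(meta)
        expected = [(a >= 0.1) and (b < 10.0) for a, b in itertools.product(rseals, rss)]
        assert list(out["pass"]) == expected


@pytest.fixture(scope="module")
def clean_pair():
    proto = SweepProtocol(dt_ms=5.0)
    truth = GVTruth()
    before, after = simulate_sweeps(proto, truth, rseries_MOhm=4.0, seed=21)
    return proto, truth, before, after


class TestBlockerSubtract:
    def test_identical_recordings_flagged_insensitive(self, clean_pair):
        _, _, before, _ = clean_pair
        diff, sensitive = ephys.blocker_subtract(before, before)
        assert not sensitive
        assert np.allclose(diff.sweeps["i_pA"], 0.0)

    def test_pointwise_difference(self, clean_pair):
        _, _, before, after = clean_pair
        diff, sensitive = ephys.blocker_subtract(before, after)
        assert sensitive
        expected = before.sweeps["i_pA"].to_numpy() - after.sweeps["i_pA"].to_numpy()
        assert np.array_equal(diff.sweeps["i_pA"].to_numpy(), expected)

    def test_linearity_under_gain(self, clean_pair):
        _, _, before, after = clean_pair
        a = 3.0
        sb, sa = before.sweeps.copy(), after.sweeps.copy()
        sb["i_pA"] *= a
        sa["i_pA"] *= a
        from dataclasses import replace
        scaled_diff, _ = ephys.blocker_subtract(replace(before, sweeps=sb),
                                                replace(after, sweeps=sa))
        diff, _ = ephys.blocker_subtract(before, after)
        assert np.allclose(scaled_diff.sweeps["i_pA"], a * diff.sweeps["i_pA"])

    def test_mismatched_protocols_rejected(self, clean_pair):
        _, truth, before, _ = clean_pair
        other_b, _ = simulate_sweeps(SweepProtocol(dt_ms=10.0), truth, seed=21)
        with pytest.raises(IntegrityError):
            ephys.blocker_subtract(before, other_b)


def flat_recording(i_pA=500.0, cm=10.0, dt=10.0):
    proto = SweepProtocol(v_test_mV=(0.0, 10.0, 20.0, 30.0, 40.0), dt_ms=dt)
    frames = []
    n = int(4000 / dt)
    t = np.arange(n) * dt
    for sid, v in enumerate(proto.v_test_mV):
        vc = np.where(t < proto.t_depol_ms, v, proto.v_tail_mV)
        frames.append(pd.DataFrame(
            {"sweep_id": sid, "time_ms": t, "v_cmd_mV": vc, "i_pA": i_pA}))
    from traffickit.simulate.sweeps import SweepRecording
    return SweepRecording("flat", "before_blocker", pd.concat(frames, ignore_index=True),
                          cm_pF=cm, rseries_MOhm=0.0, rseal_GOhm=1.0, protocol=proto)


class TestCurrentDensity:
    def test_constant_trace_identity(self):
        rec = flat_recording(i_pA=500.0, cm=10.0)
        dens = ephys.peak_current_density(rec)
        assert np.allclose(dens["density_pA_pF"], 50.0)

    def test_activation_closed_form_at_1990ms(self, clean_pair):
        proto, truth, before, after = clean_pair
        diff, _ = ephys.blocker_subtract(before, after)
        dens = ephys.peak_current_density(diff)
        # top step: I(1990) = I_ss * (1 - exp(-1990/tau)); I_ss implied by the
        # generator's self-consistent membrane potential
        i_1990 = dens["i_pA"].iloc[-1]
        act = 1 - np.exp(-1990.0 / truth.tau_act_ms)
        leak = 60.0 / before.rseal_GOhm  # seal leak at the command potential
        vm = 60.0
        for _ in range(200):
            i_spec = truth.gmax_nS * boltzmann(vm, truth.v_half_mV, truth.k_mV) * (
                vm - truth.e_rev_mV) * act
            vm = 0.5 * vm + 0.5 * (60.0 - (i_spec + leak) * before.rseries_MOhm * 1e-3)
        i_expected = truth.gmax_nS * boltzmann(vm, truth.v_half_mV, truth.k_mV) * (
            vm - truth.e_rev_mV) * act
        assert i_1990 == pytest.approx(i_expected, rel=1e-6)

    def test_short_trace_rejected(self):
        rec = flat_recording()
        rec.sweeps = rec.sweeps[rec.sweeps["time_ms"] < 1000.0]
        with pytest.raises(ConfigurationError, match="1990"):
            ephys.peak_current_density(rec)


class TestGVFromTails:
    def test_ohms_law_correction_example(self, clean_pair):
        # V_cmd 60 mV, 5 nA step, 4 MOhm -> 40 mV corrected
        _, _, before, after = clean_pair
        diff, _ = ephys.blocker_subtract(before, after)
        n = len(diff.test_potentials())
        steps = np.zeros(n)
        steps[-1] = 5000.0  # pA
        gv = ephys.gv_from_tails(diff, rseries_MOhm=4.0, step_currents_pA=steps)
        assert gv["v_corr_mV"].iloc[-1] == pytest.approx(40.0)

    def test_zero_rseries_correction_is_identity(self, clean_pair):
        _, _, before, after = clean_pair
        diff, _ = ephys.blocker_subtract(before, after)
        gv = ephys.gv_from_tails(diff, rseries_MOhm=0.0)
        assert np.array_equal(gv["v_corr_mV"].to_numpy(), gv["v_test_mV"].to_numpy())

    def test_max_normalized_conductance_is_one(self, clean_pair):
        _, _, before, after = clean_pair
        diff, _ = ephys.blocker_subtract(before, after)
        gv = ephys.gv_from_tails(diff)
        assert gv["g_norm"].max() == pytest.approx(1.0)

    def test_no_activation_raises(self):
        rec = flat_recording(i_pA=0.0)
        with pytest.raises(Exception, match="no activation"):
            ephys.gv_from_tails(rec)


class TestBoltzmannFit:
    def test_noiseless_recovery_to_1e6(self):
        v = np.arange(-80.0, 61.0, 10.0)
        g = boltzmann(v, -10.0, 12.0)
        points = pd.DataFrame({"v_corr_mV": v, "g_norm": g / g.max()})
        fit = ephys.fit_boltzmann(points)
        assert fit.v_half_mV == pytest.approx(-10.0, abs=1e-6)
        assert fit.k_mV == pytest.approx(12.0, abs=1e-6)

    def test_half_activation_at_v_half(self):
        v = np.arange(-80.0, 61.0, 10.0)
        points = pd.DataFrame({"v_corr_mV": v, "g_norm": boltzmann(v, 5.0, 9.0)})
        fit = ephys.fit_boltzmann(points)
        assert fit.predict(fit.v_half_mV) == pytest.approx(0.5)

    def test_non_sigmoidal_data_rejected(self):
        points = pd.DataFrame({"v_corr_mV": np.linspace(-80, 60, 10),
                               "g_norm": np.full(10, 0.5)})
        with pytest.raises(Exception, match="non-sigmoidal"):
            ephys.fit_boltzmann(points)


class TestParameterRecovery:
    def test_vhalf_and_slope_recovered_across_noisy_cells(self):
        truth = GVTruth()
        proto = SweepProtocol(dt_ms=5.0)
        vh_err, k_err = [], []
        for i in range(20):
            before, after = simulate_sweeps(
                proto, truth, rseries_MOhm=4.0, noise_sd_pA=8.0,
                cell_id=f"cell-{i:02d}", seed=100 + i,
            )
            res = ephys.analyze_cell(before, after)
            assert res["qc_pass"] and res["blocker_sensitive"]
            vh_err.append(abs(res["v_half_mV"] - truth.v_half_mV))
            k_err.append(abs(res["k_mV"] - truth.k_mV) / truth.k_mV)
        assert np.median(vh_err) < 2.0
        assert np.median(k_err) < 0.15
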