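"""Flow-cytometry pipeline: compensation, gating, TE, normalization."""

import numpy as np
import pandas as pd
import pytest

from traffickit import flow
from traffickit.errors import ConfigurationError, IntegrityError
from traffickit.flow import TraffickingResult
from traffickit.simulate import FlowSimConfig, simulate_flow_experiment


def events(surface, internal, reporter=None):
    n = len(surface)
    return pd.DataFrame(
        {"event_id": range(n),
         "reporter": reporter if reporter is not None else np.full(n, 1000.0),
         "ch_surface": surface, "ch_internal": internal}
    )


class TestCompensation:
    def test_identity_spillover_leaves_events_unchanged(self):
        ev = events([10.0, 20.0], [5.0, 6.0])
        out = flow.compensate(ev, np.eye(2))
        assert np.allclose(out[["ch_surface", "ch_internal"]], ev[["ch_surface", "ch_internal"]])

    def test_two_by_two_linear_solve_example(self):
        # S = [[1, 0.1], [0.05, 1]]; observed (100.5, 20) -> true (100, 10)
        S = np.array([[1.0, 0.1], [0.05, 1.0]])
        out = flow.compensate(events([100.5], [20.0]), S)
        assert out["ch_surface"].iloc[0] == pytest.approx(100.0)
        assert out["ch_internal"].iloc[0] == pytest.approx(10.0)

    def test_round_trip_recovers_inputs(self):
        rng = np.random.default_rng(0)
        true = rng.lognormal(5, 0.5, (200, 2))
        S = np.array([[1.0, 0.08], [0.03, 1.0]])
        observed = true @ S
        out = flow.compensate(events(observed[:, 0], observed[:, 1]), S)
        rel = np.abs(out[["ch_surface", "ch_internal"]].to_numpy() - true) / true
        assert rel.max() < 1e-9

    def test_linearity(self):
        S = np.array([[1.0, 0.1], [0.05, 1.0]])
        x = events([100.0, 50.0], [30.0, 10.0])
        y = events([5.0, 7.0], [2.0, 1.0])
        a = 2.5
        combo = events(a * x["ch_surface"] + y["ch_surface"],
                       a * x["ch_internal"] + y["ch_internal"])
        lhs = flow.compensate(combo, S)[["ch_surface", "ch_internal"]].to_numpy()
        rhs = (a * flow.compensate(x, S)[["ch_surface", "ch_internal"]].to_numpy()
               + flow.compensate(y, S)[["ch_surface", "ch_internal"]].to_numpy())
        assert np.allclose(lhs, rhs)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ConfigurationError, match="ch_surface"):
            flow.compensate(events([1.0], [1.0]), np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_spillover_estimated_from_single_color_controls(self, flow_experiment):
        cfg, exp = flow_experiment
        ctrls = exp.controls[exp.controls["replicate"] == 1]
        byname = {name: g for name, g in ctrls.groupby("control")}
        S = flow.estimate_spillover(
            {"ch_surface": byname["single_color_surface"],
             "ch_internal": byname["single_color_internal"]},
            byname["unstained"],
        )
        truth = np.asarray(cfg.spillover)
        assert np.allclose(S, truth, atol=0.01)

    def test_pure_controls_give_identity(self):
        single = {
            "ch_surface": events([1000.0] * 50, [0.0] * 50),
            "ch_internal": events([0.0] * 50, [1000.0] * 50),
        }
        S = flow.estimate_spillover(single, events([0.0] * 50, [0.0] * 50))
        assert np.allclose(S, np.eye(2))

    def test_uninformative_control_rejected(self):
        single = {
            "ch_surface": events([1.0] * 10, [0.0] * 10),
            "ch_internal": events([0.0] * 10, [1000.0] * 10),
        }
        with pytest.raises(ConfigurationError, match="uninformative"):
            flow.estimate_spillover(single, events([5.0] * 10, [0.0] * 10))


class TestGating:
    def test_gated_fraction_matches_planted(self, flow_experiment):
        cfg, exp = flow_experiment
        sample = exp.samples[exp.samples["sample_id"] == "vehicle-r1"]
        unstained = exp.controls[exp.controls["sample_id"] == "unstained-r1"]
        gated = flow.gate_reporter_positive(sample, unstained)
        frac = len(gated) / len(sample)
        # binomial sd at n = 2500, p = 0.85 is ~0.007
        assert abs(frac - cfg.reporter_pos_fraction) < 0.03

    def test_empty_gate_raises(self):
        neg = events([0.0] * 100, [0.0] * 100, reporter=np.full(100, 1000.0))
        dim = events([0.0] * 10, [0.0] * 10, reporter=np.full(10, 1.0))
        with pytest.raises(IntegrityError, match="reporter-positive"):
            flow.gate_reporter_positive(dim, neg)


class TestTraffickingMetrics:
    def background(self):
        return events([0.0] * 50, [0.0] * 50)

    def test_all_surface_limit_gives_te_1(self):
        r = flow.trafficking_metrics(events([100.0] * 50, [0.0] * 50),
                                     self.background(), brightness_factor=0.8)
        assert r.trafficking_efficiency == pytest.approx(1.0)

    def test_symmetric_split_gives_te_half(self):
        # S_corr = b * I_corr -> TE = 0.5
        r = flow.trafficking_metrics(events([80.0] * 50, [100.0] * 50),
                                     self.background(), brightness_factor=0.8)
        assert r.trafficking_efficiency == pytest.approx(0.5)

    def test_te_scale_invariance_and_bounds(self):
        rng = np.random.default_rng(1)
        s = rng.lognormal(5, 0.4, 500)
        i = rng.lognormal(6, 0.4, 500)
        for gain in (1.0, 7.3):
            r = flow.trafficking_metrics(events(gain * s, gain * i),
                                         self.background(), brightness_factor=0.8)
            assert 0.0 <= r.trafficking_efficiency <= 1.0
        r1 = flow.trafficking_metrics(events(s, i), self.background(), 0.8)
        r2 = flow.trafficking_metrics(events(10 * s, 10 * i), self.background(), 0.8)
        assert r1.trafficking_efficiency == pytest.approx(r2.trafficking_efficiency)

    def test_negative_corrected_signals_clipped(self):
        bg = events([50.0] * 50, [0.0] * 50)
        r = flow.trafficking_metrics(events([10.0] * 50, [100.0] * 50), bg, 1.0)
        assert r.s_corr == 0.0 and r.n_clipped == 1
        assert r.trafficking_efficiency == 0.0

    def test_zero_total_flags_undefined_te(self):
        r = TraffickingResult("s", 0.0, 0.0, 1.0, 10)
        with pytest.raises(IntegrityError):
            _ = r.trafficking_efficiency


class TestNormalization:
    def make(self, s, i, b=1.0):
        return TraffickingResult("x", s, i, b, 100)

    def test_treated_equals_vehicle_gives_100(self):
        pct = flow.normalize_to_control(self.make(50, 50), self.make(50, 50))
        assert pct == pytest.approx({"surface_pct": 100.0, "total_pct": 100.0, "te_pct": 100.0})

    def test_25_percent_increase(self):
        pct = flow.normalize_to_control(self.make(125, 100), self.make(100, 100))
        assert pct["surface_pct"] == pytest.approx(125.0)

    def test_decrease_arithmetic(self):
        pct = flow.normalize_to_control(self.make(150, 100), self.make(200, 100))
        assert pct["surface_pct"] == pytest.approx(75.0)

    def test_zero_vehicle_raises(self):
        with pytest.raises(IntegrityError):
            flow.normalize_to_control(self.make(10, 10), self.make(0.0, 10))


class TestEndToEnd:
    def test_preset_effects_recovered(self, flow_experiment):
        cfg, exp = flow_experiment
        per_rep = flow.analyze_flow_experiment(exp.samples, exp.controls)
        truth = exp.truth["effect_preset"]
        recovered = {
            "surface": per_rep["surface_pct"].mean(),
            "total": per_rep["total_pct"].mean(),
            "te": per_rep["te_pct"].mean(),
        }
        assert recovered["surface"] == pytest.approx(100 * truth["surface_mult"], abs=2.0)
        assert recovered["total"] == pytest.approx(100 * truth["total_mult"], abs=1.5)
        assert recovered["te"] == pytest.approx(100 * truth["te_mult"], abs=1.5)

    def test_brightness_calibrated_from_control(self, flow_experiment):
        cfg, exp = flow_experiment
        per_rep = flow.analyze_flow_experiment(exp.samples, exp.controls)
        assert np.allclose(per_rep["brightness_factor"], cfg.brightness_factor, atol=0.02)

    def test_noise_free_recovery_is_exact(self, clean_flow_config):
        exp = simulate_flow_experiment(clean_flow_config)
        per_rep = flow.analyze_flow_experiment(
            exp.samples, exp.controls, brightness_factor=clean_flow_config.brightness_factor
        )
        assert per_rep["surface_pct"].iloc[0] == pytest.approx(100.0)
        assert per_rep["te_pct"].iloc[0] == pytest.approx(100.0)
        assert per_rep["vehicle_te"].iloc[0] == pytest.approx(
            clean_flow_config.vehicle_te()
        )
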