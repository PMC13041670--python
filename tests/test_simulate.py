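"""Generator-level tests: determinism, planted ground truth, degenerate cases."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from traffickit import plate
from traffickit.errors import ConfigurationError
from traffickit.models import boltzmann, four_pl
from traffickit.simulate import (
    CURVE_PRESETS,
    CurveSimConfig,
    FlowSimConfig,
    GVTruth,
    PlantedEffect,
    ScreenSimConfig,
    SweepProtocol,
    simulate_curve,
    simulate_flow_experiment,
    simulate_screen,
    simulate_sweeps,
)
from traffickit.simulate.curves import preset_config
from traffickit.simulate.screen import well_labels_384


class TestScreenGenerator:
    def test_deterministic_given_seed(self):
        cfg = ScreenSimConfig(n_plates=1, seed=5)
        a = simulate_screen(cfg)
        b = simulate_screen(cfg)
        for x, y in zip(a, b):
            pdt.assert_frame_equal(x, y)

    def test_well_labels_are_A1_to_P24(self):
        labels = well_labels_384()
        assert len(labels) == 384
        assert labels[0] == "A1" and labels[-1] == "P24"

    def test_no_noise_no_hits_gives_identical_compound_wells(self):
        cfg = ScreenSimConfig(
            n_plates=1, seed=0, cell_level_cv=0.0, plate_effect_sd=0.0,
            n_cells_mean=50, n_cells_dispersion=None,
        )
        # fix cell counts by replacing the Poisson draw's effect: with zero CV
        # every cell in a well is identical, so well means are exact
        cells, pm, _ = simulate_screen(cfg)
        wells = plate.summarize_wells(cells, pm, min_cells=1)
        comp = wells[wells["role"] == "compound"]
        assert comp["mean_surface"].nunique() == 1
        assert comp["mean_total"].nunique() == 1

    def test_positive_controls_sit_below_negative_controls(self, small_screen):
        _, cells, pm, _ = small_screen
        wells = plate.summarize_wells(cells, pm, min_cells=1)
        by_role = wells.groupby("role")[["mean_surface", "mean_total"]].mean()
        assert by_role.loc["e115g_pos", "mean_surface"] < by_role.loc["dmso_neg", "mean_surface"]
        assert by_role.loc["e115g_pos", "mean_total"] < by_role.loc["dmso_neg", "mean_total"]

    def test_planted_10mad_hit_scores_above_3(self, small_screen, robust_z_oracle):
        _, cells, pm, truth = small_screen
        wells = plate.summarize_wells(cells, pm, min_cells=1)
        p1 = wells[(wells["plate_id"] == "P001") & (wells["role"] == "compound")]
        values = p1.set_index("compound_id")["mean_surface"]
        z = robust_z_oracle(values.to_numpy(), values["C001-A3"])
        assert z > 3

    def test_plate_layout_completeness(self, small_screen):
        _, cells, pm, _ = small_screen
        in_cells = set(map(tuple, cells[["plate_id", "well"]].drop_duplicates().to_numpy()))
        in_map = set(map(tuple, pm[["plate_id", "well"]].to_numpy()))
        assert in_cells <= in_map
        # Poisson(120) makes empty wells vanishingly rare
        assert in_map == in_cells

    @pytest.mark.parametrize(
        "bad",
        [
            dict(control_layout={"Z99": "dmso_neg"}),
            dict(baseline_surface=-5.0),
            dict(planted_hits=(PlantedEffect("NOPE", "surface", factor=2.0),)),
            dict(toxic_compounds={"NOPE": 0.5}),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            simulate_screen(ScreenSimConfig(n_plates=1, **bad))

    def test_planted_effect_needs_exactly_one_size(self):
        with pytest.raises(ConfigurationError):
            PlantedEffect("C001-A3", "surface")
        with pytest.raises(ConfigurationError):
            PlantedEffect("C001-A3", "surface", factor=2.0, mad_units=5.0)


class TestFlowGenerator:
    def test_default_event_count_is_2500(self):
        assert FlowSimConfig().n_events == 2500

    def test_deterministic_given_seed(self):
        cfg = FlowSimConfig(n_events=200, n_replicates=2, seed=9)
        a = simulate_flow_experiment(cfg)
        b = simulate_flow_experiment(cfg)
        pdt.assert_frame_equal(a.samples, b.samples)
        pdt.assert_frame_equal(a.controls, b.controls)

    def test_clean_config_events_equal_true_signals(self, clean_flow_config):
        exp = simulate_flow_experiment(clean_flow_config)
        vehicle = exp.samples[exp.samples["condition"] == "vehicle"]
        assert np.allclose(vehicle["ch_surface"], exp.truth["vehicle"]["surface"])
        assert np.allclose(vehicle["ch_internal"], exp.truth["vehicle"]["internal"])

    def test_degenerate_spillover_rejected(self):
        with pytest.raises(ConfigurationError):
            FlowSimConfig(spillover=((1.0, 1.0), (1.0, 1.0))).validate()

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_flow_experiment(FlowSimConfig(effect_preset="mystery"))

    def test_te_effect_is_surface_over_total(self):
        cfg = FlowSimConfig()
        eff = cfg.effect()
        assert eff.te_mult == pytest.approx(eff.surface_mult / eff.total_mult)
        t = cfg.vehicle_te()
        tr = simulate_flow_experiment(FlowSimConfig(n_events=10, n_replicates=1)).truth
        assert tr["treated"]["te"] == pytest.approx(t * eff.te_mult)


class TestCurveGenerator:
    def test_noiseless_values_lie_on_curve(self):
        cfg = preset_config("vu0494372-surface", n_replicates=2, noise_cv=0.0, seed=1)
        table, truth = simulate_curve(cfg)
        expected = four_pl(table["concentration_uM"], truth["bottom"], truth["top"],
                           truth["ec50"], truth["hill"])
        assert np.allclose(table["value"], expected)

    def test_surface_preset_stores_reported_ec50(self):
        assert CURVE_PRESETS["vu0494372-surface"].true_params["ec50"] == 12.8

    def test_response_at_ec50_is_midpoint(self):
        p = CURVE_PRESETS["vu0494372-trafficking"].true_params
        mid = four_pl(p["ec50"], p["bottom"], p["top"], p["ec50"], p["hill"])
        assert mid == pytest.approx(0.5 * (p["top"] + p["bottom"]))

    def test_unknown_preset_and_bad_design_rejected(self):
        with pytest.raises(ConfigurationError):
            preset_config("no-such-preset")
        with pytest.raises(ConfigurationError):
            simulate_curve(CurveSimConfig("decay", {"half_life": 7.0},
                                          design_points=[3.0, 1.0, 2.0]))

    def test_deterministic_given_seed(self):
        cfg = preset_config("wt-kcnq1-decay", n_replicates=3, noise_cv=0.1, seed=4)
        a, _ = simulate_curve(cfg)
        b, _ = simulate_curve(cfg)
        pdt.assert_frame_equal(a, b)


class TestSweepGenerator:
    def test_full_block_no_leak_gives_zero_after_traces(self):
        before, after = simulate_sweeps(
            SweepProtocol(dt_ms=10.0), GVTruth(), rseal_GOhm=np.inf,
            blocker_fraction=1.0, seed=0,
        )
        assert np.allclose(after.sweeps["i_pA"], 0.0)
        assert not np.allclose(before.sweeps["i_pA"], 0.0)

    def test_default_tail_potential_minus_30(self):
        assert SweepProtocol().v_tail_mV == -30.0

    def test_tails_reproduce_boltzmann_at_corrected_potentials(self):
        truth = GVTruth()
        proto = SweepProtocol(dt_ms=5.0)
        before, after = simulate_sweeps(proto, truth, rseries_MOhm=5.0, seed=2)
        from traffickit.ephys import blocker_subtract, gv_from_tails, _current_at

        sens, _ = blocker_subtract(before, after)
        total = np.array([
            _current_at(before.sweeps, i, 1990.0) for i in range(len(proto.v_test_mV))
        ])
        gv = gv_from_tails(sens, step_currents_pA=total)
        expected = boltzmann(gv["v_corr_mV"], truth.v_half_mV, truth.k_mV)
        expected = expected / expected.max()
        assert np.allclose(gv["g_norm"], expected, atol=1e-9)

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_sweeps(cm_pF=-1.0)
        with pytest.raises(ConfigurationError):
            simulate_sweeps(rseries_MOhm=-1.0)
        with pytest.raises(ConfigurationError):
            simulate_sweeps(blocker_fraction=0.0)
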