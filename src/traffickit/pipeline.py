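"""End-to-end orchestration of the synthetic screen analysis.

``run_pipeline`` drives every stage on generated data -- primary screen with
robust z-scoring, QC and hit calling, replicate confirmation and
counter-screen funnel, flow-cytometry effect quantification, dose-response
EC50 fits, mechanism assays, and patch-clamp G-V analysis -- and
``write_report`` renders the consolidated results as machine-readable JSON
plus a human-readable markdown summary.  All randomness flows from the
config seed; rerunning with an identical config reproduces the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from traffickit import assays, doseresponse, ephys, flow, funnel, plate
from traffickit.errors import ConfigurationError
from traffickit.simulate import (
    FlowSimConfig,
    GVTruth,
    ScreenSimConfig,
    SweepProtocol,
    simulate_flow_experiment,
    simulate_screen,
    simulate_sweeps,
)
from traffickit.simulate.curves import preset_config, simulate_curve

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline-wide thresholds and stage toggles.

    Defaults follow the assay's operating points: hit threshold tau = 3,
    confirmation in >= 2 of 3 replicates, patch-clamp QC at
    Rseal >= 0.1 GOhm and Rseries < 10 MOhm.
    """

    seed: int = 0
    tau: float = 3.0
    confirm_k: int = 2
    confirm_n: int = 3
    min_cells: int = 20
    run_screen: bool = True
    run_flow: bool = True
    run_dose: bool = True
    run_assays: bool = True
    run_ephys: bool = True
    screen: ScreenSimConfig = field(default_factory=ScreenSimConfig)
    flow: FlowSimConfig = field(default_factory=FlowSimConfig)
    dose_presets: tuple[str, ...] = (
        "vu0494372-surface", "vu0494372-total", "vu0494372-trafficking"
    )
    dose_constraints: dict = field(
        default_factory=lambda: {
            "vu0494372-total": {"top": 130.0},
            "vu0494372-trafficking": {"top": 145.0},
        }
    )
    n_ephys_cells: int = 8

    def validate(self) -> None:
        if self.confirm_k > self.confirm_n:
            raise ConfigurationError("confirm_k cannot exceed confirm_n")
        if self.tau <= 0:
            raise ConfigurationError("tau must be > 0")


def _screen_zscores(cfg: ScreenSimConfig, min_cells: int):
    cells, plate_map, truth = simulate_screen(cfg)
    wells = plate.summarize_wells(cells, plate_map, min_cells=min_cells)
    z = plate.robust_z_scores(wells)
    qc = plate.plate_qc(wells, zscores=z)
    return wells, z, qc, truth


def run_screen_stage(config: PipelineConfig) -> dict:
    """Primary screen, replicate confirmation, counter-screen, funnel."""
    cfg = config.screen
    cfg.seed = config.seed
    wells, z, qc, truth = _screen_zscores(cfg, config.min_cells)
    calls = plate.call_hits(z, plate.HitThresholds(tau=config.tau), qc=qc)
    hits = calls[calls["is_hit"]]

    n_compounds = int((calls["compound_id"] != "").sum())
    primary = funnel.FunnelStage(
        name="primary_screen",
        rule=f"|robust z| > {config.tau} on >= 1 metric, not toxic",
        dispositions=pd.DataFrame(
            {"compound_id": calls["compound_id"],
             "kept": calls["is_hit"],
             "reason": np.where(
                 calls["is_hit"], "hit",
                 np.where(calls["is_toxic"], "toxic", "inactive")
             )}
        ),
    )

    # biological replicates of the hits: same layout and planted truth, fresh
    # noise per replicate
    from dataclasses import replace as dc_replace

    rep_frames = []
    for rep in range(1, config.confirm_n + 1):
        rep_cfg = dc_replace(cfg, seed=cfg.seed + 1000 * rep)
        _, z_rep, qc_rep, _ = _screen_zscores(rep_cfg, config.min_cells)
        calls_rep = plate.call_hits(z_rep, plate.HitThresholds(tau=config.tau), qc=qc_rep)
        sub = calls_rep[calls_rep["compound_id"].isin(hits["compound_id"])].copy()
        sub["replicate"] = rep
        rep_frames.append(sub)
    replicate_calls = pd.concat(rep_frames, ignore_index=True) if rep_frames else pd.DataFrame(
        columns=["compound_id", "replicate", "z_surface", "z_total", "z_ratio"]
    )
    confirm = funnel.confirm_hits(
        replicate_calls, tau=config.tau, k=config.confirm_k, n=config.confirm_n
    )
    confirmed = confirm.dispositions.loc[confirm.dispositions["kept"], "compound_id"].tolist()

    # counter-screen on the unrelated-protein line: null screen (no planted
    # effects) sharing the layout
    counter_cfg = dc_replace(cfg, planted_hits=(), toxic_compounds={}, seed=cfg.seed + 777)
    _, z_cs, _, _ = _screen_zscores(counter_cfg, config.min_cells)
    counter = funnel.counter_screen_filter(
        confirmed,
        z_cs[z_cs["role"] == plate.ROLE_COMPOUND][
            ["compound_id", "z_surface", "z_total", "z_ratio"]
        ],
        tau=config.tau,
    )

    report = funnel.funnel_report([primary, confirm, counter], library_size=n_compounds)
    return {
        "wells": wells, "zscores": z, "plate_qc": qc, "hit_calls": calls,
        "truth": truth, "funnel_stages": [primary, confirm, counter],
        "funnel_report": report,
        "hit_rate_pct": funnel.hit_rate_percent(len(hits), n_compounds),
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the configured stages end to end; optionally write artifacts."""
    config.validate()
    results: dict = {"config": {"seed": config.seed, "tau": config.tau}}

    if config.run_screen:
        results["screen"] = run_screen_stage(config)

    if config.run_flow:
        fcfg = config.flow
        fcfg.seed = config.seed
        exp = simulate_flow_experiment(fcfg)
        per_rep = flow.analyze_flow_experiment(exp.samples, exp.controls)
        results["flow"] = {
            "per_replicate": per_rep,
            "effects_pct": {
                "surface": float(per_rep["surface_pct"].mean() - 100.0),
                "total": float(per_rep["total_pct"].mean() - 100.0),
                "te": float(per_rep["te_pct"].mean() - 100.0),
            },
            "truth": exp.truth,
        }

    if config.run_dose:
        fits = {}
        for preset in config.dose_presets:
            cfg = preset_config(preset, n_replicates=4, noise_cv=0.05, seed=config.seed)
            table, truth = simulate_curve(cfg)
            fit = doseresponse.fit_four_pl(
                table["concentration_uM"], table["value"],
                constraints=config.dose_constraints.get(preset),
                n_boot=200, seed=config.seed,
            )
            fits[preset] = {"fit": fit, "truth": truth}
        results["dose_response"] = fits

    if config.run_assays:
        chase, chase_truth = simulate_curve(
            preset_config("wt-kcnq1-decay", n_replicates=3, noise_cv=0.08, seed=config.seed)
        )
        decay = assays.fit_half_life(chase["time_h"], chase["value"])
        melt, melt_truth = simulate_curve(
            preset_config("cetsa-dmso", n_replicates=3, noise_cv=0.05, seed=config.seed)
        )
        meltfit = assays.fit_melt_curve(melt["temperature_C"], melt["value"])
        results["assays"] = {
            "half_life_h": decay.half_life_h, "half_life_truth_h": chase_truth["half_life"],
            "t_agg_C": meltfit.t_agg_C, "t_agg_truth_C": melt_truth["t_agg"],
        }

    if config.run_ephys:
        truth = GVTruth()
        fits = []
        for i in range(config.n_ephys_cells):
            before, after = simulate_sweeps(
                SweepProtocol(dt_ms=5.0), truth, noise_sd_pA=5.0,
                cell_id=f"cell-{i:03d}", seed=config.seed + i,
            )
            res = ephys.analyze_cell(before, after)
            if res.get("v_half_mV") is not None:
                fits.append(res)
        results["ephys"] = {
            "n_cells": config.n_ephys_cells,
            "n_passing": len(fits),
            "v_half_mV": float(np.median([r["v_half_mV"] for r in fits])) if fits else np.nan,
            "k_mV": float(np.median([r["k_mV"] for r in fits])) if fits else np.nan,
            "truth": {"v_half_mV": truth.v_half_mV, "k_mV": truth.k_mV},
        }

    if outdir is not None:
        write_report(results, outdir)
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(results: dict, outdir: str | Path) -> dict[str, Path]:
    """Write machine-readable JSON and a markdown summary; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"seed": results.get("config", {}).get("seed")}
    lines = ["# Screen analysis report", ""]

    if "screen" in results:
        scr = results["screen"]
        summary["hit_rate_pct"] = scr["hit_rate_pct"]
        summary["funnel"] = scr["funnel_report"].to_dict(orient="records")
        scr["funnel_report"].to_csv(outdir / "funnel.csv", index=False)
        scr["hit_calls"].to_csv(outdir / "hit_calls.csv", index=False)
        scr["plate_qc"].to_csv(outdir / "plate_qc.csv", index=False)
        lines += ["## Screening funnel", "",
                  scr["funnel_report"].to_string(index=False),
                  f"\nPrimary hit rate: {scr['hit_rate_pct']}%", ""]

    if "flow" in results:
        eff = results["flow"]["effects_pct"]
        summary["flow_effects_pct"] = eff
        results["flow"]["per_replicate"].to_csv(outdir / "flow_effects.csv", index=False)
        lines += ["## Flow trafficking effects (treated vs vehicle)", "",
                  f"surface {eff['surface']:+.1f}%, total {eff['total']:+.1f}%, "
                  f"trafficking efficiency {eff['te']:+.1f}%", ""]

    if "dose_response" in results:
        summary["ec50_uM"] = {}
        lines += ["## Dose-response EC50s", ""]
        for preset, d in results["dose_response"].items():
            fit = d["fit"]
            summary["ec50_uM"][preset] = {
                "ec50": fit.ec50, "ci": fit.ci_ec50, "truth": d["truth"]["ec50"],
            }
            ci = f" (95% CI {fit.ci_ec50[0]:.1f}-{fit.ci_ec50[1]:.1f})" if fit.ci_ec50 else ""
            lines.append(f"- {preset}: EC50 = {fit.ec50:.1f} uM{ci}")
        lines.append("")

    if "assays" in results:
        summary["assays"] = results["assays"]
        a = results["assays"]
        lines += ["## Mechanism assays", "",
                  f"half-life {a['half_life_h']:.1f} h; T_agg {a['t_agg_C']:.1f} C", ""]

    if "ephys" in results:
        e = results["ephys"]
        summary["ephys"] = {k: e[k] for k in ("n_cells", "n_passing", "v_half_mV", "k_mV")}
        lines += ["## I_Ks activation", "",
                  f"median V1/2 = {e['v_half_mV']:.1f} mV, k = {e['k_mV']:.1f} mV "
                  f"({e['n_passing']}/{e['n_cells']} cells passing)", ""]

    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(_jsonable(summary), indent=2))
    md_path = outdir / "report.md"
    md_path.write_text("\n".join(lines))
    return {"json": json_path, "markdown": md_path}
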