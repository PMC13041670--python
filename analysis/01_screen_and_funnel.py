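#!/usr/bin/env python
"""Primary screen to funnel: robust z hit calling, confirmation, specificity.

Simulates a multi-plate 384-well screen with a handful of planted trafficking
modulators and one toxic compound, scores every compound well with plate-wise
robust z-scores on the three metrics (surface, total, trafficking ratio),
applies plate QC, calls hits at |z| > 3, confirms them in 2-of-3 biological
replicates, counter-screens against an unrelated-protein line, and writes the
stage-by-stage funnel accounting.
"""

import argparse
from pathlib import Path

from traffickit import pipeline
from traffickit.simulate import PlantedEffect, ScreenSimConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/screen"))
    args = ap.parse_args()

    planted = (
        PlantedEffect("C001-B5", "surface", mad_units=8.0),
        PlantedEffect("C002-D7", "total", mad_units=6.0),
        PlantedEffect("C002-K12", "ratio", mad_units=-7.0),
        PlantedEffect("C003-F20", "surface", mad_units=5.0),
    )
    config = pipeline.PipelineConfig(
        seed=args.seed,
        screen=ScreenSimConfig(
            n_plates=3, planted_hits=planted, toxic_compounds={"C001-M9": 0.15}
        ),
        run_flow=False, run_dose=False, run_assays=False, run_ephys=False,
    )
    res = pipeline.run_screen_stage(config)

    args.outdir.mkdir(parents=True, exist_ok=True)
    res["funnel_report"].to_csv(args.outdir / "funnel.csv", index=False)
    res["hit_calls"].to_csv(args.outdir / "hit_calls.csv", index=False)
    res["plate_qc"].to_csv(args.outdir / "plate_qc.csv", index=False)
    res["truth"].to_csv(args.outdir / "planted_truth.csv", index=False)

    qc = res["plate_qc"]
    hits = res["hit_calls"].query("is_hit")
    print(f"plates passing QC: {int(qc['pass'].sum())}/{len(qc)} "
          f"(median z' = {qc['z_prime'].median():.2f})")
    print(f"primary hits: {len(hits)} of {len(res['hit_calls'])} compounds "
          f"({res['hit_rate_pct']}% hit rate)")
    print(res["funnel_report"][["stage", "input_count", "output_count", "pct_of_library"]]
          .to_string(index=False))
    planted_ids = set(res["truth"].query("kind == 'hit'")["compound_id"])
    final = res["funnel_stages"][-1].dispositions
    recovered = planted_ids & set(final.loc[final["kept"], "compound_id"])
    print(f"planted modulators recovered through the funnel: "
          f"{len(recovered)}/{len(planted_ids)}")


if __name__ == "__main__":
    main()
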