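"""Screening-funnel logic: replicate confirmation, counter-screen
specificity, and stage accounting.

Initial hits are re-tested in biological replicates and confirmed when the
same metric crosses the z threshold in the same direction in at least k of n
replicates; confirmed hits are then counter-screened against an unrelated
membrane protein and excluded as nonspecific when they move any metric of
that protein beyond the same threshold.  Every compound receives exactly one
disposition per stage so the funnel is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traffickit.errors import ConfigurationError, IntegrityError

METRICS = ("surface", "total", "ratio")


@dataclass
class FunnelStage:
    """One funnel stage with its rule and per-compound dispositions."""

    name: str
    rule: str
    dispositions: pd.DataFrame  # columns: compound_id, kept (bool), reason

    @property
    def input_count(self) -> int:
        return len(self.dispositions)

    @property
    def output_count(self) -> int:
        return int(self.dispositions["kept"].sum())


# ---------------------------------------------------------------------------
# Confirmation
# ---------------------------------------------------------------------------

def confirm_hits(
    replicate_calls: pd.DataFrame,
    tau: float = 3.0,
    k: int = 2,
    n: int = 3,
    metrics: tuple[str, ...] = METRICS,
) -> FunnelStage:
    """Confirm hits across biological replicates.

    ``replicate_calls`` needs columns ``compound_id, replicate`` and
    ``z_<metric>`` columns.  A compound is confirmed iff some metric crosses
    |z| > tau *in the same direction* in >= k of the n replicates; missing
    replicates count as failures (the denominator stays n).
    """
    if k > n:
        raise ConfigurationError(f"k = {k} cannot exceed n = {n}")
    rows = []
    for cid, grp in replicate_calls.groupby("compound_id", sort=True):
        if len(grp) > n:
            raise ConfigurationError(f"{cid}: more than n = {n} replicates supplied")
        confirmed_metrics = []
        for m in metrics:
            z = grp[f"z_{m}"].to_numpy(dtype=float)
            z = z[~np.isnan(z)]
            if (z > tau).sum() >= k:
                confirmed_metrics.append(f"{m}:up")
            elif (z < -tau).sum() >= k:
                confirmed_metrics.append(f"{m}:down")
        kept = bool(confirmed_metrics)
        rows.append(
            {"compound_id": cid, "kept": kept,
             "reason": ",".join(confirmed_metrics) if kept else "not-reproducible"}
        )
    return FunnelStage(
        name="confirmation",
        rule=f"|z| > {tau} same metric/direction in >= {k} of {n} replicates",
        dispositions=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Counter-screen
# ---------------------------------------------------------------------------

def counter_screen_filter(
    confirmed: list[str],
    counterscreen_z: pd.DataFrame,
    tau: float = 3.0,
    metrics: tuple[str, ...] = METRICS,
) -> FunnelStage:
    """Drop compounds that also move the unrelated counter-screen protein.

    ``counterscreen_z`` needs ``compound_id`` and ``z_<metric>`` columns for
    the unrelated-protein line.  A compound is retained iff |z| <= tau on all
    metrics there; compounds without counter-screen data are carried forward
    flagged ``untested`` (never silently treated as specific).
    """
    cz = counterscreen_z.set_index("compound_id")
    rows = []
    for cid in confirmed:
        if cid not in cz.index:
            rows.append({"compound_id": cid, "kept": True, "reason": "untested"})
            continue
        offending = [
            m for m in metrics
            if abs(float(cz.loc[cid, f"z_{m}"])) > tau
        ]
        if offending:
            rows.append(
                {"compound_id": cid, "kept": False,
                 "reason": "nonspecific:" + ",".join(offending)}
            )
        else:
            rows.append({"compound_id": cid, "kept": True, "reason": "specific"})
    return FunnelStage(
        name="counter_screen",
        rule=f"retained iff counter-screen |z| <= {tau} on all metrics",
        dispositions=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def hit_rate_percent(n_hits: int, n_screened: int, decimals: int = 1) -> float:
    """Hit rate as a percentage of the screened library, rounded."""
    if n_screened <= 0:
        raise ConfigurationError("library size must be > 0")
    if n_hits < 0 or n_hits > n_screened:
        raise IntegrityError("hit count outside [0, library size]")
    return round(100.0 * n_hits / n_screened, decimals)


def funnel_report(stages: list[FunnelStage], library_size: int | None = None) -> pd.DataFrame:
    """Stage-by-stage accounting with percentages of the initial library.

    Counts must narrow monotonically (each stage's input equals the previous
    stage's output); violations raise an integrity error.
    """
    if not stages:
        raise ConfigurationError("at least one funnel stage required")
    lib = library_size if library_size is not None else stages[0].input_count
    rows = []
    prev_out = None
    for stage in stages:
        if stage.output_count > stage.input_count:
            raise IntegrityError(f"stage {stage.name}: output exceeds input")
        if prev_out is not None and stage.input_count > prev_out:
            raise IntegrityError(
                f"stage {stage.name}: input {stage.input_count} exceeds prior output {prev_out}"
            )
        rows.append(
            {"stage": stage.name, "rule": stage.rule,
             "input_count": stage.input_count, "output_count": stage.output_count,
             "pct_of_library": hit_rate_percent(stage.output_count, lib)}
        )
        prev_out = stage.output_count
    return pd.DataFrame(rows)
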