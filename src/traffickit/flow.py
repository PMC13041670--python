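"""Flow-cytometry trafficking quantification.

Processing order mirrors the bench workflow: estimate spillover from
single-color controls, compensate all samples, gate reporter-positive single
cells against a negative control, compute background-subtracted surface and
internal statistics, convert to total protein and trafficking efficiency with
the brightness factor, and normalize treated to vehicle within each
replicate.

Trafficking efficiency is the surface fraction of channel-corrected total
protein:

    TE = S_corr / (S_corr + b * I_corr)

where ``S_corr`` and ``I_corr`` are background-subtracted surface- and
internal-channel statistics and the brightness factor ``b`` (surface-channel
signal per epitope over internal-channel signal per epitope) places both
channels on a common scale.  Total protein is ``S_corr + b * I_corr``; the
surface antibody occupies surface epitopes before permeabilization, so the
internal stain labels only the internal pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from traffickit.errors import ConfigurationError, IntegrityError

log = logging.getLogger(__name__)

CHANNELS = ("ch_surface", "ch_internal")


# ---------------------------------------------------------------------------
# Compensation
# ---------------------------------------------------------------------------

def estimate_spillover(
    single_color_controls: dict[str, pd.DataFrame],
    unstained: pd.DataFrame,
    channels: tuple[str, ...] = CHANNELS,
) -> np.ndarray:
    """Spillover matrix from single-color controls.

    ``single_color_controls[ch]`` holds events stained only in channel ``ch``.
    Entry ``S[i, j]`` is the median background-subtracted off-channel (j)
    signal divided by the on-channel (i) signal, background taken from the
    unstained control; the diagonal is 1.
    """
    n = len(channels)
    bg = unstained[list(channels)].median()
    S = np.eye(n)
    for i, ch in enumerate(channels):
        if ch not in single_color_controls:
            raise ConfigurationError(f"missing single-color control for {ch!r}")
        ctrl = single_color_controls[ch]
        on = ctrl[ch].median() - bg[ch]
        if on <= 0:
            raise ConfigurationError(f"uninformative single-color control for {ch!r}")
        for j, other in enumerate(channels):
            if other == ch:
                continue
            S[i, j] = max((ctrl[other].median() - bg[other]) / on, 0.0)
    return S


def compensate(events: pd.DataFrame, spillover: np.ndarray,
               channels: tuple[str, ...] = CHANNELS) -> pd.DataFrame:
    """Invert spillover: solve ``observed = true @ S`` for the true signals."""
    S = np.asarray(spillover, dtype=float)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e8:
        raise ConfigurationError(
            f"numerically singular spillover matrix for channels {channels}"
        )
    out = events.copy()
    observed = events[list(channels)].to_numpy(dtype=float)
    true = np.linalg.solve(S.T, observed.T).T
    out[list(channels)] = true
    return out


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

def gate_reporter_positive(
    events: pd.DataFrame,
    negative_control: pd.DataFrame,
    quantile: float = 0.99,
    reporter: str = "reporter",
) -> pd.DataFrame:
    """Keep events whose reporter exceeds the negative control's quantile."""
    if not 0 < quantile < 1:
        raise ConfigurationError("quantile must be in (0, 1)")
    threshold = float(negative_control[reporter].quantile(quantile))
    gated = events[events[reporter] > threshold]
    if gated.empty:
        raise IntegrityError("no reporter-positive events above the gate")
    log.info("reporter gate at %.1f kept %d/%d events", threshold, len(gated), len(events))
    return gated


# ---------------------------------------------------------------------------
# Trafficking metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraffickingResult:
    """Per-sample corrected signals and trafficking efficiency."""

    sample_id: str
    s_corr: float
    i_corr: float
    brightness_factor: float
    n_events: int
    n_clipped: int = 0

    @property
    def total(self) -> float:
        return self.s_corr + self.brightness_factor * self.i_corr

    @property
    def trafficking_efficiency(self) -> float:
        if self.total == 0:
            raise IntegrityError(f"{self.sample_id}: TE undefined (zero corrected total)")
        return self.s_corr / self.total


def estimate_brightness(calibration_events: pd.DataFrame,
                        background_control: pd.DataFrame | None = None,
                        channels: tuple[str, ...] = CHANNELS) -> float:
    """Brightness factor from a fully-permeabilized dual-stain control.

    Both antibodies label the same epitope pool there, so the median per-event
    surface/internal signal ratio is the per-epitope brightness ratio ``b``.
    When a background-staining control is given, its per-channel medians are
    subtracted from the calibration events first.
    """
    ev = calibration_events[list(channels)]
    if background_control is not None:
        ev = ev - background_control[list(channels)].median()
    ratio = ev[channels[0]] / ev[channels[1]]
    b = float(ratio.median())
    if not np.isfinite(b) or b <= 0:
        raise ConfigurationError("uninformative brightness-calibration control")
    return b


def trafficking_metrics(
    sample: pd.DataFrame,
    background_control: pd.DataFrame,
    brightness_factor: float,
    sample_id: str = "",
    statistic: str = "median",
) -> TraffickingResult:
    """Background-subtracted surface/internal statistics and TE for a sample.

    ``sample`` must be compensated and gated; ``background_control`` must be
    compensated and processed identically apart from the reporter gate (it is
    reporter-negative by construction).  Negative corrected signals are
    clipped to zero and counted.
    """
    if statistic not in ("median", "mean"):
        raise ConfigurationError("statistic must be 'median' or 'mean'")
    stat = (lambda s: float(s.median())) if statistic == "median" else (lambda s: float(s.mean()))
    s_corr = stat(sample["ch_surface"]) - stat(background_control["ch_surface"])
    i_corr = stat(sample["ch_internal"]) - stat(background_control["ch_internal"])
    clipped = int(s_corr < 0) + int(i_corr < 0)
    if clipped:
        log.warning("%s: %d corrected signal(s) clipped to 0", sample_id, clipped)
    return TraffickingResult(
        sample_id=sample_id,
        s_corr=max(s_corr, 0.0),
        i_corr=max(i_corr, 0.0),
        brightness_factor=brightness_factor,
        n_events=len(sample),
        n_clipped=clipped,
    )


def normalize_to_control(
    treated: TraffickingResult, vehicle: TraffickingResult
) -> dict[str, float]:
    """Percent-of-control triplet (surface, total, TE), 100 = no change."""
    out = {}
    for name, t, v in (
        ("surface_pct", treated.s_corr, vehicle.s_corr),
        ("total_pct", treated.total, vehicle.total),
        ("te_pct", treated.trafficking_efficiency, vehicle.trafficking_efficiency),
    ):
        if v <= 0:
            raise IntegrityError(f"vehicle quantity for {name} is <= 0; percent undefined")
        out[name] = 100.0 * t / v
    return out


# ---------------------------------------------------------------------------
# Experiment-level pipeline
# ---------------------------------------------------------------------------

def analyze_flow_experiment(
    samples: pd.DataFrame,
    controls: pd.DataFrame,
    brightness_factor: float | None = None,
    gate_quantile: float = 0.99,
    statistic: str = "median",
) -> pd.DataFrame:
    """Run the full flow pipeline on a generated/recorded experiment.

    Expects the table layout produced by
    :func:`traffickit.simulate.simulate_flow_experiment` (a ``replicate``
    column pairing treated/vehicle samples with their per-replicate controls).
    Spillover, the reporter gate, and background statistics are derived from
    each replicate's own controls.  When ``brightness_factor`` is None it is
    calibrated from the replicate's fully-permeabilized dual-stain control.

    Returns one row per replicate with treated-vs-vehicle percent-of-control
    values for surface, total, and trafficking efficiency.
    """
    rows = []
    for rep, ctrls in controls.groupby("replicate", sort=True):
        byname = {name: grp for name, grp in ctrls.groupby("control")}
        spill = estimate_spillover(
            {"ch_surface": byname["single_color_surface"],
             "ch_internal": byname["single_color_internal"]},
            byname["unstained"],
        )
        background = compensate(byname["background_staining"], spill)
        if brightness_factor is None:
            calib = compensate(byname["brightness_calibration"], spill)
            b = estimate_brightness(calib, background)
        else:
            b = brightness_factor

        results = {}
        for condition in ("vehicle", "treated"):
            ev = samples[(samples["replicate"] == rep) & (samples["condition"] == condition)]
            ev = compensate(ev, spill)
            ev = gate_reporter_positive(ev, byname["unstained"], gate_quantile)
            results[condition] = trafficking_metrics(
                ev, background, b, sample_id=f"{condition}-r{rep}", statistic=statistic
            )
        pct = normalize_to_control(results["treated"], results["vehicle"])
        rows.append(
            {"replicate": rep, "brightness_factor": b,
             "vehicle_te": results["vehicle"].trafficking_efficiency,
             "treated_te": results["treated"].trafficking_efficiency,
             **pct}
        )
    return pd.DataFrame(rows)
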