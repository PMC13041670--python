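"""Synthetic flow-cytometry trafficking experiment with planted effects.

The generator emulates the dual-stain trafficking assay: surface protein is
labeled before permeabilization in one channel, the internal pool in a second
channel after permeabilization, and an integrated reporter marks expressing
cells.  Raw events are true per-event signals passed through a spillover
matrix, plus staining background and autofluorescence.  The standard control
set is emitted alongside every sample: unstained cells, single-color
compensation controls, a background-staining control (unexpressing cells
stained with both antibodies), and a fully-permeabilized dual-stain
calibration control for the brightness factor.

Treated-versus-vehicle effects are planted as per-event multipliers on the
surface and internal pools.  Named presets pin the (surface, total,
trafficking-efficiency) effect triple; because trafficking efficiency is the
identity ``TE = S/(S + b*I)``, the TE effect is fully determined by the
surface and total effects, so a preset stores the first two and the third is
implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traffickit._rng import substream
from traffickit.errors import ConfigurationError


@dataclass(frozen=True)
class EffectPreset:
    """Multiplicative treated-vs-vehicle effect on surface and total signal.

    ``te_mult`` is derived (``surface_mult / total_mult``) and recorded for
    reference; the internal-pool multiplier needed to realize ``total_mult``
    is computed from the vehicle composition at generation time.
    """

    surface_mult: float
    total_mult: float

    def __post_init__(self):
        if self.surface_mult <= 0 or self.total_mult <= 0:
            raise ConfigurationError("effect multipliers must be > 0")

    @property
    def te_mult(self) -> float:
        return self.surface_mult / self.total_mult


#: Named effect presets.  'vu0494372-10uM' encodes the compound's reported
#: 10 uM effect triple projected onto the closest point consistent with the
#: TE identity: +23.3% surface, +10.4% total, +11.7% trafficking efficiency.
EFFECT_PRESETS: dict[str, EffectPreset] = {
    "null": EffectPreset(1.0, 1.0),
    "vu0494372-10uM": EffectPreset(1.233128, 1.103546),
}


@dataclass
class FlowSimConfig:
    """Study conditions for the synthetic flow experiment.

    ``true_surface_mean`` / ``true_internal_mean`` are vehicle-condition mean
    channel signals (FIU) of the expressing population; ``brightness_factor``
    b is surface-channel signal per epitope divided by internal-channel signal
    per epitope, so total protein in surface-channel units is ``S + b*I``.
    ``spillover[i][j]`` is the fraction of channel-i signal read in channel j.
    """

    n_events: int = 2500
    n_replicates: int = 8
    true_surface_mean: float = 700.0
    true_internal_mean: float = 1625.0
    brightness_factor: float = 0.8
    event_cv: float = 0.30
    spillover: tuple[tuple[float, float], ...] = ((1.0, 0.06), (0.04, 1.0))
    autofluor_surface: float = 10.0
    autofluor_internal: float = 15.0
    background_surface: float = 30.0
    background_internal: float = 50.0
    background_cv: float = 0.40
    reporter_pos_fraction: float = 0.85
    reporter_pos_mean: float = 5000.0
    reporter_neg_mean: float = 25.0
    reporter_cv: float = 0.5
    replicate_batch_cv: float = 0.10
    single_color_mean: float = 2000.0
    effect_preset: str | EffectPreset = "vu0494372-10uM"
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 1:
            raise ConfigurationError("n_events must be >= 1")
        S = np.asarray(self.spillover, dtype=float)
        if S.shape != (2, 2) or not np.allclose(np.diag(S), 1.0):
            raise ConfigurationError("spillover must be 2x2 with unit diagonal")
        if np.any((S - np.diag(np.diag(S))) < 0) or np.any((S - np.diag(np.diag(S))) >= 1):
            raise ConfigurationError("off-diagonal spillover must lie in [0, 1)")
        if abs(np.linalg.det(S)) < 1e-12:
            raise ConfigurationError("singular spillover matrix")
        if not 0 < self.reporter_pos_fraction <= 1:
            raise ConfigurationError("reporter_pos_fraction must be in (0, 1]")
        if self.brightness_factor <= 0:
            raise ConfigurationError("brightness factor must be > 0")

    def effect(self) -> EffectPreset:
        if isinstance(self.effect_preset, EffectPreset):
            return self.effect_preset
        try:
            return EFFECT_PRESETS[self.effect_preset]
        except KeyError:
            raise ConfigurationError(f"unknown effect preset {self.effect_preset!r}") from None

    def vehicle_te(self) -> float:
        s, bi = self.true_surface_mean, self.brightness_factor * self.true_internal_mean
        return s / (s + bi)


@dataclass
class FlowExperiment:
    """Generated experiment: raw event tables plus planted ground truth.

    ``samples`` holds treated/vehicle events (columns ``sample_id, replicate,
    condition, event_id, reporter, ch_surface, ch_internal``); ``controls``
    holds the control samples per replicate with a ``control`` column in
    {unstained, single_color_surface, single_color_internal,
    background_staining, brightness_calibration}.
    """

    samples: pd.DataFrame
    controls: pd.DataFrame
    truth: dict


def _lognormal_mult(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-0.5 * sigma2, np.sqrt(sigma2), size)


def _raw_events(rng, cfg: FlowSimConfig, true_s, true_i, reporter, stained: bool) -> pd.DataFrame:
    """Apply spillover, staining background, and autofluorescence."""
    S = np.asarray(cfg.spillover, dtype=float)
    true = np.column_stack([true_s, true_i])
    observed = true @ S
    n = len(true_s)
    bg_s = cfg.autofluor_surface + (cfg.background_surface if stained else 0.0)
    bg_i = cfg.autofluor_internal + (cfg.background_internal if stained else 0.0)
    observed[:, 0] += bg_s * _lognormal_mult(rng, cfg.background_cv, n)
    observed[:, 1] += bg_i * _lognormal_mult(rng, cfg.background_cv, n)
    return pd.DataFrame(
        {"event_id": np.arange(n), "reporter": reporter,
         "ch_surface": observed[:, 0], "ch_internal": observed[:, 1]}
    )


def simulate_flow_experiment(config: FlowSimConfig) -> FlowExperiment:
    """Generate paired treated/vehicle samples plus the full control set.

    The expressing (reporter-positive) population carries log-normal per-event
    surface and internal signals; reporter-negative events carry background
    only.  A per-replicate staining-batch factor multiplies both channels of
    every sample in the replicate (it cancels in within-replicate
    normalization, as in the real assay).  Ground truth records the planted
    per-replicate effect multipliers, the spillover matrix, and the brightness
    factor.
    """
    config.validate()
    eff = config.effect()
    b = config.brightness_factor
    s_v, i_v = config.true_surface_mean, config.true_internal_mean
    total_v = s_v + b * i_v
    # internal-pool multiplier that realizes the preset's total effect
    beta = (eff.total_mult * total_v - eff.surface_mult * s_v) / (b * i_v)
    if beta <= 0:
        raise ConfigurationError("effect preset implies a non-positive internal pool")

    sample_frames = []
    control_frames = []
    for rep in range(1, config.n_replicates + 1):
        brng = substream(config.seed, "flow", "batch", rep)
        batch = float(_lognormal_mult(brng, config.replicate_batch_cv, ()))
        for condition, s_mult, i_mult in (
            ("vehicle", 1.0, 1.0),
            ("treated", eff.surface_mult, beta),
        ):
            rng = substream(config.seed, "flow", condition, rep)
            n = config.n_events
            pos = rng.random(n) < config.reporter_pos_fraction
            ls = _lognormal_mult(rng, config.event_cv, n)
            li = _lognormal_mult(rng, config.event_cv, n)
            true_s = np.where(pos, s_v * s_mult * ls * batch, 0.0)
            true_i = np.where(pos, i_v * i_mult * li * batch, 0.0)
            reporter = np.where(
                pos,
                config.reporter_pos_mean * _lognormal_mult(rng, config.reporter_cv, n),
                config.reporter_neg_mean * _lognormal_mult(rng, config.reporter_cv, n),
            )
            ev = _raw_events(rng, config, true_s, true_i, reporter, stained=True)
            ev.insert(0, "condition", condition)
            ev.insert(0, "replicate", rep)
            ev.insert(0, "sample_id", f"{condition}-r{rep}")
            sample_frames.append(ev)

        for control, maker in _control_makers(config, batch).items():
            rng = substream(config.seed, "flow", control, rep)
            ev = maker(rng)
            ev.insert(0, "control", control)
            ev.insert(0, "replicate", rep)
            ev.insert(0, "sample_id", f"{control}-r{rep}")
            control_frames.append(ev)

    te_v = config.vehicle_te()
    truth = {
        "effect_preset": {
            "surface_mult": eff.surface_mult,
            "total_mult": eff.total_mult,
            "te_mult": eff.te_mult,
            "internal_mult": beta,
        },
        "vehicle": {"surface": s_v, "internal": i_v, "total": total_v, "te": te_v},
        "treated": {
            "surface": s_v * eff.surface_mult,
            "internal": i_v * beta,
            "total": total_v * eff.total_mult,
            "te": te_v * eff.te_mult,
        },
        "brightness_factor": b,
        "spillover": [list(r) for r in config.spillover],
        "reporter_pos_fraction": config.reporter_pos_fraction,
    }
    return FlowExperiment(
        samples=pd.concat(sample_frames, ignore_index=True),
        controls=pd.concat(control_frames, ignore_index=True),
        truth=truth,
    )


def _control_makers(cfg: FlowSimConfig, batch: float):
    """Control-sample generators, each taking a Generator."""
    n = cfg.n_events
    neg_reporter = lambda rng: cfg.reporter_neg_mean * _lognormal_mult(rng, cfg.reporter_cv, n)

    def unstained(rng):
        return _raw_events(rng, cfg, np.zeros(n), np.zeros(n), neg_reporter(rng), stained=False)

    def single_color_surface(rng):
        sig = cfg.single_color_mean * _lognormal_mult(rng, cfg.event_cv, n) * batch
        return _raw_events(rng, cfg, sig, np.zeros(n), neg_reporter(rng), stained=False)

    def single_color_internal(rng):
        sig = cfg.single_color_mean * _lognormal_mult(rng, cfg.event_cv, n) * batch
        return _raw_events(rng, cfg, np.zeros(n), sig, neg_reporter(rng), stained=False)

    def background_staining(rng):
        # unexpressing cells stained with both antibodies: background only
        return _raw_events(rng, cfg, np.zeros(n), np.zeros(n), neg_reporter(rng), stained=True)

    def brightness_calibration(rng):
        # fully-permeabilized dual stain: both antibodies see the same epitope
        # pool, so per-event channel ratio equals the brightness factor b
        pool = (cfg.true_surface_mean / cfg.brightness_factor + cfg.true_internal_mean)
        li = pool * _lognormal_mult(rng, cfg.event_cv, n) * batch
        ls = cfg.brightness_factor * li
        reporter = cfg.reporter_pos_mean * _lognormal_mult(rng, cfg.reporter_cv, n)
        return _raw_events(rng, cfg, ls, li, reporter, stained=True)

    return {
        "unstained": unstained,
        "single_color_surface": single_color_surface,
        "single_color_internal": single_color_internal,
        "background_staining": background_staining,
        "brightness_calibration": brightness_calibration,
    }
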