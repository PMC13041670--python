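"""Synthetic dose-response, decay, and melt measurement tables.

Values are drawn as ``closed-form mean * (1 + noise_cv * N(0,1))`` at the
configured design points.  Named presets pin the ground-truth parameters of
the compound's characterized curves: the three dose-response presets store
the reported EC50s (12.8 / 11.3 / 15.4 uM for surface, total, and trafficking
efficiency), and the decay preset stores the ~7 h protein half-life.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from traffickit._rng import substream
from traffickit.errors import ConfigurationError
from traffickit.models import boltzmann, exp_decay, four_pl, melt_sigmoid

_XCOL = {
    "dose_response": "concentration_uM",
    "decay": "time_h",
    "melt": "temperature_C",
    "gv_tails": "voltage_mV",
}


def _default_design(kind: str) -> np.ndarray:
    if kind == "dose_response":
        return np.logspace(0, 2, 8)  # 1-100 uM
    if kind == "decay":
        return np.array([0.0, 3.0, 6.0, 9.0])  # hours
    if kind == "melt":
        return np.arange(37.0, 68.0, 4.0)  # deg C
    if kind == "gv_tails":
        return np.arange(-80.0, 61.0, 10.0)  # mV
    raise ConfigurationError(f"unknown curve kind {kind!r}")


@dataclass
class CurveSimConfig:
    """One synthetic measurement series from a closed-form truth."""

    kind: str
    true_params: dict = field(default_factory=dict)
    design_points: np.ndarray | None = None
    n_replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in _XCOL:
            raise ConfigurationError(f"unknown curve kind {self.kind!r}")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        x = self.design()
        if len(x) < 2 or np.any(np.diff(x) <= 0):
            raise ConfigurationError("design points must be strictly increasing")

    def design(self) -> np.ndarray:
        if self.design_points is None:
            return _default_design(self.kind)
        return np.asarray(self.design_points, dtype=float)

    def mean_curve(self, x: np.ndarray) -> np.ndarray:
        p = self.true_params
        if self.kind == "dose_response":
            return four_pl(x, p["bottom"], p["top"], p["ec50"], p["hill"])
        if self.kind == "decay":
            return exp_decay(x, p["half_life"], p.get("amplitude", 100.0))
        if self.kind == "melt":
            return melt_sigmoid(x, p["upper"], p["lower"], p["t_agg"], p["slope"])
        return boltzmann(x, p["v_half"], p["k"], p.get("gmax", 1.0))


#: Named curve presets; the dose-response tops mirror the fitted asymptotes
#: (the total and trafficking fits were run with their tops constrained to
#: 130% and 145% of control).
CURVE_PRESETS: dict[str, CurveSimConfig] = {
    "vu0494372-surface": CurveSimConfig(
        "dose_response", {"bottom": 100.0, "top": 150.0, "ec50": 12.8, "hill": 1.5}
    ),
    "vu0494372-total": CurveSimConfig(
        "dose_response", {"bottom": 100.0, "top": 130.0, "ec50": 11.3, "hill": 1.5}
    ),
    "vu0494372-trafficking": CurveSimConfig(
        "dose_response", {"bottom": 100.0, "top": 145.0, "ec50": 15.4, "hill": 1.5}
    ),
    "wt-kcnq1-decay": CurveSimConfig("decay", {"amplitude": 100.0, "half_life": 7.0}),
    "cetsa-dmso": CurveSimConfig(
        "melt", {"upper": 1.0, "lower": 0.05, "t_agg": 52.0, "slope": 2.5}
    ),
}


def preset_config(
    name: str,
    n_replicates: int | None = None,
    noise_cv: float | None = None,
    seed: int | None = None,
    design_points=None,
) -> CurveSimConfig:
    """A copy of a named preset with overridden sampling conditions."""
    try:
        base = CURVE_PRESETS[name]
    except KeyError:
        raise ConfigurationError(f"unknown preset {name!r}") from None
    cfg = replace(base, true_params=dict(base.true_params))
    if n_replicates is not None:
        cfg.n_replicates = n_replicates
    if noise_cv is not None:
        cfg.noise_cv = noise_cv
    if seed is not None:
        cfg.seed = seed
    if design_points is not None:
        cfg.design_points = np.asarray(design_points, dtype=float)
    return cfg


def simulate_curve(config: CurveSimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a tidy measurement table ``(x, replicate, value)`` + truth.

    Deterministic given ``config.seed``; with ``noise_cv = 0`` every value
    lies exactly on the closed-form curve.
    """
    config.validate()
    x = config.design()
    mean = config.mean_curve(x)
    rng = substream(config.seed, "curve", config.kind)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        noise = rng.standard_normal(len(x)) * config.noise_cv
        values = mean * (1.0 + noise)
        for xi, vi in zip(x, values):
            rows.append({_XCOL[config.kind]: xi, "replicate": rep, "value": vi})
    table = pd.DataFrame(rows)
    truth = dict(config.true_params)
    return table, truth
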