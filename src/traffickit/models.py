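"""Closed-form curve models shared by the generators and the fitters.

All models are written in the field's standard parameterizations so fitted
parameters read directly as the quantities reported in screening and
electrophysiology work (EC50 in concentration units, half-life in hours,
T_agg in deg C, V1/2 and slope in mV).
"""

from __future__ import annotations

import numpy as np

__all__ = ["four_pl", "exp_decay", "melt_sigmoid", "boltzmann"]

LN2 = float(np.log(2.0))


def four_pl(conc, bottom: float, top: float, ec50: float, hill: float):
    """Four-parameter logistic dose-response curve.

    ``response = bottom + (top - bottom) / (1 + (ec50/conc)**hill)``;
    at ``conc == ec50`` the response is the midpoint of the asymptotes.
    """
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill)


def exp_decay(t, half_life: float, amplitude: float = 100.0):
    """Single-exponential decay, parameterized by half-life.

    ``y = amplitude * exp(-ln2 * t / half_life)``; the default amplitude of
    100 matches percent-remaining data normalized to the t = 0 point.
    """
    t = np.asarray(t, dtype=float)
    return amplitude * np.exp(-LN2 * t / half_life)


def melt_sigmoid(temperature, upper: float, lower: float, t_agg: float, slope: float):
    """Two-plateau thermal-aggregation melt curve (decreasing sigmoid).

    ``y = lower + (upper - lower) / (1 + exp((T - t_agg)/slope))``; the
    inflection point ``t_agg`` is the aggregation temperature.
    """
    temperature = np.asarray(temperature, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp((temperature - t_agg) / slope))


def boltzmann(v, v_half: float, k: float, gmax: float = 1.0):
    """Boltzmann voltage dependence of activation.

    ``G/Gmax = gmax / (1 + exp((v_half - V)/k))`` with ``v`` in mV.
    """
    v = np.asarray(v, dtype=float)
    return gmax / (1.0 + np.exp((v_half - v) / k))
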