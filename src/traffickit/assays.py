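"""Mechanism-of-action readouts.

Four small estimators used to characterize how a trafficking corrector acts:

* cycloheximide-chase half-life -- single-exponential decay fit to
  percent-remaining band intensities after translation arrest;
* CETSA melt curve -- two-plateau sigmoid in temperature whose inflection is
  the aggregation temperature T_agg;
* qPCR relative quantification -- classic delta-delta-Ct fold change against
  a reference gene (GAPDH by default), with an optional amplification
  efficiency;
* trypan-blue viability -- percent live cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from traffickit.errors import ConfigurationError, FitError
from traffickit.models import LN2, exp_decay, melt_sigmoid

__all__ = [
    "DecayFit",
    "MeltFit",
    "QpcrResult",
    "fit_half_life",
    "fit_melt_curve",
    "qpcr_fold_change",
    "viability_percent",
]


# ---------------------------------------------------------------------------
# Cycloheximide chase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayFit:
    """Exponential-decay fit; amplitude is fixed at 100% (t = 0 normalized).

    ``no_decay`` marks non-decreasing inputs, for which the rate sits at the
    zero boundary and the half-life is infinite.
    """

    rate_per_h: float
    no_decay: bool = False

    @property
    def half_life_h(self) -> float:
        if self.rate_per_h <= 0:
            return np.inf
        return LN2 / self.rate_per_h


def fit_half_life(time_h, percent_remaining) -> DecayFit:
    """Fit ``y = 100 * exp(-k t)`` to percent-remaining chase data.

    Inputs are already normalized to the loading control and to the 0-hour
    time point, so the amplitude is fixed at 100 and only the rate is free
    (with 3-4 chase time points a free amplitude is poorly identified).
    Requires >= 3 time points including t = 0.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(percent_remaining, dtype=float)
    if t.shape != y.shape:
        raise ConfigurationError("time and intensity must align")
    if len(np.unique(t)) < 3 or not np.any(t == 0):
        raise ConfigurationError(">= 3 time points including t = 0 required")

    # trend check on per-time means (replicates may be interleaved)
    means = pd.Series(y).groupby(pd.Series(t)).mean()
    if np.all(np.diff(means.to_numpy()) >= 0):
        return DecayFit(rate_per_h=0.0, no_decay=True)

    # log-linear slope through the origin as starting value
    pos = y > 0
    k0 = max(-np.polyfit(t[pos], np.log(y[pos] / 100.0), 1)[0], 1e-6)
    (k,), _ = curve_fit(lambda tt, k: exp_decay(tt, LN2 / k), t, y, p0=[k0], maxfev=10000)
    return DecayFit(rate_per_h=float(k))


# ---------------------------------------------------------------------------
# CETSA melt curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltFit:
    """Two-plateau melt fit; ``t_agg_C`` is the curve's inflection point."""

    upper: float
    lower: float
    t_agg_C: float
    slope_C: float

    def predict(self, temperature):
        return melt_sigmoid(temperature, self.upper, self.lower, self.t_agg_C, self.slope_C)


def fit_melt_curve(temperature_C, fraction_remaining) -> MeltFit:
    """Fit a decreasing two-plateau sigmoid to thermal-aggregation data.

    Requires >= 6 temperatures spanning both plateaus; monotone-increasing
    data indicate mis-oriented input (soluble fraction must fall with
    temperature) and raise a configuration error.  T_agg must land inside the
    measured range.
    """
    T = np.asarray(temperature_C, dtype=float)
    y = np.asarray(fraction_remaining, dtype=float)
    if T.shape != y.shape:
        raise ConfigurationError("temperature and fraction must align")
    if len(np.unique(T)) < 6:
        raise ConfigurationError(">= 6 temperatures required")
    means = pd.Series(y).groupby(pd.Series(T)).mean()
    if np.all(np.diff(means.to_numpy()) >= 0):
        raise ConfigurationError(
            "fraction remaining increases with temperature; check input orientation"
        )

    upper0, lower0 = float(means.iloc[0]), float(means.iloc[-1])
    mid = 0.5 * (upper0 + lower0)
    t0 = float(means.index[np.argmin(np.abs(means.to_numpy() - mid))])
    try:
        popt, _ = curve_fit(
            melt_sigmoid, T, y,
            p0=[upper0, lower0, t0, 2.0],
            bounds=([-np.inf, -np.inf, T.min(), 1e-6], [np.inf, np.inf, T.max(), np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"melt-curve fit failed: {exc}") from exc
    upper, lower, t_agg, slope = map(float, popt)
    if lower >= upper:
        raise FitError("melt-curve fit degenerate: lower plateau above upper")
    return MeltFit(upper=upper, lower=lower, t_agg_C=t_agg, slope_C=slope)


# ---------------------------------------------------------------------------
# qPCR delta-delta-Ct
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrResult:
    """Relative quantification of a target against a reference gene."""

    delta_delta_ct: float
    fold_change: float
    ct_means: dict


def qpcr_fold_change(
    ct_table: pd.DataFrame,
    target: str,
    reference: str = "GAPDH",
    treated: str = "treated",
    control: str = "control",
    efficiency: float = 2.0,
) -> QpcrResult:
    """Delta-delta-Ct fold change from a tidy Ct table.

    ``ct_table`` needs columns ``gene, condition, ct`` with technical
    replicates as rows; replicates are averaged on the Ct scale first.  Then

        ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control
        fold = efficiency ** (-ddCt)

    with the classic assumption of doubling per cycle (``efficiency = 2``).
    """
    if not 1.0 < efficiency <= 2.0:
        raise ConfigurationError("amplification efficiency must be in (1, 2]")
    means = ct_table.groupby(["gene", "condition"])["ct"].mean()
    try:
        d_treated = means[(target, treated)] - means[(reference, treated)]
        d_control = means[(target, control)] - means[(reference, control)]
    except KeyError as exc:
        raise ConfigurationError(f"missing Ct values for {exc.args[0]!r}") from exc
    ddct = float(d_treated - d_control)
    return QpcrResult(
        delta_delta_ct=ddct,
        fold_change=float(efficiency ** (-ddct)),
        ct_means={f"{g}:{c}": float(v) for (g, c), v in means.items()},
    )


# ---------------------------------------------------------------------------
# Viability
# ---------------------------------------------------------------------------

def viability_percent(live: int, total: int) -> float:
    """Percent live cells from a trypan-blue exclusion count."""
    if total <= 0:
        raise ConfigurationError("total cell count must be > 0")
    if not 0 <= live <= total:
        raise ConfigurationError("live count must lie in [0, total]")
    return 100.0 * live / total
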