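"""Four-parameter logistic (4PL) dose-response fitting with EC50 bootstrap.

The response model is

    y = bottom + (top - bottom) / (1 + (ec50/c)**hill)

fit by least squares on log10 concentration with a log-parameterized EC50
(positivity by construction) and multi-start initialization over the
concentration range.  Either asymptote can be fixed (e.g. a top constrained
to 130% of control when high-concentration variability leaves it poorly
determined).  EC50 uncertainty comes from a seeded case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from traffickit.errors import ConfigurationError, FitError
from traffickit.models import four_pl

__all__ = ["DoseResponseFit", "fit_four_pl"]


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters; ``ci_ec50`` is a percentile bootstrap interval."""

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    n: int
    constraints: dict = field(default_factory=dict)
    ci_ec50: tuple[float, float] | None = None

    def predict(self, conc):
        return four_pl(conc, self.bottom, self.top, self.ec50, self.hill)


def _fit_once(logc, y, fixed: dict[str, float], x0: dict[str, float]):
    names = sorted(k for k in ("bottom", "top", "log_ec50", "hill") if k not in fixed)

    def unpack(theta):
        p = dict(zip(names, theta))
        p.update(fixed)
        return p

    def resid(theta):
        p = unpack(theta)
        return four_pl(10.0**logc, p["bottom"], p["top"], 10.0 ** p["log_ec50"], p["hill"]) - y

    res = least_squares(resid, [x0[k] for k in names], method="lm", max_nfev=5000)
    return unpack(res.x), float(np.sum(res.fun**2))


def _best_fit(logc, y, fixed):
    """Multi-start LM fit: EC50 starts at quartiles of the log-conc range,
    hill at a few plausible slopes."""
    lo, hi = logc.min(), logc.max()
    ec50_starts = lo + np.array([0.25, 0.5, 0.75]) * (hi - lo)
    spread = y.max() - y.min()
    base = {"bottom": float(y.min()), "top": float(y.max())}
    best_p, best_rss = None, np.inf
    for le in ec50_starts:
        for hill in (0.7, 1.5, 3.0):
            x0 = dict(base, log_ec50=float(le), hill=hill)
            try:
                p, rss = _fit_once(logc, y, fixed, x0)
            except (ValueError, RuntimeError):
                continue
            if rss < best_rss:
                best_p, best_rss = p, rss
    if best_p is None:
        raise FitError("4PL fit failed from every start")
    return best_p, best_rss, spread


def fit_four_pl(
    concentration,
    response,
    constraints: dict | None = None,
    n_boot: int = 500,
    seed: int = 0,
    min_span_log10: float = 1.0,
) -> DoseResponseFit:
    """Fit a 4PL curve and report EC50 with a bootstrap CI.

    Parameters
    ----------
    concentration, response
        Paired observations; concentrations must be positive, cover >= 4
        distinct values, and span more than ``min_span_log10`` decades.
    constraints
        Optional fixed asymptotes, e.g. ``{"top": 130.0}``; a constrained
        parameter is returned exactly at its fixed value.
    n_boot, seed
        Case-resampling bootstrap replicates for the EC50 percentile CI
        (``n_boot = 0`` skips the bootstrap).

    Raises
    ------
    FitError
        If the data show no usable concentration dependence ("unidentifiable
        EC50") rather than silently returning an arbitrary fit.
    """
    conc = np.asarray(concentration, dtype=float)
    y = np.asarray(response, dtype=float)
    if conc.shape != y.shape:
        raise ConfigurationError("concentration and response must align")
    if np.any(conc <= 0):
        raise ConfigurationError("concentrations must be > 0")
    if not np.all(np.isfinite(y)):
        raise ConfigurationError("responses must be finite")
    distinct = np.unique(conc)
    if len(distinct) < 4:
        raise ConfigurationError(">= 4 distinct concentrations required")
    span = np.log10(distinct.max() / distinct.min())
    if span <= min_span_log10:
        raise ConfigurationError(
            f"concentrations span {span:.2f} decades; > {min_span_log10} required"
        )

    fixed = {}
    for k, v in (constraints or {}).items():
        if k not in ("top", "bottom"):
            raise ConfigurationError(f"unknown constraint {k!r}")
        fixed[k] = float(v)

    logc = np.log10(conc)
    p, rss, spread = _best_fit(logc, y, fixed)

    # identifiability: the fit must beat a flat model decisively and place
    # EC50 within (an extension of) the tested range
    flat_rss = float(np.sum((y - y.mean()) ** 2))
    noise_scale = max(np.abs(y).max(), 1.0)
    if flat_rss - rss <= 1e-10 * noise_scale**2 or (
        spread > 0 and (flat_rss - rss) / flat_rss < 1e-6
    ):
        raise FitError("unidentifiable EC50: no concentration dependence detected")
    if not (logc.min() - 2.0 < p["log_ec50"] < logc.max() + 2.0):
        raise FitError("unidentifiable EC50: estimate far outside the tested range")

    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        idx_all = np.arange(len(conc))
        boots = []
        x0 = {k: v for k, v in p.items() if k not in fixed}
        for _ in range(n_boot):
            idx = rng.choice(idx_all, size=len(idx_all), replace=True)
            if len(np.unique(conc[idx])) < 4:
                continue
            try:
                pb, _ = _fit_once(logc[idx], y[idx], fixed, x0)
            except (ValueError, RuntimeError):
                continue
            boots.append(10.0 ** pb["log_ec50"])
        if len(boots) >= max(50, n_boot // 4):
            ci = tuple(np.percentile(boots, [2.5, 97.5]))

    return DoseResponseFit(
        bottom=float(p["bottom"]),
        top=float(p["top"]),
        ec50=float(10.0 ** p["log_ec50"]),
        hill=float(p["hill"]),
        rss=rss,
        n=len(conc),
        constraints=dict(fixed),
        ci_ec50=ci,
    )
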