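"""Automated patch-clamp I_Ks analysis.

The chain mirrors standard planar-array workflows for slow delayed-rectifier
currents: recordings must pass seal/series-resistance QC (Rseal >= 0.1 GOhm,
Rseries < 10 MOhm); nonspecific components are removed by subtracting the
trace recorded after a selective blocker; peak current is read at 1,990 ms
into the 2,000 ms depolarization and normalized by membrane capacitance;
tail-current amplitudes at -30 mV build the conductance-voltage relation,
with each test potential corrected for the uncompensated series-resistance
voltage drop (V_corr = V_cmd - I*Rseries); and the normalized G-V is fit with
a Boltzmann function to report the half-activation voltage and slope factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from traffickit.errors import ConfigurationError, FitError, IntegrityError
from traffickit.models import boltzmann
from traffickit.simulate.sweeps import SweepRecording

__all__ = [
    "GVFit",
    "blocker_subtract",
    "fit_boltzmann",
    "gv_from_tails",
    "peak_current_density",
    "qc_recordings",
    "analyze_cell",
]

RSEAL_MIN_GOHM = 0.1
RSERIES_MAX_MOHM = 10.0


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_recordings(metadata: pd.DataFrame) -> pd.DataFrame:
    """Apply the recording-quality rule to per-cell metadata.

    ``metadata`` needs columns ``cell_id, rseal_GOhm, rseries_MOhm``.  A cell
    passes iff Rseal >= 0.1 GOhm (inclusive) and Rseries < 10 MOhm (strict);
    missing metadata fails with reason ``metadata-absent``.  Blocker
    sensitivity is a separate criterion applied after subtraction.
    """
    rows = []
    for _, r in metadata.iterrows():
        rseal, rs = r.get("rseal_GOhm"), r.get("rseries_MOhm")
        reasons = []
        if rseal is None or rs is None or pd.isna(rseal) or pd.isna(rs):
            reasons.append("metadata-absent")
        else:
            if not rseal >= RSEAL_MIN_GOHM:
                reasons.append("rseal-low")
            if not rs < RSERIES_MAX_MOHM:
                reasons.append("rseries-high")
        rows.append(
            {"cell_id": r["cell_id"], "pass": not reasons, "reasons": ";".join(reasons)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Blocker subtraction
# ---------------------------------------------------------------------------

def blocker_subtract(
    before: SweepRecording,
    after: SweepRecording,
    sensitivity_floor_pA: float = 100.0,
    sample_ms: float = 1990.0,
) -> tuple[SweepRecording, bool]:
    """Pointwise ``before - after`` per sweep; flags blocker sensitivity.

    The pair must share the protocol and time base.  A cell is
    blocker-sensitive iff the subtracted current at the peak sample of the
    highest test potential exceeds ``sensitivity_floor_pA``; only sensitive
    cells proceed to analysis.
    """
    if before.protocol != after.protocol:
        raise IntegrityError("before/after protocols differ")
    b, a = before.sweeps, after.sweeps
    if len(b) != len(a) or not (
        np.array_equal(b["sweep_id"].to_numpy(), a["sweep_id"].to_numpy())
        and np.allclose(b["time_ms"].to_numpy(), a["time_ms"].to_numpy())
    ):
        raise IntegrityError("before/after time bases differ")
    diff = b.copy()
    diff["i_pA"] = b["i_pA"].to_numpy() - a["i_pA"].to_numpy()

    subtracted = SweepRecording(
        cell_id=before.cell_id,
        phase="blocker_sensitive",
        sweeps=diff,
        cm_pF=before.cm_pF,
        rseries_MOhm=before.rseries_MOhm,
        rseal_GOhm=before.rseal_GOhm,
        protocol=before.protocol,
    )
    top_sweep = int(diff["sweep_id"].max())
    peak = _current_at(diff, top_sweep, sample_ms)
    return subtracted, bool(peak > sensitivity_floor_pA)


def _current_at(sweeps: pd.DataFrame, sweep_id: int, sample_ms: float,
                window_ms: float = 0.0) -> float:
    """Current at (or averaged +/- window around) a sample time in one sweep."""
    sw = sweeps[sweeps["sweep_id"] == sweep_id]
    if sw.empty:
        raise ConfigurationError(f"no sweep {sweep_id}")
    t = sw["time_ms"].to_numpy()
    if sample_ms > t.max():
        raise ConfigurationError(
            f"trace ends at {t.max():.0f} ms, before the {sample_ms:.0f} ms sample"
        )
    i = sw["i_pA"].to_numpy()
    if window_ms > 0:
        mask = np.abs(t - sample_ms) <= window_ms
        return float(i[mask].mean())
    return float(i[np.argmin(np.abs(t - sample_ms))])


# ---------------------------------------------------------------------------
# Current density
# ---------------------------------------------------------------------------

def peak_current_density(
    rec: SweepRecording,
    sample_ms: float = 1990.0,
    window_ms: float = 0.0,
) -> pd.DataFrame:
    """Capacitance-normalized current (pA/pF) per test potential.

    Current is read at the nearest sample to ``sample_ms`` (or the mean over
    ``+/- window_ms``) near the end of the depolarization, then divided by
    the cell's membrane capacitance.
    """
    if rec.cm_pF <= 0:
        raise ConfigurationError("Cm must be > 0")
    v_test = rec.test_potentials()
    rows = []
    for sweep_id, v in enumerate(v_test):
        i = _current_at(rec.sweeps, sweep_id, sample_ms, window_ms)
        rows.append({"v_test_mV": v, "i_pA": i, "density_pA_pF": i / rec.cm_pF})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tail-current G-V
# ---------------------------------------------------------------------------

def gv_from_tails(
    rec: SweepRecording,
    rseries_MOhm: float | None = None,
    step_currents_pA: np.ndarray | None = None,
    tail_window_ms: float = 50.0,
    baseline_fraction: float = 0.25,
    sample_ms: float = 1990.0,
) -> pd.DataFrame:
    """Normalized conductance points from tail currents.

    Tail amplitude per test potential is the extremum within the first
    ``tail_window_ms`` of the -30 mV segment minus the post-deactivation
    baseline (mean of the last ``baseline_fraction`` of the tail).  Each test
    potential is corrected for the series-resistance drop,
    ``V_corr = V_cmd - I_step * Rseries`` (mV = nA * MOhm), where ``I_step``
    defaults to the recording's own current at the peak sample but can be
    supplied explicitly (e.g. the pre-blocker total current, which carries
    the full drop across Rseries).

    Returns columns ``v_test_mV, v_corr_mV, tail_pA, g_norm`` with
    ``max(g_norm) = 1``.
    """
    rs = rec.rseries_MOhm if rseries_MOhm is None else rseries_MOhm
    if rs < 0:
        raise ConfigurationError("Rseries must be >= 0")
    proto = rec.protocol
    v_test = rec.test_potentials()
    if step_currents_pA is None:
        step_currents_pA = np.array(
            [_current_at(rec.sweeps, i, sample_ms) for i in range(len(v_test))]
        )
    step_currents_pA = np.asarray(step_currents_pA, dtype=float)
    if step_currents_pA.shape != v_test.shape:
        raise ConfigurationError("step currents must align with test potentials")

    tails = []
    for sweep_id in range(len(v_test)):
        sw = rec.sweeps[rec.sweeps["sweep_id"] == sweep_id]
        # segment by time: the test step at v_tail would alias a voltage gate
        tail = sw[sw["time_ms"] >= proto.t_depol_ms]
        if tail.empty:
            raise ConfigurationError(f"sweep {sweep_id}: no tail segment")
        t = tail["time_ms"].to_numpy()
        i = tail["i_pA"].to_numpy()
        t0 = t.min()
        head = i[t - t0 <= tail_window_ms]
        base = i[t >= t.max() - baseline_fraction * (t.max() - t0)].mean()
        # extremum relative to baseline (tails may be inward or outward)
        rel = head - base
        tails.append(rel[np.argmax(np.abs(rel))])
    tails = np.asarray(tails)

    gmax = tails.max()
    if gmax <= 0:
        raise FitError("no activation detected: tail amplitudes are non-positive")
    v_corr = v_test - step_currents_pA * 1e-3 * rs  # pA*MOhm = uV -> mV
    return pd.DataFrame(
        {"v_test_mV": v_test, "v_corr_mV": v_corr, "tail_pA": tails,
         "g_norm": tails / gmax}
    )


def _scaled_boltzmann(v, v_half, k, scale):
    return boltzmann(v, v_half, k, scale)


@dataclass(frozen=True)
class GVFit:
    """Boltzmann activation fit: G/Gmax = 1 / (1 + exp((v_half - V)/k))."""

    v_half_mV: float
    k_mV: float
    gmax: float
    rss: float

    def predict(self, v):
        return boltzmann(v, self.v_half_mV, self.k_mV)


def fit_boltzmann(gv_points: pd.DataFrame) -> GVFit:
    """Fit a Boltzmann to normalized conductance points.

    ``gv_points`` needs columns ``v_corr_mV`` and ``g_norm``; at least five
    points spanning the transition are required.  A free scale absorbs the
    normalization-to-maximum convention (the largest measured point need not
    sit on the saturated plateau); reported ``v_half`` and ``k`` describe the
    unit-amplitude Boltzmann.
    """
    v = gv_points["v_corr_mV"].to_numpy(dtype=float)
    g = gv_points["g_norm"].to_numpy(dtype=float)
    if len(v) < 5:
        raise ConfigurationError(">= 5 G-V points required")
    spread = g.max() - g.min()
    if spread < 0.1:
        raise FitError("non-sigmoidal G-V: dynamic range < 0.1 of the maximum")
    v0 = float(v[np.argmin(np.abs(g - 0.5 * (g.max() + g.min())))])
    try:
        popt, _ = curve_fit(
            _scaled_boltzmann, v, g, p0=[v0, 10.0, 1.0], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit failed: {exc}") from exc
    v_half, k, scale = map(float, popt)
    if k <= 0 or not (v.min() - 100 < v_half < v.max() + 100):
        raise FitError(
            f"non-sigmoidal G-V: fitted v_half={v_half:.1f} mV, k={k:.1f} mV"
        )
    resid = g - _scaled_boltzmann(v, *popt)
    return GVFit(v_half_mV=v_half, k_mV=k, gmax=scale, rss=float(np.sum(resid**2)))


# ---------------------------------------------------------------------------
# Per-cell pipeline
# ---------------------------------------------------------------------------

def analyze_cell(
    before: SweepRecording,
    after: SweepRecording,
    sensitivity_floor_pA: float = 100.0,
) -> dict:
    """QC, subtract, and fit one cell; returns a result dict.

    The voltage-drop correction uses the pre-blocker total current at the
    peak sample, since the drop across Rseries is produced by the whole
    current, not only its blocker-sensitive component.
    """
    meta = pd.DataFrame(
        [{"cell_id": before.cell_id, "rseal_GOhm": before.rseal_GOhm,
          "rseries_MOhm": before.rseries_MOhm}]
    )
    qc = qc_recordings(meta)
    result = {"cell_id": before.cell_id, "qc_pass": bool(qc["pass"].iloc[0]),
              "qc_reasons": qc["reasons"].iloc[0]}
    if not result["qc_pass"]:
        return result

    sensitive_rec, is_sensitive = blocker_subtract(before, after, sensitivity_floor_pA)
    result["blocker_sensitive"] = is_sensitive
    if not is_sensitive:
        return result

    density = peak_current_density(sensitive_rec)
    v_test = before.test_potentials()
    total_step = np.array(
        [_current_at(before.sweeps, i, 1990.0) for i in range(len(v_test))]
    )
    gv = gv_from_tails(sensitive_rec, step_currents_pA=total_step)
    fit = fit_boltzmann(gv)
    result.update(
        density=density, gv=gv, v_half_mV=fit.v_half_mV, k_mV=fit.k_mV,
        peak_density_pA_pF=float(density["density_pA_pF"].max()),
    )
    return result
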