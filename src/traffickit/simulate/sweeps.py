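"""Synthetic automated patch-clamp recordings of blocker-sensitive current.

Each simulated cell is held at -80 mV and stepped through 2,000 ms
depolarizations from -80 to +60 mV in +10 mV increments, each followed by a
2,000 ms repolarization to -30 mV for tail currents -- the standard protocol
for slow delayed-rectifier (I_Ks) analysis.  The specific current obeys a
Boltzmann steady-state activation with first-order kinetics; a seal-leak
conductance (1/Rseal) carries the blocker-insensitive component.  Because the
recording has uncompensated series resistance, the membrane potential during
each step sits below the command potential by I*Rseries; the generator solves
the self-consistent membrane potential at the analysis sample point
(1,990 ms) so the planted Boltzmann is exactly recoverable from tail
amplitudes at voltage-drop-corrected potentials.  "After-blocker" recordings
scale the specific component by (1 - blocker_fraction); capacitive transients
are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traffickit._rng import substream
from traffickit.errors import ConfigurationError
from traffickit.models import boltzmann


@dataclass(frozen=True)
class SweepProtocol:
    """Voltage protocol: test steps, durations, tail potential, sampling."""

    v_test_mV: tuple[float, ...] = tuple(np.arange(-80.0, 61.0, 10.0))
    t_depol_ms: float = 2000.0
    t_tail_ms: float = 2000.0
    v_tail_mV: float = -30.0
    v_hold_mV: float = -80.0
    dt_ms: float = 1.0

    def validate(self) -> None:
        v = np.asarray(self.v_test_mV)
        if len(v) < 2 or np.any(np.diff(v) <= 0):
            raise ConfigurationError("test potentials must be strictly increasing")
        if self.dt_ms <= 0 or self.t_depol_ms <= 0 or self.t_tail_ms <= 0:
            raise ConfigurationError("durations and dt must be > 0")


@dataclass(frozen=True)
class GVTruth:
    """Planted activation truth: Boltzmann midpoint/slope and max conductance."""

    v_half_mV: float = 20.0
    k_mV: float = 13.0
    gmax_nS: float = 10.0
    e_rev_mV: float = -85.0
    tau_act_ms: float = 500.0
    tau_deact_ms: float = 150.0


@dataclass
class SweepRecording:
    """One cell/phase recording: tidy sweep table plus chip metadata.

    ``sweeps`` columns: ``sweep_id, time_ms, v_cmd_mV, i_pA`` where
    ``v_cmd_mV`` is the instantaneous command potential (test level during the
    depolarization, the tail level afterwards).
    """

    cell_id: str
    phase: str  # before_blocker | after_blocker
    sweeps: pd.DataFrame
    cm_pF: float
    rseries_MOhm: float
    rseal_GOhm: float
    protocol: SweepProtocol

    def test_potentials(self) -> np.ndarray:
        return np.asarray(self.protocol.v_test_mV, dtype=float)


def _self_consistent_vm(v_cmd, truth: GVTruth, rs_MOhm, leak_nS, act_frac, block=1.0):
    """Membrane potential solving Vm = Vcmd - Itot(Vm)*Rs at the sample point.

    The seal-leak component sits across the pipette-bath seal and follows the
    command potential, so it is identical before and after the blocker.
    """
    vm = float(v_cmd)
    i_leak = leak_nS * v_cmd
    for _ in range(200):
        i_spec = block * truth.gmax_nS * boltzmann(vm, truth.v_half_mV, truth.k_mV) * (
            vm - truth.e_rev_mV
        ) * act_frac
        new = v_cmd - (i_spec + i_leak) * rs_MOhm * 1e-3  # pA*MOhm = uV
        if abs(new - vm) < 1e-12:
            vm = new
            break
        vm = 0.5 * vm + 0.5 * new
    return vm


def simulate_sweeps(
    protocol: SweepProtocol = SweepProtocol(),
    gv_truth: GVTruth = GVTruth(),
    rseries_MOhm: float = 4.0,
    rseal_GOhm: float = 1.0,
    cm_pF: float = 15.0,
    blocker_fraction: float = 1.0,
    noise_sd_pA: float = 0.0,
    sample_ms: float = 1990.0,
    cell_id: str = "cell-000",
    seed: int = 0,
) -> tuple[SweepRecording, SweepRecording]:
    """Simulate one cell before and after the selective blocker.

    Returns ``(before, after)`` recordings sharing protocol and metadata.  The
    leak conductance is ``1/Rseal`` and is unaffected by the blocker; the
    specific current after blocker is scaled by ``1 - blocker_fraction``.
    Deterministic given ``seed``.
    """
    protocol.validate()
    if cm_pF <= 0:
        raise ConfigurationError("Cm must be > 0")
    if rseries_MOhm < 0 or rseal_GOhm <= 0:
        raise ConfigurationError("Rseries must be >= 0 and Rseal > 0")
    if not 0 < blocker_fraction <= 1:
        raise ConfigurationError("blocker_fraction must be in (0, 1]")
    if noise_sd_pA < 0:
        raise ConfigurationError("noise_sd_pA must be >= 0")

    leak_nS = 1.0 / rseal_GOhm
    act_frac = 1.0 - np.exp(-sample_ms / gv_truth.tau_act_ms)

    n_dep = int(round(protocol.t_depol_ms / protocol.dt_ms))
    n_tail = int(round(protocol.t_tail_ms / protocol.dt_ms))
    t = np.arange(n_dep + n_tail) * protocol.dt_ms
    t_dep = t[:n_dep]
    t_tail_rel = t[n_dep:] - protocol.t_depol_ms

    recordings = {}
    for phase, block in (("before_blocker", 1.0), ("after_blocker", 1.0 - blocker_fraction)):
        rng = substream(seed, "sweeps", cell_id, phase)
        frames = []
        for idx, v in enumerate(protocol.v_test_mV):
            vm = _self_consistent_vm(v, gv_truth, rseries_MOhm, leak_nS, act_frac, block)
            p_open = float(boltzmann(vm, gv_truth.v_half_mV, gv_truth.k_mV))
            i_spec_ss = block * gv_truth.gmax_nS * p_open * (vm - gv_truth.e_rev_mV)
            i_dep = i_spec_ss * (1.0 - np.exp(-t_dep / gv_truth.tau_act_ms)) + leak_nS * v

            # tail: channels opened to p_open*act_frac deactivate fully at the
            # tail potential; leak follows the tail command potential
            p_end = p_open * act_frac
            tail_amp = block * gv_truth.gmax_nS * p_end * (
                protocol.v_tail_mV - gv_truth.e_rev_mV
            )
            i_tail = tail_amp * np.exp(-t_tail_rel / gv_truth.tau_deact_ms) + (
                leak_nS * protocol.v_tail_mV
            )

            i = np.concatenate([i_dep, i_tail])
            if noise_sd_pA > 0:
                i = i + rng.normal(0.0, noise_sd_pA, i.shape)
            v_cmd = np.concatenate(
                [np.full(n_dep, v), np.full(n_tail, protocol.v_tail_mV)]
            )
            frames.append(
                pd.DataFrame(
                    {"sweep_id": idx, "time_ms": t, "v_cmd_mV": v_cmd, "i_pA": i}
                )
            )
        recordings[phase] = SweepRecording(
            cell_id=cell_id,
            phase=phase,
            sweeps=pd.concat(frames, ignore_index=True),
            cm_pF=cm_pF,
            rseries_MOhm=rseries_MOhm,
            rseal_GOhm=rseal_GOhm,
            protocol=protocol,
        )
    return recordings["before_blocker"], recordings["after_blocker"]
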