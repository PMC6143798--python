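"""Diagnostic analyses of the decision circuit.

Computational counterparts of the standard diagnostics for this model
family: the single-synapse dopamine/STDP interaction experiment, learned
weight maps on the state x action grid, baseline-subtracted firing-rate
dynamics across decisions, orbitofrontal weight trajectories and
decision-latency statistics for the OFC ablation comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neurons import DEFAULT_DT, NeuronState, RS, izhikevich_step
from .plasticity import OnlineSTDP, STDPParams
from .circuit import NetworkState
from .loop import EpisodeTrace

SINGLE_SYNAPSE_CONDITIONS = ("stdp_only", "da_d1_stdp", "da_d2_stdp")


@dataclass
class SingleSynapseResult:
    condition: str
    dt: float
    pre_spikes: np.ndarray      # ms
    post_spikes: np.ndarray     # ms
    weight_trajectory: np.ndarray  # per tick
    reward_time: float


def single_synapse_experiment(
    condition: str = "stdp_only",
    duration: float = 1000.0,
    reward_time: float = 400.0,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    drive: float = 15.0,
    gain: float = 30.0,
    w0: float = 1.0,
    tau_syn: float = 5.0,
    stdp: STDPParams = STDPParams(),
    eta: float = 0.05,
) -> SingleSynapseResult:
    """One presynaptic RS neuron under constant drive feeding one
    postsynaptic RS neuron through a single plastic synapse.

    STDP runs throughout; at ``reward_time`` the synapse is multiplied
    by the phasic dopamine factor of the chosen condition (x2 for the
    direct-pathway burst, x0.5 for the indirect-pathway view of the
    same burst, nothing for the control).  Before the reward the three
    conditions are identical by construction.
    """
    if condition not in SINGLE_SYNAPSE_CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {SINGLE_SYNAPSE_CONDITIONS}"
        )
    if not 0 < reward_time < duration:
        raise ValueError("reward_time must lie inside the simulation window")
    n = int(round(duration / dt))
    reward_tick = int(round(reward_time / dt))
    decay = np.exp(-dt / tau_syn)

    rest = NeuronState.resting()
    v = np.array([rest.v, rest.v])
    u = np.array([rest.u, rest.u])
    syn = OnlineSTDP(w0, stdp, eta=eta, tie_epsilon=dt)
    trace = 0.0
    pre_t, post_t, w_traj = [], [], []
    for k in range(n):
        t = k * dt
        if k == reward_tick and condition != "stdp_only":
            syn.modulate(2.0 if condition == "da_d1_stdp" else 0.5)
        current = np.array([drive, gain * syn.w * trace])
        v, u, fired = izhikevich_step(v, u, current, dt)
        if fired[0]:
            pre_t.append(t)
        if fired[1]:
            post_t.append(t)
        syn.observe(t, bool(fired[0]), bool(fired[1]))
        trace = trace * decay + (1.0 if fired[0] else 0.0)
        w_traj.append(syn.w)
    return SingleSynapseResult(
        condition=condition,
        dt=dt,
        pre_spikes=np.asarray(pre_t),
        post_spikes=np.asarray(post_t),
        weight_trajectory=np.asarray(w_traj),
        reward_time=reward_time,
    )


_WEIGHT_MAP_CONNECTIONS = {
    "dlpfc_strd1": "DLPFC->StrD1",
    "dlpfc_strd2": "DLPFC->StrD2",
    "dlpfc_pm": "DLPFC->PM",
}


def weight_map(net: NetworkState, connection: str) -> np.ndarray:
    """Collapse a learned projection to a (state, action) matrix.

    For the pair-indexed cortico-striatal blocks entry (s, a) is the
    weight from DLPFC neuron s onto striatal pair (s, a); for the
    cortico-premotor block it is the weight matrix itself.
    """
    key = connection.lower().replace("->", "_").replace("-", "_").replace("strd", "strd")
    if key not in _WEIGHT_MAP_CONNECTIONS:
        raise ValueError(
            f"unknown connection {connection!r}; expected one of "
            f"{sorted(_WEIGHT_MAP_CONNECTIONS.values())}"
        )
    w = net.weights[key]
    ns, na = net.n_states, net.n_actions
    if key == "dlpfc_pm":
        return w.copy()
    grid = np.empty((ns, na))
    for s in range(ns):
        grid[s] = w[s, s * na:(s + 1) * na]
    return grid


def weight_map_frame(net: NetworkState, connection: str) -> pd.DataFrame:
    grid = weight_map(net, connection)
    return pd.DataFrame(
        grid,
        index=[f"s{s}" for s in range(grid.shape[0])],
        columns=[f"a{a}" for a in range(grid.shape[1])],
    )


def firing_rates(
    traces: list[EpisodeTrace] | EpisodeTrace,
    population: str,
    phase: str = "decision",
    baseline: float | None = None,
    feedback_ticks: int | None = None,
) -> np.ndarray:
    """Per-decision firing rate of a population, minus a baseline.

    Rate = spikes per tick in the decision (or feedback) window of each
    decision event.  The default baseline is the first decision's rate,
    mirroring baseline-subtracted rate plots where the untrained
    network's first decision defines zero.
    """
    if isinstance(traces, EpisodeTrace):
        traces = [traces]
    events = [e for tr in traces for e in tr.events]
    if not events:
        import warnings

        warnings.warn("empty trace set; no rates to compute")
        return np.array([])
    if phase == "feedback" and feedback_ticks is None:
        from .circuit import CircuitConfig

        feedback_ticks = CircuitConfig().feedback_ticks
    rates = []
    for e in events:
        if phase == "decision":
            counts, ticks = e.decision_counts, max(e.latency, 1)
        elif phase == "feedback":
            counts, ticks = e.feedback_counts or {}, feedback_ticks
        else:
            raise ValueError("phase must be 'decision' or 'feedback'")
        if population not in counts:
            raise KeyError(f"population {population!r} absent from the record")
        rates.append(counts[population] / ticks)
    rates = np.asarray(rates)
    if baseline is None:
        baseline = rates[0]
    return rates - baseline


def latency_stats(
    traces: list[EpisodeTrace] | EpisodeTrace, n_decisions: int = 100
) -> float:
    """Mean decision latency (ticks) over the first ``n_decisions`` events."""
    if isinstance(traces, EpisodeTrace):
        traces = [traces]
    lats = [lat for tr in traces for lat in tr.latencies]
    if not lats:
        raise ValueError("latency_stats requires at least one decision")
    if len(lats) < n_decisions:
        import warnings

        warnings.warn(
            f"only {len(lats)} decisions available; mean computed over those"
        )
    return float(np.mean(lats[:n_decisions]))


def ofc_weight_trajectories(
    traces: list[EpisodeTrace] | EpisodeTrace,
) -> pd.DataFrame:
    """Per-update sums of the four OFC->striatum weight blocks.

    One row per decision event (after its feedback was applied), columns
    mofc_strd1, mofc_strd2, lofc_strd1, lofc_strd2.
    """
    if isinstance(traces, EpisodeTrace):
        traces = [traces]
    rows = []
    for tr in traces:
        for e in tr.events:
            if not e.ofc_weight_sums:
                raise ValueError(
                    "trace events carry no OFC weight snapshots; rerun the "
                    "episode with learning enabled"
                )
            rows.append(dict(e.ofc_weight_sums))
    return pd.DataFrame(rows)
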