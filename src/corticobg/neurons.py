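"""Izhikevich point-neuron dynamics.

All populations in the decision circuit use the two-variable Izhikevich
model

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

with a spike emitted when the membrane potential ``v`` reaches the 30 mV
peak, after which ``v`` is reset to ``c`` and the recovery variable ``u``
is incremented by ``d``.  The regular-spiking (RS) parameter set
(a=0.02, b=0.2, c=-65, d=8) is used everywhere; inhibition in the circuit
is carried purely by negative synaptic weights, not by separate
inhibitory neuron classes.

Integration is forward Euler at a configurable step (0.5 ms default).
Spike detection follows the canonical detect-then-reset scheme: a tick
that begins at or above the peak registers the spike and applies the
reset without integrating, so the post-spike state is exactly
(v, u) = (c, u + d).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

V_PEAK = 30.0
#: Hard numerical guard: |v| beyond this without a reset means the Euler
#: step size is misconfigured, and the simulation refuses to continue.
V_GUARD = 500.0
#: Hyperpolarisation floor (mV).  Strong inhibitory input would otherwise
#: drive the quadratic term into an unphysical rebound; clamping at the
#: potassium-reversal scale keeps inhibition saturating rather than
#: explosive.  The floor never binds for purely excitatory drive.
V_FLOOR = -90.0

DEFAULT_DT = 0.5  # ms


class NumericalBlowupError(FloatingPointError):
    """Membrane state left the physically meaningful range (dt too large)."""


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of the two-variable Izhikevich neuron.

    a : recovery time scale (1/ms semantics)
    b : sensitivity of recovery to the membrane potential
    c : post-spike reset potential (mV)
    d : post-spike recovery increment
    v_peak : spike cutoff (mV); fixed at 30 for the standard model
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_peak: float = V_PEAK

    @classmethod
    def regular_spiking(cls) -> "IzhikevichParams":
        """The RS preset used for every population in the circuit."""
        return cls(a=0.02, b=0.2, c=-65.0, d=8.0)


RS = IzhikevichParams.regular_spiking()


@dataclass
class NeuronState:
    """Membrane state of one neuron: potential, recovery, spike flag."""

    v: float
    u: float
    fired: bool = False

    @classmethod
    def resting(cls, params: IzhikevichParams = RS) -> "NeuronState":
        """The stationary point of the RS dynamics at zero input.

        Solves 0.04 v^2 + 5 v + 140 - u = 0 with u = b v; for RS this is
        (v, u) = (-70, -14).
        """
        b = params.b
        # 0.04 v^2 + (5 - b) v + 140 = 0, lower (stable) root
        disc = (5.0 - b) ** 2 - 4 * 0.04 * 140.0
        v = (-(5.0 - b) - np.sqrt(disc)) / (2 * 0.04)
        return cls(v=float(v), u=float(params.b * v), fired=False)


def izhikevich_step(
    v: np.ndarray,
    u: np.ndarray,
    current: np.ndarray | float,
    dt: float,
    params: IzhikevichParams = RS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance a population of neurons by one Euler tick (vectorised).

    Returns ``(v, u, fired)`` where ``fired`` marks neurons whose
    membrane potential had reached the peak at the start of the tick;
    those neurons are reset instead of integrated.

    Raises
    ------
    NumericalBlowupError
        If any membrane state becomes non-finite or exceeds the
        +-500 mV guard band without having been reset.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    fired = v >= params.v_peak

    v_new = np.where(fired, params.c, v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current))
    u_new = np.where(fired, u + params.d, u + dt * params.a * (params.b * v - u))
    v_new = np.maximum(v_new, V_FLOOR)

    if not (np.all(np.isfinite(v_new)) and np.all(np.isfinite(u_new))):
        raise NumericalBlowupError(
            "non-finite membrane state after Euler update; reduce dt"
        )
    if np.any(np.abs(v_new) > V_GUARD):
        raise NumericalBlowupError(
            f"|v| exceeded {V_GUARD} mV without reset; reduce dt or input gain"
        )
    return v_new, u_new, fired


def step_neuron(
    state: NeuronState,
    params: IzhikevichParams = RS,
    input_current: float = 0.0,
    dt: float = DEFAULT_DT,
) -> NeuronState:
    """Advance a single neuron by one tick; pure (returns a new state).

    The spike flag of the returned state is True iff the neuron's
    potential had reached the 30 mV peak, in which case the reset
    v <- c, u <- u + d was applied. The flag doubles as the neuron's
    output o for downstream input summation (o = 1 iff fired).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not (np.isfinite(state.v) and np.isfinite(state.u)):
        raise ValueError("neuron state must be finite")
    v, u, fired = izhikevich_step(
        np.array([state.v]), np.array([state.u]), input_current, dt, params
    )
    return replace(state, v=float(v[0]), u=float(u[0]), fired=bool(fired[0]))


def spike_train(
    current: float,
    duration_ms: float,
    dt: float = DEFAULT_DT,
    params: IzhikevichParams = RS,
    state: NeuronState | None = None,
) -> np.ndarray:
    """Spike times (ms) of a single neuron under constant drive.

    Convenience routine used for calibration and step-size regression
    tests; starts from the resting state unless one is given.
    """
    s = state if state is not None else NeuronState.resting(params)
    v = np.array([s.v])
    u = np.array([s.u])
    n = int(round(duration_ms / dt))
    times = []
    for k in range(n):
        v, u, fired = izhikevich_step(v, u, current, dt, params)
        if fired[0]:
            times.append(k * dt)
    return np.asarray(times)
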