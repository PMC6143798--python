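"""Synaptic learning rules: STDP and phasic dopamine modulation.

Two mechanisms act on the plastic synapses of the circuit:

* **STDP** — the weight change for a pre/post spike pair separated by
  ``delta_t = t_pre - t_post`` is

      dw = +A_plus  * exp( delta_t / tau_plus)   if delta_t < 0 (pre first)
      dw = -A_minus * exp(-delta_t / tau_minus)  if delta_t > 0 (post first)

  with defaults A_plus = 0.925, A_minus = 0.9, tau_plus = tau_minus = 20 ms.
  Pairs are formed nearest-neighbour: each postsynaptic spike pairs with
  the most recent presynaptic spike, and each presynaptic spike with the
  most recent earlier postsynaptic spike.  Simultaneous spikes count as
  causal potentiation at one-tick separation.  The raw pair increment is
  scaled by a learning rate ``eta`` before being added to the weight.

* **Dopamine** — after each action, the phasic dopamine level is read off
  the valence of the actual reward r_end and applied multiplicatively to
  the cortico-striatal weights of the executed state-action pair: the D1
  (direct, "Go") pathway sees x2 on reward and x0.5 on punishment, the D2
  (indirect, "No Go") pathway the reciprocal, so the product of the two
  modulation factors is always exactly 1.

Weights live in a configurable band [w_min, w_max] (default [0, 10]);
both rules clip into that band, and a structurally absent synapse
(weight 0 under multiplication, outside the plastic mask under STDP)
stays absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_W_MIN = 0.0
DEFAULT_W_MAX = 10.0
DEFAULT_ETA = 0.05


@dataclass(frozen=True)
class STDPParams:
    A_plus: float = 0.925
    A_minus: float = 0.9
    tau_plus: float = 20.0
    tau_minus: float = 20.0


@dataclass(frozen=True)
class DALevels:
    """Multiplicative dopamine modulation factors for the two pathways.

    ``da_d1`` acts on the direct (D1/"Go") cortico-striatal block and
    ``da_d2`` on the indirect (D2/"No Go") block; the two are always
    reciprocal (da_d1 * da_d2 == 1).
    """

    da_d1: float
    da_d2: float


def stdp_delta(delta_t: float, params: STDPParams = STDPParams()) -> float:
    """Raw STDP weight change for one spike pair.

    ``delta_t`` is the pre-minus-post spike time difference in ms;
    negative means the presynaptic spike led (potentiation).
    """
    if not np.isfinite(delta_t):
        raise ValueError("delta_t must be finite")
    if delta_t == 0:
        raise ValueError(
            "delta_t == 0 is ambiguous; the caller must apply the "
            "simultaneous-spike tie rule (potentiation at one tick)"
        )
    if delta_t < 0:
        return params.A_plus * float(np.exp(delta_t / params.tau_plus))
    return -params.A_minus * float(np.exp(-delta_t / params.tau_minus))


def pair_spike_trains(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    params: STDPParams = STDPParams(),
    tie_epsilon: float = 0.5,
) -> float:
    """Total raw STDP change from two spike trains.

    Symmetric nearest-neighbour pairing: only adjacent unlike spikes in
    the merged train interact — a pre spike immediately followed by a
    post spike potentiates (delta_t < 0), a post spike immediately
    followed by a pre spike depresses (delta_t > 0); a tie counts as
    pre-leading by ``tie_epsilon``.  Returns the summed raw dw,
    unscaled by the learning rate.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    # merge the trains and let only adjacent unlike spikes interact:
    # a pre immediately followed by a post potentiates, a post
    # immediately followed by a pre depresses.  This symmetric
    # nearest-neighbour scheme keeps a tonically firing presynaptic
    # neuron from accumulating unbounded depression against a sparse
    # postsynaptic train.
    times = np.concatenate([pre, post])
    kinds = np.concatenate([np.zeros(pre.size), np.ones(post.size)])
    order = np.lexsort((kinds, times))  # ties: pre sorts before post
    times, kinds = times[order], kinds[order]
    dw = 0.0
    for k in range(1, len(times)):
        if kinds[k] == kinds[k - 1]:
            continue
        if kinds[k] == 1:  # pre -> post: potentiation, delta_t < 0
            dt = times[k - 1] - times[k]
            if dt == 0:
                dt = -tie_epsilon
            dw += params.A_plus * np.exp(dt / params.tau_plus)
        else:  # post -> pre: depression, delta_t > 0
            dt = times[k] - times[k - 1]
            if dt == 0:
                continue  # simultaneous handled by the potentiation branch
            dw += -params.A_minus * np.exp(-dt / params.tau_minus)
    return float(dw)


def da_concentration(r_end: float) -> DALevels:
    """Phasic dopamine levels from the valence of the actual reward.

    Positive r_end (reward burst): (da_d1, da_d2) = (2, 0.5).
    Non-positive r_end (dip):      (da_d1, da_d2) = (0.5, 2).
    Exactly these two values, no interpolation; the boundary r_end = 0
    lies on the punishment branch.
    """
    if not np.isfinite(r_end):
        raise ValueError("r_end must be finite")
    if r_end > 0:
        return DALevels(da_d1=2.0, da_d2=0.5)
    return DALevels(da_d1=0.5, da_d2=2.0)


def apply_da_modulation(
    weights: np.ndarray,
    level: float,
    w_min: float = DEFAULT_W_MIN,
    w_max: float = DEFAULT_W_MAX,
) -> np.ndarray:
    """Multiply an excitatory weight block by a dopamine level and clip.

    The caller passes in only the synapses that dopamine targets (the
    current-state cortical neuron onto the executed state-action pair).
    Zero entries (absent synapses) are fixed points of the
    multiplication and stay zero.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("dopamine modulation applies to excitatory (>= 0) weights")
    if level <= 0:
        raise ValueError(f"modulation level must be positive, got {level}")
    return np.clip(w * level, w_min, w_max)


class OnlineSTDP:
    """Incremental nearest-neighbour STDP for one synapse.

    Used where the weight trajectory matters (the single-synapse
    dopamine/STDP experiment): feed spike events tick by tick and the
    weight is updated as pairs complete.
    """

    def __init__(
        self,
        w0: float,
        params: STDPParams = STDPParams(),
        eta: float = DEFAULT_ETA,
        w_min: float = DEFAULT_W_MIN,
        w_max: float = DEFAULT_W_MAX,
        tie_epsilon: float = 0.5,
    ):
        self.w = float(w0)
        self.params = params
        self.eta = eta
        self.w_min = w_min
        self.w_max = w_max
        self.tie_epsilon = tie_epsilon
        self._last_pre: float | None = None
        self._last_post: float | None = None

    def observe(self, t: float, pre_fired: bool, post_fired: bool) -> float:
        """Register spike events at time t (ms); returns the current weight.

        Adjacent unlike spikes interact, matching
        :func:`pair_spike_trains`: a post spike potentiates against the
        latest pre spike if no post intervened, a pre spike depresses
        against the latest post spike if no pre intervened.
        """
        pre_leads = self._last_pre is not None and (
            self._last_post is None or self._last_pre >= self._last_post
        )
        post_leads = self._last_post is not None and (
            self._last_pre is None or self._last_post > self._last_pre
        )
        if post_fired and (pre_fired or pre_leads):
            dt = -self.tie_epsilon if pre_fired else self._last_pre - t
            if dt == 0:
                dt = -self.tie_epsilon
            self._apply(self.params.A_plus * np.exp(dt / self.params.tau_plus))
        if pre_fired and not post_fired and post_leads:
            dt = t - self._last_post
            if dt > 0:
                self._apply(-self.params.A_minus * np.exp(-dt / self.params.tau_minus))
        if pre_fired:
            self._last_pre = t
        if post_fired:
            self._last_post = t
        return self.w

    def modulate(self, level: float) -> float:
        """Apply a multiplicative dopamine event to the weight."""
        self.w = float(
            apply_da_modulation(np.array([self.w]), level, self.w_min, self.w_max)[0]
        )
        return self.w

    def _apply(self, raw_dw: float) -> None:
        self.w = float(np.clip(self.w + self.eta * raw_dw, self.w_min, self.w_max))
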