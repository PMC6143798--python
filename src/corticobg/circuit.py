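"""The spiking cortico-basal-ganglia-thalamo-cortical decision circuit.

Eleven populations of regular-spiking Izhikevich neurons are wired
following the anatomy of the action-selection loop:

=========  ====================  =========================================
DLPFC      N_s neurons           state input (one neuron per state)
PM         N_a neurons           premotor output, winner-take-all
Thalamus   N_a neurons           relay: cortex excitation vs GPi inhibition
StrD1      N_s * N_a             direct-pathway ("Go") striatal cells
StrD2      N_s * N_a             indirect-pathway ("No Go") striatal cells
GPi        N_a                   output nucleus (inhibits thalamus)
GPe        N_a                   indirect-pathway intermediate
STN        2                     hyperdirect pathway (only excitatory
                                 drive into the pallidal nuclei)
VTA        2                     reward / punishment dopamine cells
MOFC       1                     positive-valence orbitofrontal channel
LOFC       1                     negative-valence orbitofrontal channel
=========  ====================  =========================================

A decision clamps a constant current onto the DLPFC neuron of the
current state and runs the network until the first premotor spike; the
first PM neuron to fire is the selected action (delay coding: stronger
channels fire earlier), with lateral inhibition silencing the rivals.
Channel strength is shaped by the striatum: strong direct-pathway
weights for a state-action pair suppress that action's GPi neuron,
releasing its thalamic relay early; strong indirect-pathway weights do
the opposite.

Feedback applies phasic dopamine multiplicatively to the executed
pair's cortico-striatal weights, drives the valence-matched VTA neuron
(reward -> MOFC, punishment -> LOFC) for a fixed window, and then runs
nearest-neighbour STDP over the decision-plus-feedback spike record on
every plastic connection (DLPFC->StrD1/StrD2/PM and OFC->striatum).

Synaptic transmission convolves presynaptic spikes with a short
exponential current kernel (tau_syn, 5 ms default), the smooth-kernel
form of the instantaneous weighted spike sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .neurons import RS, IzhikevichParams, izhikevich_step
from .plasticity import (
    DEFAULT_ETA,
    DEFAULT_W_MAX,
    DEFAULT_W_MIN,
    STDPParams,
    apply_da_modulation,
    da_concentration,
    pair_spike_trains,
)

logger = logging.getLogger(__name__)

POPULATIONS = (
    "DLPFC", "PM", "Thalamus", "StrD1", "StrD2",
    "GPi", "GPe", "STN", "VTA", "MOFC", "LOFC",
)

EXCITATORY, INHIBITORY = 1, -1

#: Per-connection drive gains (dimensionless current per unit weight and
#: unit synaptic trace).  These magnitudes are a calibration of the
#: circuit's operating point — the loop is tuned so that an untrained
#: network reaches its first premotor spike within roughly a hundred
#: half-millisecond ticks and so that striatal activity arrives early
#: enough to gate the pallidal-thalamic race.
DEFAULT_GAINS = {
    "dlpfc_pm": 0.5,
    "dlpfc_strd1": 6.5,
    "dlpfc_strd2": 6.5,
    "pm_strd1": 2.0,
    "pm_strd2": 2.0,
    "strd1_gpi": 200.0,
    "strd2_gpe": 100.0,
    "gpe_gpi": 25.0,
    "dlpfc_stn": 80.0,
    "stn_gpe": 48.0,
    "stn_gpi": 48.0,
    "gpe_stn": 1.0,
    "vta_mofc": 60.0,
    "vta_lofc": 60.0,
    "mofc_strd1": 12.0,
    "mofc_strd2": 12.0,
    "lofc_strd1": 12.0,
    "lofc_strd2": 12.0,
    "gpi_thal": 60.0,
    "dlpfc_thal": 8.0,
    "thal_pm": 40.0,
    "pm_pm": 60.0,
}

#: Connections whose weights learn (STDP; the cortico-striatal pair also
#: receives multiplicative dopamine).
PLASTIC = (
    "dlpfc_strd1", "dlpfc_strd2", "dlpfc_pm",
    "mofc_strd1", "mofc_strd2", "lofc_strd1", "lofc_strd2",
)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    role: int = EXCITATORY  # output sign of the population's projections


@dataclass(frozen=True)
class ConnectionSpec:
    name: str
    source: str
    target: str
    pattern: str          # full | specific | one_to_one | lateral_inhibition | indexed
    sign: int             # +1 excitatory, -1 inhibitory
    plastic: bool = False
    index: int | None = None  # source neuron for 'indexed' pattern


def population_sizes(n_states: int, n_actions: int) -> dict[str, int]:
    """Population sizes as functions of the state/action space."""
    return {
        "DLPFC": n_states,
        "PM": n_actions,
        "Thalamus": n_actions,
        "StrD1": n_states * n_actions,
        "StrD2": n_states * n_actions,
        "GPi": n_actions,
        "GPe": n_actions,
        "STN": 2,
        "VTA": 2,
        "MOFC": 1,
        "LOFC": 1,
    }


def connection_table() -> tuple[ConnectionSpec, ...]:
    """The anatomical connection list with signs.

    Inhibitory: StrD1->GPi, StrD2->GPe, GPe->GPi, GPe->STN, GPi->Thalamus
    and PM lateral inhibition; everything else is excitatory.
    """
    c = ConnectionSpec
    return (
        c("dlpfc_pm", "DLPFC", "PM", "full", EXCITATORY, plastic=True),
        c("dlpfc_strd1", "DLPFC", "StrD1", "specific", EXCITATORY, plastic=True),
        c("dlpfc_strd2", "DLPFC", "StrD2", "specific", EXCITATORY, plastic=True),
        c("pm_strd1", "PM", "StrD1", "specific", EXCITATORY),
        c("pm_strd2", "PM", "StrD2", "specific", EXCITATORY),
        c("strd1_gpi", "StrD1", "GPi", "specific", INHIBITORY),
        c("strd2_gpe", "StrD2", "GPe", "specific", INHIBITORY),
        c("gpe_gpi", "GPe", "GPi", "one_to_one", INHIBITORY),
        c("dlpfc_stn", "DLPFC", "STN", "full", EXCITATORY),
        c("stn_gpe", "STN", "GPe", "full", EXCITATORY),
        c("stn_gpi", "STN", "GPi", "full", EXCITATORY),
        c("gpe_stn", "GPe", "STN", "full", INHIBITORY),
        c("vta_mofc", "VTA", "MOFC", "indexed", EXCITATORY, index=0),
        c("vta_lofc", "VTA", "LOFC", "indexed", EXCITATORY, index=1),
        c("mofc_strd1", "MOFC", "StrD1", "full", EXCITATORY, plastic=True),
        c("mofc_strd2", "MOFC", "StrD2", "full", EXCITATORY, plastic=True),
        c("lofc_strd1", "LOFC", "StrD1", "full", EXCITATORY, plastic=True),
        c("lofc_strd2", "LOFC", "StrD2", "full", EXCITATORY, plastic=True),
        c("gpi_thal", "GPi", "Thalamus", "one_to_one", INHIBITORY),
        c("dlpfc_thal", "DLPFC", "Thalamus", "full", EXCITATORY),
        c("thal_pm", "Thalamus", "PM", "one_to_one", EXCITATORY),
        c("pm_pm", "PM", "PM", "lateral_inhibition", INHIBITORY),
    )


def connection_mask(
    spec: ConnectionSpec, sizes: dict[str, int], n_states: int, n_actions: int
) -> np.ndarray:
    """Binary topology mask (source x target) for a connection."""
    ns, nt = sizes[spec.source], sizes[spec.target]
    m = np.zeros((ns, nt))
    if spec.pattern == "full":
        m[:] = 1.0
    elif spec.pattern == "one_to_one":
        if ns != nt:
            raise ValueError(f"{spec.name}: one_to_one needs equal sizes, got {ns}x{nt}")
        np.fill_diagonal(m, 1.0)
    elif spec.pattern == "lateral_inhibition":
        m[:] = 1.0
        np.fill_diagonal(m, 0.0)
    elif spec.pattern == "indexed":
        m[spec.index, 0] = 1.0
    elif spec.pattern == "specific":
        # state/action <-> state-action pair associations, pair = s * N_a + a
        if spec.source == "DLPFC":
            for s in range(n_states):
                m[s, s * n_actions:(s + 1) * n_actions] = 1.0
        elif spec.source == "PM":
            for a in range(n_actions):
                m[a, a::n_actions] = 1.0
        elif spec.source in ("StrD1", "StrD2"):
            for s in range(n_states):
                for a in range(n_actions):
                    m[s * n_actions + a, a] = 1.0
        else:
            raise ValueError(f"no specific pattern defined for {spec.source}")
    else:
        raise ValueError(f"unknown connection pattern {spec.pattern!r}")
    return m


@dataclass(frozen=True)
class CircuitConfig:
    """Numerical and learning parameters of the circuit simulation."""

    dt: float = 0.5                  # Euler step, ms
    i_in: float = 15.0               # DLPFC state clamp / VTA feedback drive
    tau_syn: float = 5.0             # synaptic current kernel, ms
    tau_syn_striatal: float = 40.0   # slow striato-pallidal kernel, ms
    max_ticks: int = 500             # decision timeout
    feedback_ticks: int = 320        # feedback window length (160 ms)
    init_w_low: float = 0.8          # plastic initial weight band
    init_w_high: float = 1.2
    #: orbitofrontal-striatal synapses start weak; their influence is
    #: acquired through valence-gated STDP (reward-context priming)
    init_w_ofc: float = 0.3
    #: keep membrane/trace state across decisions (the loop runs
    #: continuously, so the pallidal gate is already active when a new
    #: state is clamped); a fresh build always starts from rest
    continuous: bool = False
    w_min: float = DEFAULT_W_MIN
    w_max: float = DEFAULT_W_MAX
    eta: float = DEFAULT_ETA         # STDP learning-rate scale
    #: per-class STDP rates: orbitofrontal-striatal synapses and the
    #: cortico-premotor projection learn on faster schedules than the
    #: dopamine-dominated cortico-striatal blocks
    eta_ofc: float = 0.1
    eta_pm: float = 0.3
    stdp: STDPParams = field(default_factory=STDPParams)
    neuron: IzhikevichParams = field(default_factory=IzhikevichParams.regular_spiking)
    gains: dict = field(default_factory=lambda: dict(DEFAULT_GAINS))

    def with_gains(self, **overrides) -> "CircuitConfig":
        g = dict(self.gains)
        g.update(overrides)
        return replace(self, gains=g)


@dataclass
class DecisionRecord:
    """Outcome of one decision (and, once delivered, its feedback)."""

    state: int
    action: int
    latency: int                 # ticks from clamp onset to first PM spike
    timed_out: bool
    decision_counts: dict        # population -> spike count, decision phase
    decision_ticks: int
    r_end: float | None = None
    da_d1: float | None = None
    da_d2: float | None = None
    feedback_counts: dict | None = None
    feedback_ticks: int = 0
    ofc_weight_sums: dict | None = None  # after feedback


class NetworkState:
    """The assembled network: populations, weights, membrane state.

    Built by :func:`build_network`.  Holds per-connection signed weight
    matrices (excitatory blocks entrywise >= 0, inhibitory <= 0 via the
    sign factor applied at assembly), a plastic-synapse registry, the
    global membrane/trace vectors and the per-phase spike record.
    """

    def __init__(
        self,
        n_states: int,
        n_actions: int,
        config: CircuitConfig,
        seed: int = 0,
        ofc_enabled: bool = True,
        ablate: tuple[str, ...] = (),
    ):
        if n_states < 1 or n_actions < 2:
            raise ValueError("need n_states >= 1 and n_actions >= 2")
        unknown = set(config.gains) - {c.name for c in connection_table()}
        if unknown:
            raise ValueError(f"gains for unknown connections: {sorted(unknown)}")
        known_ablations = {"no_ofc", "no_stn", "no_dlpfc_thalamus"}
        if set(ablate) - known_ablations:
            raise ValueError(f"unknown ablation in {ablate}; known: {sorted(known_ablations)}")

        self.n_states = n_states
        self.n_actions = n_actions
        self.config = config
        self.seed = seed
        self.ofc_enabled = ofc_enabled and "no_ofc" not in ablate
        self.ablate = tuple(ablate)

        self.sizes = population_sizes(n_states, n_actions)
        self.populations = tuple(
            PopulationSpec(name, self.sizes[name]) for name in POPULATIONS
        )
        self.offsets: dict[str, int] = {}
        off = 0
        for name in POPULATIONS:
            self.offsets[name] = off
            off += self.sizes[name]
        self.n_total = off

        ss = np.random.SeedSequence(seed)
        init_ss, tie_ss = ss.spawn(2)
        self._init_rng = np.random.default_rng(init_ss)
        self._tie_rng = np.random.default_rng(tie_ss)
        #: fixed per-run permutation used to break simultaneous PM spikes
        self.tie_order = self._tie_rng.permutation(n_actions)

        self.specs = {c.name: c for c in connection_table()}
        self.masks: dict[str, np.ndarray] = {}
        self.weights: dict[str, np.ndarray] = {}
        for spec in connection_table():
            mask = connection_mask(spec, self.sizes, n_states, n_actions)
            self.masks[spec.name] = mask
            if spec.plastic:
                w = mask * self._init_rng.uniform(
                    config.init_w_low, config.init_w_high, size=mask.shape
                )
                if spec.source in ("MOFC", "LOFC"):
                    w *= config.init_w_ofc
            else:
                w = mask.copy()
            self.weights[spec.name] = w

        self._effective_gains = dict(config.gains)
        if "no_stn" in ablate:
            self._effective_gains["stn_gpe"] = 0.0
            self._effective_gains["stn_gpi"] = 0.0
        if "no_dlpfc_thalamus" in ablate:
            self._effective_gains["dlpfc_thal"] = 0.0

        self.v = np.empty(self.n_total)
        self.u = np.empty(self.n_total)
        self.trace = np.zeros(self.n_total)
        # per-neuron synaptic decay: striatal projections use the slow kernel
        tau = np.full(self.n_total, config.tau_syn)
        for pop in ("StrD1", "StrD2"):
            tau[self.pop_slice(pop)] = config.tau_syn_striatal
        self._trace_decay = np.exp(-config.dt / tau)
        self.last_valence: bool | None = None
        #: per-neuron multiplicative gain on input currents; set during the
        #: feedback window to model dopamine's population-level effect on
        #: striatal excitability (D1 facilitated / D2 suppressed under a
        #: phasic burst, the reverse under a dip)
        self._excitability: np.ndarray | None = None
        self._phase_spikes: list[np.ndarray] = []
        self._assemble()
        self.reset_dynamics()

    # -- assembly and state -------------------------------------------------
    def _assemble(self) -> None:
        g = np.zeros((self.n_total, self.n_total))
        for name, spec in self.specs.items():
            w = self.weights[name]
            gain = self._effective_gains.get(name, 0.0)
            so, to = self.offsets[spec.source], self.offsets[spec.target]
            g[so:so + w.shape[0], to:to + w.shape[1]] += spec.sign * gain * w
        self._G = g

    def reset_dynamics(self) -> None:
        """Return every membrane to rest and clear traces and spikes."""
        p = self.config.neuron
        disc = (5.0 - p.b) ** 2 - 4 * 0.04 * 140.0
        v_rest = (-(5.0 - p.b) - np.sqrt(disc)) / (2 * 0.04)
        self.v[:] = v_rest
        self.u[:] = p.b * v_rest
        self.trace[:] = 0.0
        self._phase_spikes = []

    def pop_slice(self, name: str) -> slice:
        o = self.offsets[name]
        return slice(o, o + self.sizes[name])

    def block(self, name: str) -> np.ndarray:
        """The (non-negative) weight matrix of a named connection."""
        return self.weights[name]

    # -- simulation ---------------------------------------------------------
    def tick(self, external: np.ndarray) -> np.ndarray:
        """One Euler step of the whole network; returns the fired vector."""
        cfg = self.config
        current = self._G.T @ self.trace + external
        if self._excitability is not None:
            current = current * self._excitability
        self.v, self.u, fired = izhikevich_step(self.v, self.u, current, cfg.dt, cfg.neuron)
        self.trace = self.trace * self._trace_decay + fired
        self._phase_spikes.append(fired)
        return fired

    def _external(self, state: int, feedback: bool = False) -> np.ndarray:
        ext = np.zeros(self.n_total)
        ext[self.offsets["DLPFC"] + state] = self.config.i_in
        if feedback and self.ofc_enabled and self.last_valence is not None:
            vta = self.offsets["VTA"]
            ext[vta + (0 if self.last_valence else 1)] = self.config.i_in
        return ext

    def decide(self, state: int, max_ticks: int | None = None) -> DecisionRecord:
        """Clamp a state onto DLPFC and run until the first premotor spike."""
        if not 0 <= state < self.n_states:
            raise ValueError(f"state {state} outside [0, {self.n_states})")
        if max_ticks is None:
            max_ticks = self.config.max_ticks
        if self.config.continuous:
            self._phase_spikes = []
        else:
            self.reset_dynamics()
        ext = self._external(state)
        pm = self.pop_slice("PM")
        action, latency, timed_out = None, max_ticks, False
        for k in range(1, max_ticks + 1):
            fired = self.tick(ext)
            pm_fired = np.flatnonzero(fired[pm])
            if pm_fired.size:
                # winner-take-all: first spike wins; simultaneous spikes
                # resolved by the run's fixed tie-break permutation
                order = {a: r for r, a in enumerate(self.tie_order)}
                action = int(min(pm_fired, key=lambda a: order[int(a)]))
                latency = k
                break
        if action is None:
            timed_out = True
            action = int(self._tie_rng.integers(self.n_actions))
            logger.warning(
                "no premotor spike within %d ticks for state %d; "
                "falling back to a seeded uniform draw (action %d)",
                max_ticks, state, action,
            )
        self._decision_ticks = len(self._phase_spikes)
        counts = self._phase_counts(0, self._decision_ticks)
        return DecisionRecord(
            state=state,
            action=action,
            latency=latency,
            timed_out=timed_out,
            decision_counts=counts,
            decision_ticks=len(self._phase_spikes),
        )

    def deliver_feedback(self, r_end: float, record: DecisionRecord) -> DecisionRecord:
        """Dopamine + STDP update for the decision held in ``record``.

        Applies the multiplicative dopamine factors to the executed
        state-action pair's cortico-striatal synapses, drives the
        valence-matched VTA neuron for the feedback window (activating
        MOFC on reward, LOFC on punishment), then applies STDP over the
        whole decision-plus-feedback spike record to every plastic
        connection.
        """
        if record is None or record.action is None:
            raise ValueError("deliver_feedback requires the decision record")
        cfg = self.config
        s, a = record.state, record.action
        pair = s * self.n_actions + a
        levels = da_concentration(r_end)
        for name, level in (("dlpfc_strd1", levels.da_d1), ("dlpfc_strd2", levels.da_d2)):
            w = self.weights[name]
            w[s, pair:pair + 1] = apply_da_modulation(
                w[s, pair:pair + 1], level, cfg.w_min, cfg.w_max
            )
        self.last_valence = r_end > 0

        fb_start = len(self._phase_spikes)
        ext = self._external(s, feedback=True)  # valence-matched VTA drive
        gain = np.ones(self.n_total)
        gain[self.pop_slice("StrD1")] = levels.da_d1
        gain[self.pop_slice("StrD2")] = levels.da_d2
        self._excitability = gain
        try:
            for _ in range(cfg.feedback_ticks):
                self.tick(ext)
        finally:
            self._excitability = None
        self._apply_stdp()
        self._assemble()

        record.r_end = r_end
        record.da_d1, record.da_d2 = levels.da_d1, levels.da_d2
        record.feedback_counts = self._phase_counts(fb_start, len(self._phase_spikes))
        record.feedback_ticks = cfg.feedback_ticks
        record.ofc_weight_sums = self.ofc_weight_sums()
        return record

    def _apply_stdp(self) -> None:
        cfg = self.config
        raster = np.asarray(self._phase_spikes)  # ticks x neurons
        if raster.size == 0:
            return
        times = {}  # global neuron index -> spike times (ms)

        def spike_times(idx: int, limit: int | None = None) -> np.ndarray:
            if idx not in times:
                times[idx] = np.flatnonzero(raster[:, idx]) * cfg.dt
            t = times[idx]
            if limit is not None:
                t = t[t < limit * cfg.dt]
            return t

        for name in PLASTIC:
            if not self.ofc_enabled and name.split("_")[0] in ("mofc", "lofc"):
                continue  # frozen in the ablated variant
            spec = self.specs[name]
            # the premotor projection learns from the selection event
            # itself (the decision window); reinforcement-driven synapses
            # learn from the whole decision-plus-feedback record
            limit = None
            if spec.source in ("MOFC", "LOFC"):
                eta = cfg.eta_ofc
            elif name == "dlpfc_pm":
                eta = cfg.eta_pm
                limit = getattr(self, "_decision_ticks", None)
            else:
                eta = cfg.eta
            so, to = self.offsets[spec.source], self.offsets[spec.target]
            mask = self.masks[name]
            w = self.weights[name]
            pre_active = np.flatnonzero(raster[:, so:so + mask.shape[0]].any(axis=0))
            post_active = np.flatnonzero(raster[:, to:to + mask.shape[1]].any(axis=0))
            for j in pre_active:
                pre_t = spike_times(so + j, limit)
                for i in post_active:
                    if mask[j, i] == 0:
                        continue
                    raw = pair_spike_trains(
                        pre_t, spike_times(to + i, limit), cfg.stdp, tie_epsilon=cfg.dt
                    )
                    if raw:
                        w[j, i] = float(
                            np.clip(w[j, i] + eta * raw, cfg.w_min, cfg.w_max)
                        )

    def _phase_counts(self, t0: int, t1: int) -> dict[str, int]:
        raster = np.asarray(self._phase_spikes[t0:t1])
        counts = {}
        for name in POPULATIONS:
            sl = self.pop_slice(name)
            counts[name] = int(raster[:, sl].sum()) if raster.size else 0
        return counts

    def ofc_weight_sums(self) -> dict[str, float]:
        return {
            name: float(self.weights[name].sum())
            for name in ("mofc_strd1", "mofc_strd2", "lofc_strd1", "lofc_strd2")
        }

    def spike_raster(self) -> np.ndarray:
        """Boolean (ticks x neurons) raster of the current phase."""
        return np.asarray(self._phase_spikes, dtype=bool)


def build_network(
    n_states: int,
    n_actions: int,
    config: CircuitConfig | None = None,
    seed: int = 0,
    **kwargs,
) -> NetworkState:
    """Instantiate the circuit for an ``n_states`` x ``n_actions`` task."""
    return NetworkState(n_states, n_actions, config or CircuitConfig(), seed=seed, **kwargs)


def run_decision(
    net: NetworkState, state: int, max_ticks: int | None = None
) -> tuple[int, int, DecisionRecord]:
    """Run one decision; returns (action, latency in ticks, record)."""
    rec = net.decide(state, max_ticks)
    return rec.action, rec.latency, rec


def deliver_feedback(net: NetworkState, r_end: float, record: DecisionRecord) -> NetworkState:
    net.deliver_feedback(r_end, record)
    return net


def save_hdf5(net: NetworkState, path, spikes: np.ndarray | None = None) -> None:
    """Serialise weights (and optionally a spike raster) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["n_states"] = net.n_states
        f.attrs["n_actions"] = net.n_actions
        f.attrs["seed"] = net.seed
        grp = f.create_group("weights")
        for name, w in net.weights.items():
            grp.create_dataset(name, data=w)
        if spikes is not None:
            f.create_dataset("spikes", data=np.asarray(spikes, dtype=bool))


def load_weights_hdf5(net: NetworkState, path) -> NetworkState:
    """Load weights saved by :func:`save_hdf5` into a compatible network."""
    with h5py.File(path, "r") as f:
        if f.attrs["n_states"] != net.n_states or f.attrs["n_actions"] != net.n_actions:
            raise ValueError("network shape does not match the snapshot")
        for name in net.weights:
            net.weights[name] = f["weights"][name][...]
    net._assemble()
    return net
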