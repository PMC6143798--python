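# Methods

`corticobg` simulates action selection in the cortico-basal-ganglia-
thalamo-cortical loop with spiking neurons, and trains it by combining
spike-timing-dependent plasticity (STDP) with phasic, multiplicative
dopamine modulation. This note records the model, the numerical
choices, the calibration of the circuit's operating point, what the
synthetic tasks do and do not emulate, and the known limitations.

## Neuron model and integration

Every neuron is a two-variable Izhikevich unit,

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u),        spike when v >= 30 mV, then v <- c, u <- u + d

with the regular-spiking (RS) parameter set a=0.02, b=0.2, c=-65, d=8
for all populations; inhibition is carried by negative synaptic
weights, not by separate inhibitory cell classes. Integration is
forward Euler at dt = 0.5 ms (configurable). Spike detection follows
the canonical detect-then-reset scheme: a tick that starts at or above
the peak registers the spike and applies the reset without integrating,
so the post-spike state is exactly (c, u+d). The RS resting state
(v,u) = (-70,-14) is an exact fixed point of the discretised dynamics
at zero input; unit tests compare spike counts at dt and dt/2 (<= 10%
discrepancy) and against a dt = 0.01 ms integration.

Two numerical guards: a non-finite or |v| > 500 mV state raises an
error (it indicates a misconfigured step size or gain), and the
membrane is floored at -90 mV. The floor matters because the Izhikevich
quadratic is unstable below roughly -150 mV: a strong inhibitory volley
would otherwise catapult the membrane through an unphysical rebound.
At the potassium-reversal scale the floor makes inhibition saturating
rather than explosive, and it never binds under purely excitatory
drive.

## Synaptic transmission

A presynaptic spike contributes current `gain * w * x(t)` to its
target, where the trace `x` jumps by one at each spike and decays
exponentially. The kernel time constant is tau_syn = 5 ms for most
projections and tau_syn_striatal = 40 ms for the striatal output
(StrD1 -> GPi, StrD2 -> GPe). The slow striato-pallidal kernel is the
one deliberate departure from a uniform kernel: cortical RS cells adapt
strongly under a constant clamp and fire in widely spaced waves, and a
medium-spiny-like neuron that fires once per wave can only gate its
pallidal target across waves if its inhibition outlives the wave
interval. Functionally this stands in for the slow components of
striato-pallidal GABAergic transmission. With a uniform 5 ms kernel the
gate forgets which striatal channels were active and punished actions
are re-selected; with the slow kernel a single striatal spike reliably
vetoes its pallidal channel for the rest of the decision.

## Circuit

Populations (for N_s states and N_a actions): DLPFC (N_s), PM,
thalamus, GPi, GPe (N_a each), StrD1 and StrD2 (N_s x N_a state-action
pairs), STN (2), VTA (2: one reward cell, one punishment cell), MOFC
and LOFC (1 each). Connections follow the loop's anatomy: the direct
pathway DLPFC -> StrD1 -| GPi, the indirect pathway DLPFC -> StrD2 -|
GPe -| GPi, the hyperdirect pathway DLPFC -> STN -> GPe/GPi (the only
excitatory drive into the pallidal nuclei), GPi -| thalamus -> PM,
DLPFC -> thalamus and DLPFC -> PM, GPe -| STN, PM lateral inhibition,
VTA -> MOFC (reward cell) and VTA -> LOFC (punishment cell), and full
OFC -> StrD1/StrD2 projections. "Specific" connections associate
states and actions with their pair neurons (pair index = s*N_a + a).

A decision clamps a constant current I_in = 15 onto the DLPFC neuron of
the current state and integrates the whole network from rest until the
first premotor spike; that neuron's action is executed (delay coding:
the most strongly driven channel fires earliest), and lateral
inhibition suppresses the rivals. Simultaneous first spikes are broken
by a per-run seeded permutation; if no premotor neuron fires within
max_ticks = 500 the action is a seeded uniform draw and the event is
logged. Membrane state is reset to rest between decisions — each
decision is an independent race, which keeps the mapping from weights
to choices deterministic and auditable.

### How the gate discriminates

The hyperdirect pathway turns GPi on early in each decision; the
thalamus, charging slowly from cortex, cannot fire while its GPi
channel is active. A channel opens when its StrD1 pair neuron fires and
(through the strong, slow striato-pallidal veto) silences its GPi
neuron. Because striatal first-spike time decreases with the
cortico-striatal weight, the executed action is effectively
`argmax_a W1[s, a]` with latency monotone in that weight:

* pairs reinforced by dopamine (W1 >= ~5) veto GPi within the first
  cortical wave and decide in ~28 ticks;
* naive pairs (W1 ~ 1) fire late in the first wave, their veto echoes
  into the second cortical wave, and the channel opens at ~88 ticks;
* punished pairs (W1 <= ~0.6) stay below striatal threshold, never veto,
  and their channel stays closed while any alternative remains.

This timing structure is what the gain table in
`circuit.DEFAULT_GAINS` calibrates. The gains are not measurements;
they set an operating point in which (i) an untrained network decides
within ~90 half-millisecond ticks, (ii) one dopamine punishment
(x0.5 / x2 on the pair's direct/indirect weights) removes an action
from competition in a single trial, and (iii) one reward makes the
action dominant. Points (ii) and (iii) are what make the behavioural
guarantee below structural rather than statistical.

## Learning

After each action the environment is re-evaluated and the relative
reward r_end = r_{t+1} - r_t (working memory holds r_t) gates learning:

1. **Dopamine, synapse-specific.** The executed pair's weights are
   multiplied: W1 x DA_D1, W2 x DA_D2 with (DA_D1, DA_D2) = (2, 0.5)
   for r_end > 0 and (0.5, 2) otherwise, then clipped to [0, 10].
2. **Dopamine, population-level.** During the 160 ms feedback window
   all StrD1 input currents are scaled by DA_D1 and all StrD2 currents
   by DA_D2 — a burst facilitates the whole direct pathway and
   suppresses the indirect one, a dip the reverse. Without this
   excitability effect the non-executed indirect-pathway cells keep
   firing through reward feedback and the orbitofrontal projections
   cannot specialise by valence.
3. **Valence channels.** The VTA reward cell is driven during feedback
   after positive r_end (activating MOFC), the punishment cell after
   non-positive r_end (activating LOFC).
4. **STDP.** Nearest-neighbour STDP with the update
   `A+ exp(dt/tau+)` for pre-leading pairs and `-A- exp(-dt/tau-)` for
   post-leading pairs (A+ = 0.925, A- = 0.9, tau = 20 ms) is applied to
   the plastic projections: DLPFC -> StrD1/StrD2/PM and MOFC/LOFC ->
   StrD1/StrD2. Raw pair sums are scaled by a per-class learning rate
   (eta = 0.05 cortico-striatal, eta_ofc = 0.1 orbitofrontal,
   eta_pm = 0.3 cortico-premotor) and clipped to [0, 10]; synapses
   absent from the anatomical masks never change.

Three STDP implementation choices matter and were made deliberately:

* **Pairing scheme.** Only adjacent unlike spikes in the merged train
  interact (symmetric nearest-neighbour). The asymmetric alternative —
  every presynaptic spike pairing back to the last postsynaptic one —
  lets a tonically firing presynaptic cell (MOFC under VTA drive)
  accumulate unbounded depression against a sparse postsynaptic train,
  which collapses the OFC projections to zero.
* **Premotor window.** DLPFC -> PM pairs are taken from the decision
  window only. During feedback the dopamine excitability effect opens
  every premotor channel, so feedback spikes would potentiate all
  actions of the current state equally and erase the learned
  state-to-action map; the decision window contains exactly the
  selection-relevant timing (the winner's spike follows the cortical
  drive).
* **Per-class rates.** With a single rate, either the premotor map
  never becomes action-specific (rate sized for the dopamine-dominated
  cortico-striatal blocks) or the OFC blocks saturate at the weight
  ceiling (rate sized for the premotor map). Plasticity rates differing
  across synapse classes is the biologically ordinary resolution.

Simultaneous pre/post spikes count as causal potentiation at one-tick
separation. Ties in the first-spike race, degenerate (all-zero)
networks, and empty spike windows are all exercised by tests.

## Synthetic tasks

The tasks reproduce the *abstraction* a vision pipeline would deliver,
not images. Both environments emit the geometric quantities the reward
evaluators consume, and a deterministic classifier maps observations to
discrete states.

**Window world.** The agent occupies a lattice cell (dx, dy) of
misalignments relative to a window centre (frame 320x240 px; apparent
window size shrinks with Euclidean distance; the window is displaced
opposite to the misalignment, 30 px/step horizontally, 25 px/step
vertically). Fourteen states: centred goal s0 (category C4, basic
reward +1000); four near states one step off-axis (C3, -300, scored by
border-gap imbalance); eight far compass sectors grouped by the sign
pattern of (dx, dy) (C2, -600, scored by apparent window size); and s13
"window lost" at Chebyshev distance >= 4 (C1, -1000). Rewards are
r_t = R_b + alpha * Eva with alpha = 100, which makes every move toward
the centre strictly reward-improving, across category boundaries as
well as within them. Grouping sectors by sign pattern (not by angle)
gives every state a position-independent set of improving actions, so a
policy learned once per state is correct everywhere in that state — the
property that lets a one-shot-elimination learner meet the three-trial
bound. Losing the window delivers the C1 penalty through r_end and the
agent then recovers to its previous cell; inside the lost region the
reward is a constant plateau, so no policy is definable there and the
recovery stands in for an operator pulling the vehicle back. Episodes
end only at the goal. Optional +-2 px gap jitter (off by default)
supports robustness tests.

**Obstacle world.** An obstacle at horizontal image coordinate x
(320 px frame); the agent's lateral step shifts it 40 px the opposite
way. Two states (left/right half), two actions, basic reward -500,
evaluation max(width - x, x), episode over once the obstacle leaves the
central danger band (x <= 40 or x >= 280). Runs start 40 px off-centre
on a seeded side.

What passing tests on these worlds shows: that the circuit's selection
and learning rules implement the intended algorithm under the stated
reward structure. What they do not show: robustness to real visual
noise, state misclassification, continuous dynamics of a vehicle, or
reward functions whose gradient is not monotone toward the goal.

## Metrics

* **Trials-to-correct** for a state: the number of incorrect decisions
  taken at it before its terminal streak of reward-improving decisions
  ("learned within three trials" = at most three failures). With
  one-shot elimination and <= 3 wrong actions per state this is
  structurally <= 3; the acceptance test verifies it over 15 fresh
  runs x 4 corner starts.
* **Decision latency**: ticks from clamp onset to the first premotor
  spike; experiments report the mean over the first 100 decisions of
  continuously-learning runs (weights persist across episodes within a
  run, reset between runs).
* **Firing rates**: spikes per tick per population within each
  decision (or feedback) window, minus a baseline; the default baseline
  is the first (untrained) decision's rate.

## Problem sizes

Default experiment sizes, chosen so the full suite replays comfortably
on a single CPU: 15 runs x 4 corners for the learning bound; 20 matched
seed pairs (sessions of three passes over the four corners, first 100
decisions) for the ablation latency comparison; 50 seeded runs for the
obstacle recovery statistic; 5 seeded runs x 100 decisions per variant
in the acceptance script.

## Known limitations

* **Orbitofrontal latency acceleration.** Ablating MOFC/LOFC here
  leaves mean decision latency nearly unchanged (a few percent), rather
  than slowing it by ~27%. In this implementation the OFC channels act
  during the feedback window (valence-specific priming of striatal
  learning, which does produce the expected weight orderings
  MOFC->StrD1 > MOFC->StrD2 and LOFC->StrD2 > LOFC->StrD1). Driving
  them during decisions as well does accelerate choices — but every
  operating point we found where the acceleration reaches tens of
  percent also lets the OFC excitation push once-punished striatal
  pairs back over firing threshold, breaking the three-trial learning
  bound in a noticeable fraction of episodes. The two headline
  behaviours compete for the same striatal threshold margin; the
  shipped defaults favour the learning bound. The ablation latency test
  encodes the expected ordering and currently fails on it (both
  absolute latencies remain within the +-40% tolerance band the latency test allows for these quantities).
* The gain table is a calibration artifact: magnitudes of the
  non-plastic pathways are not constrained by data.
* Tonic dopamine, conduction delays, non-RS cell classes, triplet
  STDP and eligibility traces are out of scope.
* VTA cells are silent at baseline; only phasic (feedback-window)
  activity is modelled.
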