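# corticobg

A spiking-neuron model of action selection in the cortico-basal-
ganglia-thalamo-cortical loop, with learning that combines
spike-timing-dependent plasticity (STDP) and phasic dopamine
modulation. It is aimed at computational neuroscientists and
biologically-inspired-RL researchers who want a compact, fully
inspectable basal-ganglia decision circuit that actually learns small
sensorimotor tasks.

## The model

Eleven populations of Izhikevich regular-spiking neurons
(`v' = 0.04v² + 5v + 140 − u + I`, `u' = a(bv − u)`, spike and reset at
30 mV) implement the loop's three pathways for a task with `N_s` states
and `N_a` actions:

* **direct** ("Go"): DLPFC → StrD1 ⊣ GPi — disinhibits the thalamus of
  the selected action;
* **indirect** ("No Go"): DLPFC → StrD2 ⊣ GPe ⊣ GPi — suppresses it;
* **hyperdirect**: DLPFC → STN → GPe/GPi — the only excitatory drive
  into the pallidal nuclei, holding every gate shut early in a
  decision.

A decision clamps a constant current onto the current state's DLPFC
neuron; the first premotor (PM) neuron to spike wins a lateral-
inhibition winner-take-all and its action is executed (delay coding:
stronger channels fire earlier). Learning is gated by the working-
memory relative reward

    r_end = r_{t+1} − r_t,      r_t = R_b(s_t) + α·Eva(s_t),

whose sign sets the phasic dopamine levels `(DA_D1, DA_D2) = (2, 0.5)`
on reward and `(0.5, 2)` on punishment. Dopamine multiplies the
executed state-action pair's cortico-striatal weights
(`W1 ← W1·DA_D1`, `W2 ← W2·DA_D2`), scales the excitability of the two
striatal populations during feedback, and routes a valence signal
through VTA to the orbitofrontal channels (reward → MOFC,
punishment → LOFC); STDP
(`Δw = A₊e^{Δt/τ}` pre-leading, `−A₋e^{−Δt/τ}` post-leading) shapes the
cortico-striatal, cortico-premotor and orbitofrontal-striatal synapses
around these events. Two synthetic visuomotor tasks exercise the model:
a 14-state / 4-action window-centering world and a 2-state / 2-action
obstacle-avoidance world. `docs/methods.md` has the full account.

## Worked example

A fresh network solving the obstacle task — one wrong move, a dopamine
dip, then committed correct avoidance:

```python
from corticobg import ObstacleWorld, RewardConfig, build_network, run_episode

env = ObstacleWorld(seed=4)
env.reset()
net = build_network(n_states=2, n_actions=2, seed=4)
trace = run_episode(env, net, RewardConfig.obstacle_defaults())
for e in trace.events:
    print(f"state={e.state} action={e.action} latency={e.latency:3d} ticks "
          f"r_end={e.r_end:+7.1f} DA_D1={e.da_d1} -> {'correct' if e.correct else 'wrong'}")
print("reached goal:", trace.reached_goal)
```

```
state=0 action=0 latency= 89 ticks r_end=  -40.0 DA_D1=0.5 -> wrong
state=1 action=0 latency= 92 ticks r_end=  +40.0 DA_D1=2.0 -> correct
state=1 action=0 latency= 88 ticks r_end=  +40.0 DA_D1=2.0 -> correct
state=1 action=0 latency= 88 ticks r_end=  +40.0 DA_D1=2.0 -> correct
reached goal: True
```

The first (exploratory) move pushes the obstacle toward the frame
centre, so the evaluation `Eva = max(width − x, x)` drops by 40 px and
`r_end < 0` triggers a dopamine dip that halves the direct-pathway
weight of that pair; the next decision picks the other action, is
rewarded (`r_end > 0`, direct-pathway weight doubled) and repeats until
the obstacle leaves the danger band.

The window task from the command line — 5 independent runs per corner
start, reporting steps-to-goal (mean ± variance) and the worst number
of failed trials at any state:

```bash
$ corticobg run-window --seed 1 --runs 5
             mean   var
start
lower_left   16.0  28.0
lower_right  17.0  24.5
upper_left   16.2  44.7
upper_right  13.4  22.8
max trials-to-correct: 3
```

Every state is learned within at most three failed trials: one
punishment removes an action from competition, one reward makes it
dominant. Other subcommands: `run-obstacle`, `ablate-ofc` (latency with
and without the orbitofrontal channels), `single-synapse` (the
dopamine/STDP interaction on one synapse), `report` (learned weight
maps), `fixtures`.

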