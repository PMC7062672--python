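# pioneernet

Simulation and analysis of **network spikes** — brief, all-or-none
synchronization events — in small recurrent networks of excitatory and
inhibitory leaky integrate-and-fire neurons with short-term synaptic
dynamics, and of the **pioneer neurons** whose early, reproducible spikes
ignite them. The package is for computational neuroscientists studying how
unstructured (purely random) connectivity gives rise to privileged neurons
and to rank-order ("who fires first") stimulus representations, as
observed in cultured neuronal networks on multi-electrode arrays.

## Model

Networks of 400 excitatory + 100 inhibitory LIF neurons,

&nbsp;&nbsp;dV/dt = (E_L − V)/τ_m + R_m (I_b + I_syn)/τ_m,

with threshold −50 mV, reset −65 mV, and a constant background current
that puts the equilibrium just above threshold (no noise — all variability
is deterministic network dynamics). Synapses are conductance based,
I_syn = g_exc (E_exc − V) + g_inh (E_inh − V) with g = Σ_j w_ij E_ij, and
carry finite resources: recovered → active (a presynaptic spike moves
u·R), active → inactive (τ_I), inactive → recovered (τ_rec), with
facilitating utilization u on synapses onto inhibitory targets.
Connectivity (20 % mean density) comes in three random flavours —
homogeneous (Erdős–Rényi), scale-free (preferential attachment), and
*broadly heterogeneous*, in which every neuron has individual afferent and
efferent connection densities drawn uniformly from [0, 0.2]. Excitation and
inhibition scale with factors r_E, r_I.

The analysis stack detects network spikes (excursions of the excitatory
population activity above half its maximum), measures first-spike
latencies τ relative to each NS peak, tracks a never-reset shadow voltage
V\* whose sub-threshold statistics define a neuron's *sensitivity*
CV(V\*) = std(V\*)/(V_ϑ − ⟨V\*⟩), identifies pioneers
(CV(τ) < 0.64 and |CV(V\*)| > 0.64), decodes stimulation sites from
spike-time/rank-order/rate features with a linear SVM, and quantifies
rank-order similarity with the inversion-count statistic
SOS = (1 − 2L/(n(n−1)))·100 %. A closed-form "rigid activation" theory
predicts each neuron's latency density from its V\* moments alone. See
`docs/methods.md` for the full account.

## Worked example

```python
import pioneernet as pn

cfg = pn.NetworkConfig(topology_kind="heterogeneous", seed=1)
topo = pn.make_topology(cfg)                      # 500 neurons, ~47k synapses
res = pn.simulate(topo, 62_000.0, seed=1)         # 60 s retained after warm-up
act = pn.population_activity(res)                 # Gaussian spike density, Hz
events = pn.detect_network_spikes(act)
stats = pn.ns_statistics(events, act)
```

Running `python examples/02_spontaneous_activity.py` (the code above plus
printing) gives

```
excitatory rate : 3.51 Hz per neuron
inhibitory rate : 30.79 Hz per neuron
network spikes  : 70 in 60 s (1.17 Hz)
T_INSI          : 854 ms, CV_INSI 0.52
A_max / A_mean  : 18.6
```

i.e. tonic ~30 Hz inhibition, sparse excitatory firing concentrated in
~1 Hz network spikes recurring at irregular intervals (CV ≈ 0.5), with
peak activity an order of magnitude above the mean. Exact rates scatter
widely between random realizations; that spread is a property of this
razor-balanced regime. `examples/03_pioneer_neurons.py` continues the
pipeline and prints

```
pioneers: 60/400 (15%), sorted-ID range 219-363
pioneer mean latency : -16.1 ms (negative = before the NS peak)
pioneer <V*>         : -50.1 mV (threshold -50 mV), median |CV(V*)| 1.04
silencing pioneer cohort  : largest fluctuation   5.4 x mean activity
silencing low-rank cohort : largest fluctuation  16.9 x mean activity
```

— pioneers hover within a standard deviation of threshold, fire ~16 ms
before the NS peak, and de-efferenting them (spikes kept, synapses muted)
abolishes network spikes entirely while muting an equal-size low-activity
cohort does not. The other examples cover topology structure, stimulus
decoding by cohort, the rigid-activation latency theory and the
(r_E, r_I) regime sweep; each prints what its numbers mean.

## Command line

A thin CLI wraps the same pipeline for shell use:

```bash
pioneernet simulate --config cfg.yaml --seed 1 --out run.h5
pioneernet detect   --in run.h5 --out events.csv
pioneernet metrics  --in run.h5 --events events.csv --out metrics.csv
pioneernet decode   --in run.h5 --events events.csv --cohort-size 10
pioneernet sweep    --grid grid.yaml --out sweep.csv
pioneernet toy      --metrics metrics.csv --out toy.csv
pioneernet fixture  --kind heterogeneous --scale 0.2 --out topo.h5
```

Rasters are HDF5 (or CSV) with times in ms, conductances in pS, 0-based
neuron IDs, excitatory first.

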