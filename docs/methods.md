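# Methods

## The model

`pioneernet` simulates small recurrent networks of 400 excitatory and 100
inhibitory leaky integrate-and-fire (LIF) neurons connected by
conductance-based synapses with short-term dynamics, and analyses the
brief, all-or-none synchronization events ("network spikes", NS) that such
networks generate spontaneously.

**Neurons.** Each membrane voltage obeys

    dV/dt = (E_L − V)/τ_m + R_m (I_b + I_syn)/τ_m

with threshold V_ϑ = −50 mV, reset V_res = −65 mV and an absolute
refractory period. Parameters (excitatory / inhibitory): τ_m = 30 / 10 ms,
R_m = 40 / 50 MΩ, I_b = 525 / 420 pA, τ_ref = 3 / 2 ms, E_L = −70 mV. The
constant background current places the equilibrium potential at −49 mV,
just above threshold, so isolated neurons fire tonically (closed form:
11.6 Hz excitatory, 33.6 Hz inhibitory) and the network is deterministic —
no noise process is involved. Note that the printed inhibitory parameters
give 33.6 Hz, not the 36 Hz sometimes quoted alongside them; we implement
the parameters and verify against the closed form.

**Synapses.** Each synapse carries a finite pool of resources split into
recovered (R), active (E) and inactive (I) fractions with R+E+I = 1. A
presynaptic spike instantaneously moves u·R from recovered to active
(utilization u jumps before the transfer, the transfer uses the pre-jump
R); the active fraction inactivates with τ_I (3 ms for excitatory sources,
10 ms for inhibitory sources) and recovers with τ_rec. Synapses onto
excitatory targets are depressing (mean U = 0.3, τ_rec = 0.8 s, no
facilitation); synapses onto inhibitory targets facilitate (mean U = 0.04,
τ_rec = 0.1 s, τ_facil = 1 s, u decaying between spikes). Per-edge U,
τ_rec, τ_facil are Gaussian with SD = mean/2, redrawn until inside the
physical range (resampling avoids a point mass at the bound). Conductances
are g = Σ_j w_ij E_ij per transmitter class, with reversal potentials 0 mV
(exc) and −70 mV (inh) and a uniform 0.5 ms axonal delay. Weights are
clipped Gaussians (SD = mean/2, resampled until positive) with class means
per topology (e.g. ω_ee = 1000 pS for heterogeneous, 1150 pS homogeneous,
1450 pS scale-free; ω_ei = 8500–9500 pS; ω_ie = 5 pS; ω_ii = 200 pS),
scaled by r_E (excitatory sources) and r_I (inhibitory sources).

**Topologies** (all targeting 20 % mean directed density):

* *homogeneous* — directed Erdős–Rényi, each ordered pair independently;
* *scale-free* — Barabási–Albert preferential attachment (networkx), each
  undirected edge emitted in both directions, attachment count m solved
  from m(N−m) = ρN(N−1)/2 (m = 56 at N = 500). Node labels are randomly
  permuted before E/I classes are assigned, so class is independent of
  degree (raw BA indices correlate with degree);
* *heterogeneous* — every neuron draws four personal densities
  (λ_pre,exc, λ_post,exc, λ_pre,inh, λ_post,inh ~ U[0, δ], δ = 0.2); each
  ordered pair (i, j) draws ξ, η ~ U[0,1], the ξ test creating j→i under
  i's afferent density for j's class and the η test creating i→j under
  i's efferent density for j's class, OR-combined. Expected density is
  1−(1−δ/2)² ≈ 0.19. The owner of λ_post is not uniquely determined by
  the procedure's prose; we assign it to the presynaptic neuron, which
  makes in- and out-degrees independent (measured |r| < 0.1). Self
  connections are excluded in all generators.

## Numerics

Time is discretized at dt = 0.5 ms. Voltages advance with the first-order
exponential (exponential-Euler) scheme, conductances held constant across
each step; with zero synaptic input this reproduces the closed-form LIF
inter-spike interval to within one step (tested). Spikes are detected at
step boundaries (no sub-dt interpolation), reset immediately, and reach
their targets one step later.

The synaptic (E, I) pair is linear and autonomous between presynaptic
spike arrivals, so it is advanced with its exact solution

    E(t+Δ) = E e^(−Δ/τ_I)
    I(t+Δ) = I e^(−Δ/τ_rec) + E · τ_rec/(τ_rec−τ_I) · (e^(−Δ/τ_rec) − e^(−Δ/τ_I))

lazily, only when a spike arrives at the edge or a sample is recorded;
R := 1 − E − I by construction, which keeps the conservation law exact to
rounding (tested at 1e−9) and all fractions in [0, 1]. We deliberately do
*not* freeze E across the step when integrating I: doing so overfills the
inactive pool (the one-step map then has E-column sum a + c ≈ 1.013 at
dt = 0.5 ms, τ_I = 3 ms) and lets R drift negative. Per-neuron
conductances decay by the class factor e^(−dt/τ_I) each step and receive
jump increments w·ΔE on arrivals, which reproduces Σ w_ij E_ij(t) exactly
while keeping the per-step cost O(N) instead of O(edges). The kernel is
JIT-compiled with numba; a 100-s, 500-neuron simulation takes a few
seconds on one core.

A shadow "star" voltage V* integrates the same equation with the same
conductances but is never reset or clamped; because conductances are
presynaptic quantities, sharing them with the reset voltage is exact.
Initial V (and V*) are uniform on [V_res, V_ϑ); synapses start fully
recovered (R = 1, u = 0, so a first spike utilizes exactly U). The first
2 s of every simulation are discarded from all outputs (onset transient);
output times are absolute, so retained samples start at the warm-up
boundary.

**Stimulation** forces a simultaneous spike in every neuron of a site
(reset and refractory applied, efferent synapses engaged — a failed
stimulation still consumes resources); forced spikes are flagged and all
analysis layers exclude them. An event hitting a refractory neuron is
logged as undelivered and produces no spike. **Silencing**
(de-efferentiation) retains a neuron's spikes but suppresses all of its
postsynaptic effects; its efferent resource states simply recover.

## Analyses

* **Population activity** A(t): Gaussian-kernel spike density (σ = 3 ms,
  sampled at 0.1 ms), normalized so its time integral equals the spike
  count; excitatory population by default.
* **Network spikes**: maximal excursions above θ_high = 0.5·max A(t);
  smaller fluctuations above θ_low = 1.1·mean A(t). θ_high is
  per-recording; the CLI can freeze it from a reference run for cross-run
  comparability. Interval statistics: T_INSI (mean inter-peak interval),
  CV_INSI (SD/mean, sample SD). "Between NS" always means more than 35 ms
  from every peak. The peak-amplitude histogram is flagged bimodal when
  mass sits below 10× and above 40× the mean with an empty gap; the
  NS-initiation threshold estimate is the largest peak below the gap
  (located at the largest ratio between consecutive sorted peaks), or a
  lower bound only when no high mode exists.
* **Evoked vs spontaneous**: a stimulation is successful when the next NS
  peak follows within a 100 ms window (configurable; the two clusters in
  the time-since-last vs time-to-next scatter are separated by a wide
  margin, so the exact window matters little); a uniform-time surrogate
  scatter is emitted alongside for inspection.
* **Latencies**: spikes are attributed to the nearest NS peak and qualify
  within (−80, +35] ms; the earliest qualifying spike per (neuron, NS)
  defines τ. Consistency 1/CV(τ) = ⟨−τ⟩/std(τ); the pioneer criterion
  uses its reciprocal, CV(τ) = std(τ)/⟨−τ⟩ < 0.64 together with the
  sensitivity criterion |CV(V*)| = |std(V*)/(V_ϑ−⟨V*⟩)| > 0.64, both from
  between-NS V* samples (recorded every 5 ms by default, ~20 000 samples
  per 100 s). At least two latencies are required for CV(τ); neurons
  whose mean latency is not negative are never pioneers.
* **Spike-triggered deviation** Γ_i(τ): mean of A(t_spike+τ) − ⟨A⟩ over a
  neuron's between-NS spikes, reported at negative lags.
* **PSP estimates**: closed-form single-spike amplitude at
  t_max = τ_m τ_I/(τ_m−τ_I)·ln(τ_m/τ_I) and Poisson steady state, with
  the driving force frozen at the target's between-NS mean V*, and
  depression entering as 1/(1+U τ_rec ν). The often-quoted shortcut
  ⟨W⟩_ss ≈ τ_m ν W(t_max) is only good to ~30 % at these constants
  (tested as such).
* **Spectra and correlations**: NSs removed, disjoint 20-s bins;
  per-neuron periodograms of the spike comb at 0.1 ms resolution
  (flat at the rate for Poisson trains); zero-lag normalized scalar
  products of 0.5 ms-binned trains for all excitatory pairs that both
  spike between NSs.
* **Decoding**: four features per NS over a 100 ms window anchored at the
  stimulation (spontaneous NSs: at t_peak − 100 ms, a convention needed
  because spontaneous events have no stimulation anchor) — first-spike
  times, rank order (earliest = 1, missing filled at the top ranks in
  ascending ID order, ties by ID), per-neuron rates, and cohort-summed
  2-ms temporal profiles (plus a k-bin interpolation between rate and
  timing codes). Classifier: linear-kernel SVC, stratified 50/50 split,
  20 repeats (the split protocol and hyperparameters are not fixed by the
  problem; defaults are configurable). Spike-order similarity:
  SOS = (1 − 2L/(n(n−1)))·100 % with L the inversion count (merge-sort),
  identical orders 100 %, reversed 0 %.
* **E/I sweep**: weights scaled by (r_E, r_I); per point, regimes are
  labelled transitional when A_max/A_mean ≥ 30 (pronounced all-or-none
  events), tonic when events are frequent and regular (NS rate > 2 Hz and
  CV_INSI < 0.3 — numeric stand-ins for a verbal distinction, both
  configurable), else asynchronous.
* **Rigid-activation latency theory**: all neurons' V* distributions are
  translated by the same Gaussian bump u(t) = α e^(−t²/2σ_NS²)
  (α = 0.56 mV, σ_NS = 23 ms); the latency density is the half-wave
  rectified threshold flux p(τ) ∝ [u̇]₊ e^(−(V_ϑ−⟨V⟩−u(τ))²/2σ²),
  trapezoid-normalized on a 0.1 ms grid over [−5σ_NS, 0] and zero for
  τ ≥ 0. It is verified bin-wise against direct Monte-Carlo simulation of
  frozen-voltage threshold crossings.

## Problem sizes and what the tests show

The test suite runs scaled-down fixtures (80E+20I) for code-path checks —
NS dynamics are population-size sensitive, so fixtures validate mechanics,
not quantitative claims — plus full-size (400E+100I) runs of 100–200 s
for the statistical checks, averaged over the first three to five seeds.
The acceptance script averages ten 300-s realizations. These sizes are the
package's default study conditions; longer recordings and more
realizations reduce the (large) realization-to-realization spread but do
not change any estimator.

The spontaneous regime is razor-balanced: the inhibitory drive places the
mean excitatory equilibrium within a few tenths of a millivolt of
threshold, so small realization differences reshuffle how many neurons
sit tonically above threshold. Consequently single-realization rates
(excitatory ~1.7–3.6 Hz, NS ~0.05–1.5 Hz across seeds) scatter as widely
as the originally reported spreads, and the relative height of NS peaks
over the mean activity varies accordingly. Structural results — the
latency/sensitivity hierarchy, pioneer identification, the silencing
effect, the decoding contrast, the topology ordering of pioneer
fractions — are robust across realizations; exact rate triples are not.

## Known limitations

* No sub-dt spike timing, no noise currents, no conduction-delay
  heterogeneity (all outside the model).
* The synthetic decoding fixture plants deterministic orderings; it
  bounds what the classifier machinery can do, not what a given network
  achieves.
* The heterogeneous generator's λ_post ownership is a documented
  interpretation (see above); the alternative reading changes per-neuron
  degree correlations but not the mean density.
* Pioneer fractions depend on recording length through the number of
  latency samples per neuron; 200-s recordings are used where fractions
  are compared across topologies.
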