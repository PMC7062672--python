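"""Closed-form latency prediction under a rigid activation time course.

Every neuron's between-NS star-voltage distribution N(<V*>, sigma^2) is
translated by the same Gaussian bump u(t) (amplitude 0.56 mV, width
23 ms). The predicted first-spike latency density is the rectified
probability flux through threshold. This isolates the effect of a
neuron's sub-threshold statistics from the network's own NS time course:
more sensitive neurons (larger sigma, mean closer to threshold) are
predicted to fire earlier and more consistently.
"""
import numpy as np

import pioneernet as pn

params = pn.ToyParams()  # alpha = 0.56 mV, sigma_NS = 23 ms

neurons = [
    ("sensitive (pioneer-like)", -50.30, 0.30),
    ("intermediate", -50.60, 0.20),
    ("insensitive", -51.20, 0.12),
]
print(f"{'neuron':26s} {'<V*> mV':>8s} {'sd mV':>6s} "
      f"{'<tau> ms':>9s} {'1/CV(tau)':>10s}")
for name, mean_v, sd_v in neurons:
    mt, icv = pn.predicted_latency_stats([mean_v], [sd_v], params)
    print(f"{name:26s} {mean_v:8.2f} {sd_v:6.2f} {mt[0]:9.1f} {icv[0]:10.2f}")

# the flux formula agrees with direct simulation of threshold crossings
mean_v, sd_v = -50.3, 0.25
draws = pn.monte_carlo_latencies(mean_v, sd_v, params, n_draws=100_000,
                                 seed=0)
t, dens = pn.latency_density(mean_v, sd_v, params)
mc_mean = draws.mean()
th_mean = np.trapezoid(t * dens, t)
print(f"\nMonte-Carlo mean latency {mc_mean:.1f} ms vs "
      f"flux-formula {th_mean:.1f} ms "
      f"({draws.size} crossing draws)")

print("\nNeurons hovering close to threshold are predicted to fire tens "
      "of ms before the activation peak, with high consistency - the "
      "pioneer phenotype - even when the imposed activity time course is "
      "identical for all neurons.")
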