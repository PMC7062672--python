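"""Identify pioneer neurons and show that silencing them removes NSs.

Pioneers fire early and reliably during NS build-up: consistency
CV(tau) < 0.64 together with sensitivity |CV(V*)| > 0.64, where V* is the
never-reset shadow voltage sampled between NSs. De-efferenting the
pioneer cohort (their spikes remain, their synapses are muted) abolishes
large synchronization events, while muting an equal-size cohort of
low-activity neurons does not.
"""
import numpy as np

import pioneernet as pn

cfg = pn.NetworkConfig(topology_kind="heterogeneous", seed=1)
topo = pn.make_topology(cfg)
res = pn.simulate(topo, 102_000.0, seed=1, record_vstar=True)
act = pn.population_activity(res)
events = pn.detect_network_spikes(act)

df = pn.compute_neuron_metrics(res, act, events)
pioneers = df.neuron_id[df.is_pioneer].to_numpy()
print(f"pioneers: {pioneers.size}/400 "
      f"({100*pioneers.size/400:.0f}%), sorted-ID range "
      f"{df.sorted_id[df.is_pioneer].min()}-{df.sorted_id[df.is_pioneer].max()}")
pio_rows = df[df.is_pioneer]
print(f"pioneer mean latency : {pio_rows.mean_latency_ms.mean():.1f} ms "
      "(negative = before the NS peak)")
print(f"pioneer <V*>         : {pio_rows.star_mean_mV.mean():.1f} mV "
      f"(threshold -50 mV), median |CV(V*)| "
      f"{pio_rows.cv_vstar.abs().median():.2f}")

ro = pn.sort_by_rate(res)
low = ro.band(60, 60 + pioneers.size - 1)
for name, cohort in (("pioneer cohort", pioneers), ("low-rank cohort", low)):
    sil = pn.simulate(topo, 102_000.0, seed=1, silenced=cohort)
    a = pn.population_activity(sil)
    peaks = pn.detect_fluctuations(a)
    rel = peaks / a.a_mean
    print(f"silencing {name:16s}: largest fluctuation "
          f"{rel.max():5.1f} x mean activity")

print("\nOnly the pioneer cohort is load-bearing for NS ignition: without "
      "its synapses the network never amplifies fluctuations into a full "
      "synchronization event.")
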