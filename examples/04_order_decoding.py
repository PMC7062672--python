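"""Decode the stimulation site from activity around evoked NSs.

Five disjoint sites of 10 excitatory neurons are stimulated by a 1-Hz
Poisson process (each event forces one spike per site neuron). For each
evoked NS, the 100 ms after the stimulation (excluding the forced spikes
themselves) is summarized by four features per cohort of 10
activity-sorted neurons, and a linear SVM decodes which site was
stimulated. Chance is 20%.
"""
import numpy as np

import pioneernet as pn

cfg = pn.NetworkConfig(topology_kind="heterogeneous", seed=1)
topo = pn.make_topology(cfg)
sites = pn.make_random_sites(topo, n_sites=5, site_size=10, seed=1)
prot = pn.make_poisson_protocol(sites, rate_hz=1.0, duration_ms=302_000.0,
                                seed=1)
res = pn.simulate(topo, 302_000.0, protocol=prot, seed=1)
act = pn.population_activity(res)
events = pn.detect_network_spikes(act)
events, outcomes, _ = pn.classify_ns(events, prot,
                                     analysis_span=(res.warmup, res.duration))
n_evoked = sum(ev.site >= 0 for ev in events)
print(f"{prot.n_events} stimulations, {len(events)} NS, {n_evoked} evoked\n")

ro = pn.sort_by_rate(res)
feats = ("spike_time", "spike_order", "neuronal_rates", "temporal_rates")
print(f"{'cohort (sorted IDs)':>20s} " +
      " ".join(f"{f:>14s}" for f in feats))
for start in range(240, 400, 20):
    cohort = ro.band(start, start + 9)
    ds = pn.extract_features(res, events, cohort, stim_outcomes=outcomes)
    accs = [pn.classify_sites(ds, feature=f, seed=0) for f in feats]
    print(f"{start:>12d}-{start+9:<7d} " +
          " ".join(f"{100*a:13.1f}%" for a in accs))

print("\nSpike-timing based features decode the stimulated site well "
      "above chance for cohorts in the pioneer range, where rank orders "
      "are reproducible within a site and distinct between sites; for "
      "the most active cohorts the advantage of timing over rates "
      "disappears. The location of the best cohort varies between "
      "network realizations.")
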