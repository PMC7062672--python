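"""Shared fixtures: scaled-down networks for fast tests and one full-size
heterogeneous realization reused by the slower statistical checks."""
import numpy as np
import pytest

import pioneernet as pn


@pytest.fixture(scope="session")
def small_topo():
    """80E+20I heterogeneous fixture network."""
    topo, _ = pn.make_fixture("heterogeneous", scale=0.2, seed=3)
    return topo


@pytest.fixture(scope="session")
def small_run(small_topo):
    """20 s of the small network with all traces recorded."""
    edges = np.linspace(0, small_topo.n_edges - 1, 200).astype(int)
    return pn.simulate(small_topo, 22_000.0, seed=3,
                       record_vstar=True, record_v=True,
                       record_resources=True, record_g=True,
                       synapse_sample_edges=edges)


@pytest.fixture(scope="session")
def small_activity(small_run):
    return pn.population_activity(small_run)


@pytest.fixture(scope="session")
def small_events(small_activity):
    return pn.detect_network_spikes(small_activity)


@pytest.fixture(scope="session")
def full_het_run():
    """One full-size (400E+100I) heterogeneous realization, 100 s retained,
    with star voltage and a stratified sample of synapse states."""
    cfg = pn.NetworkConfig(topology_kind="heterogeneous", seed=1)
    topo = pn.make_topology(cfg)
    edges = np.linspace(0, topo.n_edges - 1, 1000).astype(int)
    res = pn.simulate(topo, 102_000.0, seed=1, record_vstar=True,
                      synapse_sample_edges=edges, resource_stride_ms=20.0)
    return topo, res


@pytest.fixture(scope="session")
def full_het_analysis(full_het_run):
    _, res = full_het_run
    act = pn.population_activity(res)
    events = pn.detect_network_spikes(act)
    return res, act, events


def synthetic_result(spike_neuron, spike_time, n_exc, n_inh=1, dt=0.5,
                     duration=None, warmup=0.0, forced=None):
    """Assemble a SimulationResult from explicit spike lists."""
    spike_time = np.asarray(spike_time, dtype=float)
    spike_neuron = np.asarray(spike_neuron, dtype=np.int32)
    order = np.argsort(spike_time, kind="stable")
    if duration is None:
        duration = (spike_time.max() if spike_time.size else 0.0) + 1000.0
    if forced is None:
        forced = np.zeros(spike_time.size, dtype=bool)
    return pn.SimulationResult(
        n_exc=n_exc, n_inh=n_inh, dt=dt, duration=float(duration),
        warmup=float(warmup),
        spike_neuron=spike_neuron[order], spike_time=spike_time[order],
        spike_forced=np.asarray(forced, dtype=bool)[order])


@pytest.fixture
def make_result():
    return synthetic_result


def planted_decoding_problem(n_sites=5, cohort_size=10, reps_per_site=8,
                             seed=0):
    """Synthetic raster in which each stimulation site deterministically
    triggers a distinct rank order of the cohort while every neuron fires
    exactly once per window (so rate features carry no site information).

    Returns (result, events, outcomes, cohort).
    """
    from pioneernet.events import NetworkSpikeEvent, StimulationOutcome

    rng = np.random.default_rng(seed)
    cohort = np.arange(cohort_size)
    site_orders = [rng.permutation(cohort_size) for _ in range(n_sites)]
    offsets = 5.0 + 2.0 * np.arange(cohort_size)  # shared spike-time multiset
    neurons, times = [], []
    events, outcomes = [], []
    t = 1000.0
    k = 0
    site_seq = rng.permutation(np.repeat(np.arange(n_sites), reps_per_site))
    for site in site_seq:
        order = site_orders[site]
        for pos, neuron in enumerate(order):
            neurons.append(neuron)
            times.append(t + offsets[pos])
        peak = t + 60.0
        events.append(NetworkSpikeEvent(
            t_peak=peak, a_max=100.0, t_onset=peak - 10, t_offset=peak + 10,
            label=f"evoked_site_{site}", site=int(site)))
        outcomes.append(StimulationOutcome(
            time=t, site=int(site), since_last_ns=500.0, to_next_ns=60.0,
            success=True, ns_index=k))
        t += 500.0
        k += 1
    res = synthetic_result(neurons, times, n_exc=cohort_size,
                           duration=t + 1000.0)
    return res, events, outcomes, cohort
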