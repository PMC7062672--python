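"""Topology generators: densities, replay oracles, parameter tables."""
import numpy as np
import pytest

import pioneernet as pn
from pioneernet.config import ConfigurationError, substream
from pioneernet.topology import calibrate_ba_m, degree_profile


def test_homogeneous_density_matches_target():
    dens = []
    for seed in range(20):
        cfg = pn.NetworkConfig(topology_kind="homogeneous", seed=seed,
                               n_exc=400, n_inh=100)
        dens.append(pn.make_homogeneous(cfg).density())
    n_pairs = 500 * 499
    se = np.sqrt(0.2 * 0.8 / n_pairs)
    assert abs(np.mean(dens) - 0.20) < 3 * se / np.sqrt(20) + 1e-3


def test_zero_density_gives_empty_graph():
    cfg = pn.NetworkConfig(topology_kind="homogeneous", density=0.0,
                           n_exc=5, n_inh=2)
    assert pn.make_homogeneous(cfg).n_edges == 0
    cfg = pn.NetworkConfig(topology_kind="heterogeneous", density=0.0,
                           n_exc=5, n_inh=2)
    assert pn.make_heterogeneous(cfg).n_edges == 0


def test_homogeneous_replay_oracle():
    """Edge set equals a literal Bernoulli replay with the same substream."""
    cfg = pn.NetworkConfig(topology_kind="homogeneous", density=0.5,
                           n_exc=8, n_inh=2, seed=11)
    topo = pn.make_homogeneous(cfg)
    rng = substream(11, "topology")
    draws = rng.random((10, 10))
    expected = set()
    for i in range(10):       # rows = target
        for j in range(10):   # cols = source
            if i != j and draws[i, j] < 0.5:
                expected.add((j, i))
    assert set(zip(topo.pre.tolist(), topo.post.tolist())) == expected


def test_heterogeneous_replay_oracle():
    """Adjacency equals a step-by-step replay of the two-step procedure."""
    n, delta, seed = 20, 0.3, 7
    cfg = pn.NetworkConfig(topology_kind="heterogeneous", density=delta,
                           n_exc=15, n_inh=5, seed=seed)
    topo = pn.make_heterogeneous(cfg)
    rng = substream(seed, "topology")
    lam = rng.uniform(0.0, delta, size=(n, 4))
    xi = rng.random((n, n))
    eta = rng.random((n, n))
    is_exc = lambda q: q < 15
    edges = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # xi test of pair (i, j): j -> i with i's afferent density
            lam_pre = lam[i, 0] if is_exc(j) else lam[i, 2]
            if xi[i, j] < lam_pre:
                edges.add((j, i))
            # eta test of pair (i, j): i -> j with i's efferent density
            lam_post = lam[i, 1] if is_exc(j) else lam[i, 3]
            if eta[i, j] < lam_post:
                edges.add((i, j))
    assert set(zip(topo.pre.tolist(), topo.post.tolist())) == edges


def test_scale_free_base_case_is_tree():
    # n=5 at density 0.4 calibrates to m=1: a BA tree with 4 undirected edges
    assert calibrate_ba_m(5, 0.4) == 1
    cfg = pn.NetworkConfig(topology_kind="scale_free", density=0.4,
                           n_exc=4, n_inh=1)
    topo = pn.make_scale_free(cfg)
    assert topo.n_edges == 8  # 4 undirected edges, both directions


def test_scale_free_density_and_heavy_tail():
    """Directed density hits 20% and hubs make the degree tail much heavier
    than the Erdos-Renyi tail at the same density.

    At this density the attachment count is m=56, which compresses the
    power-law tail: the max/mean total-degree ratio sits near 2.7, far
    above the ~1.3 of a binomial degree distribution.
    """
    heavy = 0
    dens = []
    for seed in range(20):
        cfg = pn.NetworkConfig(topology_kind="scale_free", seed=seed)
        topo = pn.make_scale_free(cfg)
        dens.append(topo.density())
        total_deg = topo.in_degrees() + topo.out_degrees()
        er = pn.make_topology(pn.NetworkConfig(topology_kind="homogeneous",
                                               seed=seed))
        er_deg = er.in_degrees() + er.out_degrees()
        heavy += total_deg.max() / total_deg.mean() > 2.0 \
            and total_deg.max() / total_deg.mean() > 1.5 * er_deg.max() / er_deg.mean()
    assert abs(np.mean(dens) - 0.20) < 0.01
    assert heavy >= 18  # in >= 90% of seeds


def test_all_generators_hit_target_density():
    for kind, lo, hi in [("homogeneous", 0.19, 0.21),
                         ("scale_free", 0.19, 0.21),
                         ("heterogeneous", 0.18, 0.21)]:
        dens = [pn.make_topology(pn.NetworkConfig(topology_kind=kind,
                                                  seed=s)).density()
                for s in range(20)]
        assert lo <= np.mean(dens) <= hi, kind


def test_topology_determinism():
    for kind in ("homogeneous", "scale_free", "heterogeneous"):
        cfg = pn.NetworkConfig(topology_kind=kind, seed=5)
        a = pn.make_topology(cfg)
        b = pn.make_topology(pn.NetworkConfig(topology_kind=kind, seed=5))
        assert np.array_equal(a.pre, b.pre)
        assert np.array_equal(a.post, b.post)
        assert np.array_equal(a.weight, b.weight)
        assert np.array_equal(a.U, b.U)


def test_heterogeneous_degree_structure():
    """Broad, mutually independent in-/out-degrees versus homogeneous."""
    var_het, var_hom, corrs = [], [], []
    for seed in range(10):
        het = pn.make_topology(pn.NetworkConfig(
            topology_kind="heterogeneous", seed=seed))
        hom = pn.make_topology(pn.NetworkConfig(
            topology_kind="homogeneous", seed=seed))
        din, dout = het.in_degrees(), het.out_degrees()
        var_het.append(din.var())
        var_hom.append(hom.in_degrees().var())
        corrs.append(np.corrcoef(din, dout)[0, 1])
    assert np.mean(var_het) > 3 * np.mean(var_hom)
    assert abs(np.mean(corrs)) < 0.1


def test_weights_are_positive_clipped_gaussians():
    cfg = pn.NetworkConfig(topology_kind="homogeneous", seed=2)
    topo = pn.make_homogeneous(cfg)
    assert (topo.weight > 0).all()
    # Monte-Carlo oracle for the clipped-normal mean of ee weights
    klass = topo.edge_class()
    ee_w = topo.weight[klass == "ee"]
    rng = np.random.default_rng(123)
    ref = rng.normal(1150.0, 575.0, size=200_000)
    ref = ref[ref > 0]
    assert abs(ee_w.mean() - ref.mean()) < 4 * ee_w.std() / np.sqrt(ee_w.size)
    assert ee_w.mean() > 1150.0  # clipping at zero biases the mean upward


def test_weight_scaling_with_r_factors():
    cfg = pn.NetworkConfig(topology_kind="heterogeneous", seed=4,
                           r_E=2.0, r_I=0.5)
    topo = pn.make_topology(cfg)
    klass = topo.edge_class()
    assert np.isclose(topo.weight[klass == "ee"].mean(), 2.0 * 1000.0,
                      rtol=0.05)
    assert np.isclose(topo.weight[klass == "ei"].mean(), 0.5 * 8500.0,
                      rtol=0.05)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        pn.NetworkConfig(r_E=0.0)
    with pytest.raises(ConfigurationError):
        pn.NetworkConfig(n_exc=0)
    with pytest.raises(ConfigurationError):
        pn.NetworkConfig(density=1.5)
    with pytest.raises(ConfigurationError):
        pn.NetworkConfig(topology_kind="smallworld")
    with pytest.raises(ConfigurationError):
        cfg = pn.NetworkConfig(topology_kind="heterogeneous")
        pn.make_homogeneous(cfg)


def test_synapse_parameter_classes():
    cfg = pn.NetworkConfig(topology_kind="heterogeeous"
                           if False else "heterogeneous", seed=6)
    topo = pn.make_topology(cfg)
    klass = topo.edge_class()
    # synapses onto excitatory targets: depressing, no facilitation
    onto_exc = np.isin(klass, ["ee", "ei"])
    assert (topo.tau_facil[onto_exc] == 0.0).all()
    assert (topo.tau_facil[~onto_exc] > 0.0).all()
    assert ((topo.U > 0) & (topo.U <= 1)).all()
    assert (topo.tau_rec > 0).all()
    # tau_I keyed by source class
    from_exc = topo.pre < topo.n_exc
    assert (topo.tau_I[from_exc] == 3.0).all()
    assert (topo.tau_I[~from_exc] == 10.0).all()
    # class means: U ~0.3 onto exc, ~0.04 onto inh (clipping biases slightly)
    assert abs(topo.U[onto_exc].mean() - 0.31) < 0.03
    assert abs(topo.U[~onto_exc].mean() - 0.042) < 0.01


def test_ie_u_mean_matches_clipped_normal_oracle():
    cfg = pn.NetworkConfig(topology_kind="homogeneous", seed=9)
    topo = pn.make_topology(cfg)
    klass = topo.edge_class()
    u_ie = topo.U[klass == "ie"]
    rng = np.random.default_rng(42)
    ref = rng.normal(0.04, 0.02, size=500_000)
    ref = ref[(ref > 0) & (ref <= 1)]
    assert abs(u_ie.mean() - ref.mean()) < 4 * u_ie.std() / np.sqrt(u_ie.size)


def test_degree_profile_manual_graph():
    topo = pn.NetworkTopology(n_exc=2, n_inh=1,
                              pre=np.array([0, 2], dtype=np.int32),
                              post=np.array([1, 1], dtype=np.int32))
    d_exc, d_inh, ratio = degree_profile(topo, omega_ee0=1000.0)
    assert d_exc.tolist() == [0, 1, 0]
    assert d_inh.tolist() == [0, 1, 0]
    assert np.isnan(ratio[0])          # isolated neuron: undefined ratio
    assert ratio[1] == 1000.0 * 1 / 1


def test_self_connections_rejected():
    with pytest.raises(ConfigurationError):
        pn.NetworkTopology(n_exc=2, n_inh=1,
                           pre=np.array([0], dtype=np.int32),
                           post=np.array([0], dtype=np.int32))
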