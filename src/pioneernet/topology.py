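"""Random directed E/I connection topologies and synapse parameter tables.

Three generators are provided, all targeting the same mean directed
connection density (default 20 %):

* ``make_homogeneous`` — Erdos–Renyi: every ordered pair is connected
  independently with probability equal to the density.
* ``make_scale_free`` — Barabasi–Albert preferential attachment; every
  undirected edge is emitted in both directions, and the attachment count
  ``m`` is calibrated so the directed density matches the target.
* ``make_heterogeneous`` — every neuron carries four individual density
  parameters (afferent/efferent, per source/target class) drawn uniformly
  from [0, delta]; ordered pairs are then connected by two independent
  Bernoulli mechanisms combined by logical OR.  This yields broad,
  mutually independent in- and out-degree distributions without hubs.

Edge direction convention: an edge (pre, post) is the projection
pre -> post; matrix views are indexed ``[post, pre]`` so that the
conductance of neuron i sums its row.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .config import (
    ConfigurationError,
    NetworkConfig,
    SYNAPSE_PARAM_MEANS,
    TAU_I_FROM_EXC,
    TAU_I_FROM_INH,
    substream,
)

EXC, INH = 0, 1


@dataclass
class NetworkTopology:
    """Directed weighted E/I graph with per-edge short-term synapse params.

    Edges are stored as parallel arrays sorted by (pre, post).  Weight and
    parameter arrays are filled by :func:`assign_weights` and
    :func:`sample_synapse_params`.
    """

    n_exc: int
    n_inh: int
    pre: np.ndarray            # int32, source neuron of each edge
    post: np.ndarray           # int32, target neuron of each edge
    weight: Optional[np.ndarray] = None       # pS
    U: Optional[np.ndarray] = None            # utilization fraction
    tau_rec: Optional[np.ndarray] = None      # ms
    tau_facil: Optional[np.ndarray] = None    # ms (0 => non-facilitating)
    kind: str = "custom"
    config: Optional[NetworkConfig] = None

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int32)
        self.post = np.asarray(self.post, dtype=np.int32)
        if np.any(self.pre == self.post):
            raise ConfigurationError("self-connections are not allowed")
        order = np.lexsort((self.post, self.pre))
        if not np.array_equal(order, np.arange(order.size)):
            self.pre = self.pre[order]
            self.post = self.post[order]
            for name in ("weight", "U", "tau_rec", "tau_facil"):
                arr = getattr(self, name)
                if arr is not None:
                    setattr(self, name, np.asarray(arr)[order])

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def n_edges(self) -> int:
        return int(self.pre.size)

    @property
    def neuron_class(self) -> np.ndarray:
        """0 for excitatory, 1 for inhibitory; excitatory IDs come first."""
        cls = np.zeros(self.n, dtype=np.int8)
        cls[self.n_exc:] = INH
        return cls

    @property
    def tau_I(self) -> np.ndarray:
        """Per-edge inactivation time constant (ms), fixed by source class."""
        return np.where(self.pre < self.n_exc, TAU_I_FROM_EXC, TAU_I_FROM_INH)

    def edge_class(self) -> np.ndarray:
        """Per-edge class label '<target><source>' in {'ee','ei','ie','ii'}."""
        src = np.where(self.pre < self.n_exc, "e", "i")
        tgt = np.where(self.post < self.n_exc, "e", "i")
        return np.char.add(tgt, src)

    def density(self) -> float:
        """Empirical directed connection density, self-pairs excluded."""
        return self.n_edges / (self.n * (self.n - 1))

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean matrix A[i, j] = True iff projection j -> i exists."""
        a = np.zeros((self.n, self.n), dtype=bool)
        a[self.post, self.pre] = True
        return a

    def weight_matrix(self) -> np.ndarray:
        """Weight matrix w[i, j] (pS); zero where no edge exists."""
        if self.weight is None:
            raise ValueError("weights have not been assigned")
        w = np.zeros((self.n, self.n))
        w[self.post, self.pre] = self.weight
        return w

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.post, minlength=self.n)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.pre, minlength=self.n)


def _edges_from_adjacency(adj_post_pre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    post, pre = np.nonzero(adj_post_pre)
    return pre.astype(np.int32), post.astype(np.int32)


def _finish(topo: NetworkTopology, cfg: NetworkConfig) -> NetworkTopology:
    assign_weights(topo, cfg)
    sample_synapse_params(topo, cfg.seed)
    return topo


def make_homogeneous(cfg: NetworkConfig) -> NetworkTopology:
    """Erdos–Renyi directed graph: each ordered pair connected with
    probability ``cfg.density``; no self-connections."""
    if cfg.topology_kind != "homogeneous":
        raise ConfigurationError("config topology_kind must be 'homogeneous'")
    rng = substream(cfg.seed, "topology")
    n = cfg.n
    adj = rng.random((n, n)) < cfg.density
    np.fill_diagonal(adj, False)
    pre, post = _edges_from_adjacency(adj)
    topo = NetworkTopology(cfg.n_exc, cfg.n_inh, pre, post,
                           kind="homogeneous", config=cfg)
    return _finish(topo, cfg)


def calibrate_ba_m(n: int, density: float) -> int:
    """Attachment count m such that a Barabasi–Albert graph on n nodes,
    with each undirected edge emitted in both directions, best matches the
    target directed density.

    A BA graph with attachment m has m*(n-m) undirected edges, i.e.
    directed density 2*m*(n-m)/(n*(n-1)).
    """
    if n < 3:
        raise ConfigurationError("scale-free generator needs at least 3 nodes")
    target_edges = density * n * (n - 1) / 2.0  # undirected
    disc = n * n - 4.0 * target_edges
    if disc < 0:
        raise ConfigurationError(
            f"density {density} infeasible for BA graph on {n} nodes"
        )
    m_cont = (n - np.sqrt(disc)) / 2.0
    candidates = {int(np.floor(m_cont)), int(np.ceil(m_cont))}
    candidates = {m for m in candidates if 1 <= m < n}
    if not candidates:
        raise ConfigurationError(
            f"no feasible attachment count for n={n}, density={density}"
        )
    return min(candidates, key=lambda m: abs(m * (n - m) - target_edges))


def make_scale_free(cfg: NetworkConfig) -> NetworkTopology:
    """Barabasi–Albert graph, symmetrised to a directed graph.

    Node labels are randomly permuted before E/I classes are assigned so
    that class membership is independent of degree (raw BA indices
    correlate with degree because early nodes become hubs).
    """
    if cfg.topology_kind != "scale_free":
        raise ConfigurationError("config topology_kind must be 'scale_free'")
    rng = substream(cfg.seed, "topology")
    n = cfg.n
    m = calibrate_ba_m(n, cfg.density)
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    perm = rng.permutation(n)
    edges = np.array(g.edges(), dtype=np.int64)
    a, b = perm[edges[:, 0]], perm[edges[:, 1]]
    pre = np.concatenate([a, b]).astype(np.int32)
    post = np.concatenate([b, a]).astype(np.int32)
    topo = NetworkTopology(cfg.n_exc, cfg.n_inh, pre, post,
                           kind="scale_free", config=cfg)
    return _finish(topo, cfg)


def make_heterogeneous(cfg: NetworkConfig) -> NetworkTopology:
    """Two-step heterogeneous random graph with per-neuron densities.

    Step 1: neuron i draws lambda_pre_exc, lambda_post_exc, lambda_pre_inh,
    lambda_post_inh independently from U[0, delta] (delta = cfg.density).
    Step 2: each ordered pair (i, j) draws xi, eta from U[0, 1]; the xi test
    establishes j -> i when xi < lambda_pre,class(j) of i, and the eta test
    establishes i -> j when eta < lambda_post,class(j) of i.  A directed
    edge exists if either mechanism fires (logical OR).
    """
    if cfg.topology_kind != "heterogeneous":
        raise ConfigurationError("config topology_kind must be 'heterogeneous'")
    rng = substream(cfg.seed, "topology")
    n, delta = cfg.n, cfg.density
    lam = rng.uniform(0.0, delta, size=(n, 4))
    lam_pre_exc, lam_post_exc, lam_pre_inh, lam_post_inh = lam.T
    xi = rng.random((n, n))
    eta = rng.random((n, n))
    is_exc = np.arange(n) < cfg.n_exc

    # xi test of pair (i, j): creates j -> i, governed by i's afferent
    # density for the class of j.
    lam_pre = np.where(is_exc[None, :], lam_pre_exc[:, None], lam_pre_inh[:, None])
    adj = xi < lam_pre  # adj[i, j]: j -> i   (rows = target)
    # eta test of pair (i, j): creates i -> j, governed by i's efferent
    # density for the class of j; in [target, source] indexing that edge
    # lives at [j, i].
    lam_post = np.where(is_exc[None, :], lam_post_exc[:, None], lam_post_inh[:, None])
    adj |= (eta < lam_post).T
    np.fill_diagonal(adj, False)
    pre, post = _edges_from_adjacency(adj)
    topo = NetworkTopology(cfg.n_exc, cfg.n_inh, pre, post,
                           kind="heterogeneous", config=cfg)
    return _finish(topo, cfg)


def make_topology(cfg: NetworkConfig) -> NetworkTopology:
    """Dispatch on ``cfg.topology_kind``."""
    return {
        "homogeneous": make_homogeneous,
        "scale_free": make_scale_free,
        "heterogeneous": make_heterogeneous,
    }[cfg.topology_kind](cfg)


def _clipped_normal(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray,
                    low: float = 0.0, high: float = np.inf,
                    strict_low: bool = True) -> np.ndarray:
    """Gaussian samples redrawn (rejection) until inside (low, high].

    Resampling rather than truncation-at-bound avoids a point mass at the
    boundary.
    """
    out = rng.normal(mean, sd)
    for _ in range(1000):
        bad = (out <= low) if strict_low else (out < low)
        bad |= out > high
        if not np.any(bad):
            return out
        idx = np.nonzero(bad)[0] if out.ndim else bad
        out = np.where(bad, rng.normal(mean, sd), out)
    raise RuntimeError("clipped-normal rejection sampling failed to converge")


def assign_weights(topo: NetworkTopology, cfg: NetworkConfig) -> NetworkTopology:
    """Draw per-edge conductances from clipped Gaussians.

    The mean for each edge is the class mean scaled by r_E (excitatory
    source) or r_I (inhibitory source); the standard deviation is half the
    mean; samples are redrawn until positive.
    """
    rng = substream(cfg.seed, "weights")
    klass = topo.edge_class()
    mean = np.empty(topo.n_edges)
    for k in ("ee", "ei", "ie", "ii"):
        mean[klass == k] = cfg.scaled_weight_mean(k)
    topo.weight = _clipped_normal(rng, mean, mean / 2.0)
    return topo


def sample_synapse_params(topo: NetworkTopology, seed: int) -> NetworkTopology:
    """Draw per-edge short-term plasticity parameters.

    U and tau_rec come from clipped Gaussians (sd = mean/2) with class
    means keyed '<target><source>'; synapses onto excitatory targets are
    depressing (no facilitation, tau_facil = 0), synapses onto inhibitory
    targets facilitate.  U is restricted to (0, 1], time constants to
    positive values.
    """
    rng = substream(seed, "synapses")
    klass = topo.edge_class()
    n_e = topo.n_edges
    u_mean = np.empty(n_e)
    rec_mean = np.empty(n_e)
    fac_mean = np.empty(n_e)
    for k, p in SYNAPSE_PARAM_MEANS.items():
        sel = klass == k
        u_mean[sel] = p["U"]
        rec_mean[sel] = p["tau_rec"]
        fac_mean[sel] = p["tau_facil"]
    topo.U = _clipped_normal(rng, u_mean, u_mean / 2.0, low=0.0, high=1.0)
    topo.tau_rec = _clipped_normal(rng, rec_mean, rec_mean / 2.0)
    facil = fac_mean > 0
    tau_facil = np.zeros(n_e)
    if np.any(facil):
        tau_facil[facil] = _clipped_normal(
            rng, fac_mean[facil], fac_mean[facil] / 2.0
        )
    topo.tau_facil = tau_facil
    return topo


def degree_profile(topo: NetworkTopology, omega_ee0: Optional[float] = None):
    """Per-neuron afferent structure: (D_exc, D_inh, effective afference ratio).

    The effective afference ratio is ``omega_ee0 * D_exc / D_inh`` with the
    unscaled ee weight mean; it is NaN where D_inh = 0.
    """
    if omega_ee0 is None:
        if topo.config is None:
            raise ValueError("pass omega_ee0 explicitly for custom topologies")
        omega_ee0 = topo.config.weight_means["ee"]
    exc_edge = topo.pre < topo.n_exc
    d_exc = np.bincount(topo.post[exc_edge], minlength=topo.n)
    d_inh = np.bincount(topo.post[~exc_edge], minlength=topo.n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_inh > 0, omega_ee0 * d_exc / np.maximum(d_inh, 1), np.nan)
    return d_exc, d_inh, ratio
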