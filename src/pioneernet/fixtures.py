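"""Scaled-down network fixtures for fast exercises of the full pipeline.

NS dynamics are population-size sensitive: a scaled fixture (e.g. 80E+20I)
keeps every code path alive — it still produces synchronization events —
but its rates, thresholds and pioneer statistics are not quantitatively
comparable to the full-size (400E+100I) networks.  Fixtures validate
code paths, not quantitative claims.
"""
from __future__ import annotations

import math

from .config import NetworkConfig, RunConfig
from .topology import NetworkTopology, make_topology


def make_fixture(kind: str = "heterogeneous", scale: float = 1.0,
                 seed: int = 0, **config_kwargs):
    """Build a network with ceil(scale*400) E and ceil(scale*100) I neurons
    at the default density and parameters.

    Returns (NetworkTopology, RunConfig)."""
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    cfg = NetworkConfig(
        n_exc=math.ceil(scale * 400), n_inh=math.ceil(scale * 100),
        topology_kind=kind, seed=seed, **config_kwargs)
    topo = make_topology(cfg)
    run = RunConfig(network=cfg, seed=seed)
    return topo, run


def uncoupled_pair_topology() -> NetworkTopology:
    """One excitatory (ID 0) and one inhibitory (ID 1) neuron with no
    synapses — for closed-form uncoupled rate checks."""
    import numpy as np

    return NetworkTopology(n_exc=1, n_inh=1,
                           pre=np.empty(0, np.int32),
                           post=np.empty(0, np.int32),
                           weight=np.empty(0), U=np.empty(0),
                           tau_rec=np.empty(0), tau_facil=np.empty(0))
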