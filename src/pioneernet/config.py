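"""Configuration objects, default parameters, and deterministic seeding.

All quantities are kept in a fixed unit system throughout the package:
times in ms, voltages in mV, conductances in pS, currents in pA,
resistances in MOhm.  Neuron IDs are 0-based with excitatory IDs first.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

#: Default mean synaptic conductances (pS), keyed by topology kind and then
#: by connection class.  Class labels read ``<target><source>``: e.g. "ei"
#: is a synapse from an inhibitory source onto an excitatory target.
DEFAULT_WEIGHT_MEANS = {
    "homogeneous": {"ee": 1150.0, "ei": 8500.0, "ie": 5.0, "ii": 200.0},
    "scale_free": {"ee": 1450.0, "ei": 9500.0, "ie": 5.0, "ii": 200.0},
    "heterogeneous": {"ee": 1000.0, "ei": 8500.0, "ie": 5.0, "ii": 200.0},
}

TOPOLOGY_KINDS = tuple(DEFAULT_WEIGHT_MEANS)

#: Short-term synapse parameter means keyed by connection class
#: (``<target><source>``).  Standard deviations are half the mean; samples
#: are redrawn until they fall in the physical range.  tau values in ms.
SYNAPSE_PARAM_MEANS = {
    "ee": {"U": 0.3, "tau_rec": 800.0, "tau_facil": 0.0},
    "ei": {"U": 0.3, "tau_rec": 800.0, "tau_facil": 0.0},
    "ie": {"U": 0.04, "tau_rec": 100.0, "tau_facil": 1000.0},
    "ii": {"U": 0.04, "tau_rec": 100.0, "tau_facil": 1000.0},
}

#: Inactivation time constant of active synaptic resources, by *source*
#: neuron class (ms).
TAU_I_FROM_EXC = 3.0
TAU_I_FROM_INH = 10.0


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire parameters for one neuron class.

    The background current drives the equilibrium potential
    ``E_L + R_m * I_b`` above threshold, so isolated neurons fire tonically.
    """

    E_L: float = -70.0       # leak reversal, mV
    tau_m: float = 30.0      # membrane time constant, ms
    R_m: float = 40.0        # membrane resistance, MOhm
    I_b: float = 525.0       # background current, pA
    V_theta: float = -50.0   # firing threshold, mV
    V_res: float = -65.0     # reset potential, mV
    tau_ref: float = 3.0     # absolute refractory period, ms
    E_exc: float = 0.0       # excitatory reversal, mV
    E_inh: float = -70.0     # inhibitory reversal, mV

    def __post_init__(self) -> None:
        if not self.V_res < self.V_theta:
            raise ConfigurationError("V_res must lie below V_theta")
        if self.tau_m <= 0 or self.tau_ref <= 0:
            raise ConfigurationError("tau_m and tau_ref must be positive")

def exc_params() -> NeuronParams:
    """Default excitatory neuron parameters."""
    return NeuronParams()


def inh_params() -> NeuronParams:
    """Default inhibitory neuron parameters."""
    return NeuronParams(tau_m=10.0, R_m=50.0, I_b=420.0, tau_ref=2.0)


def lif_equilibrium(p: NeuronParams) -> float:
    """Equilibrium potential ``E_L + R_m I_b`` in mV (MOhm * pA = uV)."""
    return p.E_L + p.R_m * p.I_b * 1e-3


def lif_closed_form_rate(p: NeuronParams) -> float:
    """Firing rate (Hz) of an isolated LIF neuron under constant current.

    Returns 0 when the equilibrium potential stays below threshold.
    """
    v_inf = lif_equilibrium(p)
    if v_inf <= p.V_theta:
        return 0.0
    isi_ms = p.tau_ref + p.tau_m * np.log(
        (v_inf - p.V_res) / (v_inf - p.V_theta)
    )
    return 1000.0 / isi_ms


@dataclass
class NetworkConfig:
    """Size, density, topology kind and synaptic scaling of one network."""

    n_exc: int = 400
    n_inh: int = 100
    density: float = 0.20
    topology_kind: str = "heterogeneous"
    weight_means: Optional[dict] = None
    r_E: float = 1.0
    r_I: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise ConfigurationError("n_exc and n_inh must be positive")
        if not 0.0 <= self.density < 1.0:
            raise ConfigurationError("density must lie in [0, 1)")
        if self.topology_kind not in TOPOLOGY_KINDS:
            raise ConfigurationError(
                f"unknown topology kind {self.topology_kind!r}; "
                f"expected one of {TOPOLOGY_KINDS}"
            )
        if self.r_E <= 0 or self.r_I <= 0:
            raise ConfigurationError("r_E and r_I must be positive")
        if self.weight_means is None:
            self.weight_means = dict(DEFAULT_WEIGHT_MEANS[self.topology_kind])
        if any(v <= 0 for v in self.weight_means.values()):
            raise ConfigurationError("all weight means must be positive")

    @property
    def n(self) -> int:
        return self.n_exc + self.n_inh

    def scaled_weight_mean(self, klass: str) -> float:
        """Mean weight for a connection class after (r_E, r_I) scaling.

        Edges from excitatory sources (classes "ee", "ie") scale with r_E,
        edges from inhibitory sources ("ei", "ii") with r_I.
        """
        base = self.weight_means[klass]
        return base * (self.r_E if klass[1] == "e" else self.r_I)


@dataclass
class RunConfig:
    """One full experiment: network, integration, protocol and recording."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    duration_ms: float = 100_000.0
    dt_ms: float = 0.5
    warmup_ms: float = 2000.0
    seed: int = 0
    # stimulation protocol (optional)
    n_sites: int = 0
    site_size: int = 10
    stim_rate_hz: float = 1.0
    # recording
    record_vstar: bool = False
    vstar_stride_ms: float = 5.0
    record_v: bool = False
    v_stride_ms: float = 5.0
    record_resources: bool = False
    resource_stride_ms: float = 20.0
    version: str = "pioneernet-0.1.0"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        net = d.pop("network", {})
        return cls(network=NetworkConfig(**net), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# stable substream indices, one per stage that consumes randomness
_STREAMS = {
    "topology": 0,
    "weights": 1,
    "synapses": 2,
    "init": 3,
    "protocol": 4,
    "classifier": 5,
    "surrogate": 6,
    "misc": 7,
}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random generator derived from a global seed.

    Each pipeline stage draws from its own substream so that, e.g., changing
    the stimulation protocol leaves the topology unchanged.
    """
    if stage not in _STREAMS:
        raise KeyError(f"unknown random stream {stage!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stage],))
    return np.random.default_rng(ss)
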