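"""Clock-driven simulation of the LIF network with depressing/facilitating
conductance synapses.

Model
-----
Each neuron obeys ``dV/dt = (E_L - V)/tau_m + R_m(I_b + I_syn)/tau_m`` with
threshold/reset and an absolute refractory period.  Each synapse carries
finite resources partitioned into recovered (R), active (E) and inactive
(I) fractions with R+E+I = 1; a presynaptic spike moves u*R from recovered
to active (u is the utilization variable, facilitating where tau_facil > 0),
the active fraction inactivates with tau_I and recovers with tau_rec.  The
synaptic current is conductance based, g = sum_j w_ij E_ij per transmitter
class, with reversal potentials E_exc/E_inh.

Numerics
--------
Voltages advance with the first-order exponential (exponential-Euler)
scheme at step ``dt``, conductances held constant across each step.  The
per-synapse (E, I) pair is linear and autonomous between presynaptic spike
arrivals, so it is advanced with its exact solution, lazily, only when a
spike arrives or a sample is recorded; the per-neuron conductances decay by
the class factor ``exp(-dt/tau_I)`` every step and receive jump increments
``w * Delta_E`` on arrivals, which reproduces ``sum_j w_ij E_ij(t)``
exactly.  Spikes take effect at their targets after a uniform 0.5 ms
axonal delay.  A shadow "star" voltage V* integrates the identical
conductance input but is never reset; its sub-threshold statistics
quantify how close a neuron sits to firing.

The first ``warmup_ms`` (default 2 s) of every simulation are discarded
from all outputs; times in outputs are absolute, so valid samples start at
the warm-up boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .config import (
    ConfigurationError,
    NeuronParams,
    TAU_I_FROM_EXC,
    TAU_I_FROM_INH,
    exc_params,
    inh_params,
    substream,
)
from .topology import NetworkTopology

AXONAL_DELAY_MS = 0.5
DEFAULT_WARMUP_MS = 2000.0


@dataclass
class StimulationProtocol:
    """Stimulation sites (disjoint sets of excitatory neurons) and events.

    Each event forces one simultaneous spike in every neuron of its site.
    """

    sites: list  # list of int arrays
    event_times: np.ndarray  # ms, sorted
    event_sites: np.ndarray  # site index per event
    rate_hz: Optional[float] = None

    def __post_init__(self) -> None:
        self.sites = [np.asarray(s, dtype=np.int64) for s in self.sites]
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_sites = np.asarray(self.event_sites, dtype=np.int64)
        order = np.argsort(self.event_times, kind="stable")
        self.event_times = self.event_times[order]
        self.event_sites = self.event_sites[order]
        all_ids = np.concatenate(self.sites) if self.sites else np.empty(0, int)
        if all_ids.size != np.unique(all_ids).size:
            raise ConfigurationError("stimulation sites must be disjoint")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)

    def validate_for(self, topo: NetworkTopology) -> None:
        for s in self.sites:
            if np.any(s >= topo.n_exc) or np.any(s < 0):
                raise ConfigurationError(
                    "stimulation sites must contain excitatory IDs only"
                )


def make_poisson_protocol(sites: Sequence[Sequence[int]], rate_hz: float,
                          duration_ms: float, seed: int,
                          t_start_ms: float = DEFAULT_WARMUP_MS) -> StimulationProtocol:
    """Poisson stimulation: event times at ``rate_hz`` on
    [t_start_ms, duration_ms), each event at a uniformly random site."""
    if duration_ms <= 0:
        raise ConfigurationError("duration must be positive")
    if rate_hz < 0:
        raise ConfigurationError("rate must be non-negative")
    rng = substream(seed, "protocol")
    span_s = max(duration_ms - t_start_ms, 0.0) / 1000.0
    n_ev = rng.poisson(rate_hz * span_s) if rate_hz > 0 else 0
    times = np.sort(rng.uniform(t_start_ms, duration_ms, size=n_ev))
    which = rng.integers(0, max(len(sites), 1), size=n_ev)
    return StimulationProtocol(list(sites), times, which, rate_hz=rate_hz)


def make_random_sites(topo: NetworkTopology, n_sites: int, site_size: int,
                      seed: int) -> list:
    """Draw ``n_sites`` disjoint sets of ``site_size`` excitatory neurons."""
    rng = substream(seed, "protocol")
    need = n_sites * site_size
    if need > topo.n_exc:
        raise ConfigurationError("not enough excitatory neurons for sites")
    ids = rng.choice(topo.n_exc, size=need, replace=False)
    return [np.sort(ids[k * site_size:(k + 1) * site_size]) for k in range(n_sites)]


@dataclass
class SimulationResult:
    """Spike raster plus optional traces from one simulation."""

    n_exc: int
    n_inh: int
    dt: float
    duration: float            # ms, total simulated (including warm-up)
    warmup: float              # ms
    spike_neuron: np.ndarray   # int32
    spike_time: np.ndarray     # ms, nondecreasing
    spike_forced: np.ndarray   # bool
    silenced: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    protocol: Optional[StimulationProtocol] = None
    stim_delivered: Optional[np.ndarray] = None  # bool per forced spike event
    vstar: Optional[np.ndarray] = None           # (n_samples, n) float32
    vstar_times: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    v_times: Optional[np.ndarray] = None
    g_exc: Optional[np.ndarray] = None
    g_inh: Optional[np.ndarray] = None
    g_times: Optional[np.ndarray] = None
    resource_times: Optional[np.ndarray] = None
    resources: Optional[np.ndarray] = None       # efferent-mean R, (n_samples, n)
    synapse_sample_edges: Optional[np.ndarray] = None
    synapse_samples: Optional[np.ndarray] = None  # (n_samples, k, 3) = R, E, I
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def analysis_span_ms(self) -> float:
        """Length of the retained (post warm-up) recording."""
        return self.duration - self.warmup

    def spikes_of(self, neuron: int, include_forced: bool = False) -> np.ndarray:
        sel = self.spike_neuron == neuron
        if not include_forced:
            sel &= ~self.spike_forced
        return self.spike_time[sel]

    def per_neuron_rates(self, include_forced: bool = False) -> np.ndarray:
        """Mean firing rate of every neuron over the retained span (Hz)."""
        sel = slice(None) if include_forced else ~self.spike_forced
        counts = np.bincount(self.spike_neuron[sel], minlength=self.n)
        return counts / (self.analysis_span_ms / 1000.0)

    def population_ids(self, population: str = "exc") -> np.ndarray:
        if population == "exc":
            return np.arange(self.n_exc)
        if population == "inh":
            return np.arange(self.n_exc, self.n)
        if population == "all":
            return np.arange(self.n)
        raise ValueError(f"unknown population {population!r}")


@dataclass
class ActivityTrace:
    """Gaussian-kernel population spike-density estimate.

    ``values`` are in Hz summed over the population: the time integral of
    the trace equals the number of spikes it was built from.
    """

    times: np.ndarray   # ms
    values: np.ndarray  # Hz (population-summed spike density)
    stride: float       # ms
    kernel_width: float  # ms (Gaussian sigma)
    population: str
    rates: np.ndarray   # per-neuron mean rates, Hz

    @property
    def a_mean(self) -> float:
        return float(self.values.mean()) if self.values.size else 0.0

    @property
    def a_max(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0

    def integral(self) -> float:
        """Time integral in units of spike count."""
        return float(self.values.sum() * self.stride / 1000.0)


def population_activity(result: SimulationResult, population: str = "exc",
                        kernel_width: float = 3.0, stride: float = 0.1,
                        include_forced: bool = False) -> ActivityTrace:
    """Population spike density, Gaussian kernel (sigma = ``kernel_width``).

    Forced (stimulation) spikes are excluded by default, as all analysis
    layers disregard them.
    """
    from scipy.ndimage import gaussian_filter1d

    ids = result.population_ids(population)
    in_pop = np.zeros(result.n, dtype=bool)
    in_pop[ids] = True
    sel = in_pop[result.spike_neuron]
    if not include_forced:
        sel &= ~result.spike_forced
    t = result.spike_time[sel]
    t0, t1 = result.warmup, result.duration
    n_bins = max(int(round((t1 - t0) / stride)), 1)
    counts, edges = np.histogram(t, bins=n_bins, range=(t0, t1))
    if t.size:
        smooth = gaussian_filter1d(counts.astype(float), kernel_width / stride,
                                   mode="constant")
    else:
        smooth = np.zeros(n_bins)
    values = smooth / (stride / 1000.0)
    times = edges[:-1] + stride / 2.0
    span_s = (t1 - t0) / 1000.0
    rates = np.bincount(result.spike_neuron[sel], minlength=result.n)[ids] / span_s
    return ActivityTrace(times=times, values=values, stride=stride,
                         kernel_width=kernel_width, population=population,
                         rates=rates)


@njit(cache=True)
def _run_kernel(n, n_exc, dt, n_steps, warmup_steps, delay_steps,
                tau_m, rm, ib, ref_steps, e_l, v_theta, v_res,
                e_exc_rev, e_inh_rev,
                indptr, edge_post, edge_w, edge_U, edge_tau_i, edge_tau_rec,
                edge_tau_facil,
                silenced,
                stim_boundary, stim_neuron,
                v0,
                sp_neuron, sp_boundary, sp_forced,
                vstar_stride, vstar_out, v_stride, v_out,
                g_stride, gexc_out, ginh_out,
                res_stride, res_out, syn_edges, syn_out,
                stim_delivered):
    a_ge = math.exp(-dt / 3.0)
    a_gi = math.exp(-dt / 10.0)
    cap = sp_neuron.shape[0]

    v = v0.copy()
    vstar = v0.copy()
    g_exc = np.zeros(n)
    g_inh = np.zeros(n)
    ref_until = np.full(n, -1, dtype=np.int64)

    n_edges = edge_post.shape[0]
    eE = np.zeros(n_edges)
    eI = np.zeros(n_edges)
    eu = np.zeros(n_edges)
    for e in range(n_edges):
        if edge_tau_facil[e] <= 0.0:
            eu[e] = edge_U[e]
    last = np.zeros(n_edges, dtype=np.int64)

    # ring buffer of spikers by emission boundary
    buf = np.empty((delay_steps, n), dtype=np.int64)
    buf_cnt = np.zeros(delay_steps, dtype=np.int64)

    n_sp = 0
    ptr_stim = 0
    n_stim = stim_boundary.shape[0]
    overflow = 0

    for s in range(n_steps):
        b = s + 1
        # --- continuous voltage update with conductances frozen over dt
        for i in range(n):
            ge = g_exc[i]
            gi = g_inh[i]
            rg = rm[i] * 1e-6  # MOhm * pS -> dimensionless
            k = 1.0 + rg * (ge + gi)
            vinf = (e_l + rm[i] * ib[i] * 1e-3
                    + rg * (ge * e_exc_rev + gi * e_inh_rev)) / k
            lam = math.exp(-dt * k / tau_m[i])
            vstar[i] = vinf + (vstar[i] - vinf) * lam
            if b > ref_until[i]:
                v[i] = vinf + (v[i] - vinf) * lam
        # --- conductance decay to boundary b
        for i in range(n):
            g_exc[i] *= a_ge
            g_inh[i] *= a_gi
        # --- deliver spikes emitted at boundary b - delay_steps
        slot = b % delay_steps
        for q in range(buf_cnt[slot]):
            j = buf[slot, q]
            if silenced[j]:
                continue
            for e in range(indptr[j], indptr[j + 1]):
                n_adv = b - last[e]
                if n_adv > 0:
                    delta = n_adv * dt
                    t_i = edge_tau_i[e]
                    t_r = edge_tau_rec[e]
                    ea = math.exp(-delta / t_i)
                    eb = math.exp(-delta / t_r)
                    if abs(t_r - t_i) < 1e-9:
                        eI[e] = eI[e] * eb + eE[e] * (delta / t_i) * ea
                    else:
                        eI[e] = eI[e] * eb + eE[e] * (t_r / (t_r - t_i)) * (eb - ea)
                    eE[e] *= ea
                    if edge_tau_facil[e] > 0.0:
                        eu[e] *= math.exp(-delta / edge_tau_facil[e])
                    last[e] = b
                # presynaptic jump: u first (u(t+eps)), then E gains u*R(t-eps)
                if edge_tau_facil[e] > 0.0:
                    eu[e] = eu[e] + edge_U[e] * (1.0 - eu[e])
                else:
                    eu[e] = edge_U[e]
                r_now = 1.0 - eE[e] - eI[e]
                d_e = eu[e] * r_now
                eE[e] += d_e
                tgt = edge_post[e]
                if j < n_exc:
                    g_exc[tgt] += edge_w[e] * d_e
                else:
                    g_inh[tgt] += edge_w[e] * d_e
        buf_cnt[slot] = 0
        # --- forced stimulation spikes scheduled at boundary b
        while ptr_stim < n_stim and stim_boundary[ptr_stim] == b:
            i = stim_neuron[ptr_stim]
            if b > ref_until[i]:
                v[i] = v_res
                ref_until[i] = b + ref_steps[i]
                if b > warmup_steps:
                    if n_sp >= cap:
                        overflow = 1
                        return n_sp, overflow
                    sp_neuron[n_sp] = i
                    sp_boundary[n_sp] = b
                    sp_forced[n_sp] = 1
                    n_sp += 1
                buf[slot, buf_cnt[slot]] = i
                buf_cnt[slot] += 1
                stim_delivered[ptr_stim] = 1
            else:
                stim_delivered[ptr_stim] = 0
            ptr_stim += 1
        # --- threshold crossings at boundary b
        for i in range(n):
            if b > ref_until[i] and v[i] >= v_theta:
                v[i] = v_res
                ref_until[i] = b + ref_steps[i]
                if b > warmup_steps:
                    if n_sp >= cap:
                        overflow = 1
                        return n_sp, overflow
                    sp_neuron[n_sp] = i
                    sp_boundary[n_sp] = b
                    sp_forced[n_sp] = 0
                    n_sp += 1
                buf[slot, buf_cnt[slot]] = i
                buf_cnt[slot] += 1
        # --- recording
        if b >= warmup_steps:
            off = b - warmup_steps
            if vstar_stride > 0 and off % vstar_stride == 0:
                idx = off // vstar_stride
                for i in range(n):
                    vstar_out[idx, i] = vstar[i]
            if v_stride > 0 and off % v_stride == 0:
                idx = off // v_stride
                for i in range(n):
                    v_out[idx, i] = v[i]
            if g_stride > 0 and off % g_stride == 0:
                idx = off // g_stride
                for i in range(n):
                    gexc_out[idx, i] = g_exc[i]
                    ginh_out[idx, i] = g_inh[i]
            if res_stride > 0 and off % res_stride == 0:
                idx = off // res_stride
                for i in range(n):
                    acc = 0.0
                    cnt = indptr[i + 1] - indptr[i]
                    for e in range(indptr[i], indptr[i + 1]):
                        delta = (b - last[e]) * dt
                        t_i = edge_tau_i[e]
                        t_r = edge_tau_rec[e]
                        ea = math.exp(-delta / t_i)
                        eb = math.exp(-delta / t_r)
                        if abs(t_r - t_i) < 1e-9:
                            i_now = eI[e] * eb + eE[e] * (delta / t_i) * ea
                        else:
                            i_now = eI[e] * eb + eE[e] * (t_r / (t_r - t_i)) * (eb - ea)
                        acc += 1.0 - eE[e] * ea - i_now
                    res_out[idx, i] = acc / cnt if cnt > 0 else 1.0
                for q in range(syn_edges.shape[0]):
                    e = syn_edges[q]
                    delta = (b - last[e]) * dt
                    t_i = edge_tau_i[e]
                    t_r = edge_tau_rec[e]
                    ea = math.exp(-delta / t_i)
                    eb = math.exp(-delta / t_r)
                    if abs(t_r - t_i) < 1e-9:
                        i_now = eI[e] * eb + eE[e] * (delta / t_i) * ea
                    else:
                        i_now = eI[e] * eb + eE[e] * (t_r / (t_r - t_i)) * (eb - ea)
                    e_now = eE[e] * ea
                    syn_out[idx, q, 0] = 1.0 - e_now - i_now
                    syn_out[idx, q, 1] = e_now
                    syn_out[idx, q, 2] = i_now
    return n_sp, overflow


def _stride_steps(stride_ms: float, dt: float) -> int:
    steps = int(round(stride_ms / dt))
    if steps < 1:
        raise ConfigurationError("recording stride must be >= dt")
    return steps


def simulate(topo: NetworkTopology, duration_ms: float, *,
             dt: float = 0.5,
             protocol: Optional[StimulationProtocol] = None,
             silenced: Optional[Sequence[int]] = None,
             params: Optional[tuple] = None,
             warmup_ms: float = DEFAULT_WARMUP_MS,
             record_vstar: bool = False, vstar_stride_ms: float = 5.0,
             record_v: bool = False, v_stride_ms: float = 5.0,
             record_g: bool = False, g_stride_ms: float = 5.0,
             record_resources: bool = False, resource_stride_ms: float = 20.0,
             synapse_sample_edges: Optional[Sequence[int]] = None,
             seed: int = 0) -> SimulationResult:
    """Simulate the network for ``duration_ms`` (including warm-up).

    Initial voltages are drawn uniformly from [V_res, V_theta); synapses
    start fully recovered (R=1, E=I=0, u=0).  Neurons listed in
    ``silenced`` spike normally but their efferent synapses receive no
    presynaptic spikes (de-efferentiation).  Forced stimulation spikes
    reset their neuron, engage its efferent synapses and are flagged in
    the output; an event hitting a refractory neuron is logged as
    undelivered.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if duration_ms <= warmup_ms:
        raise ConfigurationError("duration must exceed the warm-up period")
    p_exc, p_inh = params if params is not None else (exc_params(), inh_params())

    n, n_exc = topo.n, topo.n_exc
    is_exc = np.arange(n) < n_exc
    tau_m = np.where(is_exc, p_exc.tau_m, p_inh.tau_m).astype(float)
    rm = np.where(is_exc, p_exc.R_m, p_inh.R_m).astype(float)
    ib = np.where(is_exc, p_exc.I_b, p_inh.I_b).astype(float)
    tau_ref = np.where(is_exc, p_exc.tau_ref, p_inh.tau_ref)
    ref_steps = np.round(tau_ref / dt).astype(np.int64)

    # efferent CSR (edges already sorted by pre)
    indptr = np.searchsorted(topo.pre, np.arange(n + 1)).astype(np.int64)
    n_edges = topo.n_edges
    if n_edges and topo.weight is None:
        raise ConfigurationError("topology weights not assigned")
    edge_w = topo.weight if topo.weight is not None else np.empty(0)
    edge_U = topo.U if topo.U is not None else np.empty(0)
    edge_tau_rec = topo.tau_rec if topo.tau_rec is not None else np.empty(0)
    edge_tau_facil = topo.tau_facil if topo.tau_facil is not None else np.empty(0)
    edge_tau_i = np.where(topo.pre < n_exc, TAU_I_FROM_EXC, TAU_I_FROM_INH).astype(float)

    sil = np.zeros(n, dtype=np.bool_)
    silenced_ids = np.empty(0, dtype=np.int64) if silenced is None \
        else np.unique(np.asarray(list(silenced), dtype=np.int64))
    sil[silenced_ids] = True

    n_steps = int(round(duration_ms / dt))
    warmup_steps = int(round(warmup_ms / dt))
    delay_steps = max(1, int(round(AXONAL_DELAY_MS / dt)))

    if protocol is not None:
        protocol.validate_for(topo)
        site_ids = np.concatenate(protocol.sites) if protocol.sites else np.empty(0, int)
        if np.intersect1d(site_ids, silenced_ids).size:
            raise ConfigurationError("silenced set overlaps stimulation sites")
        stim_boundary = []
        stim_neuron = []
        for t, k in zip(protocol.event_times, protocol.event_sites):
            bnd = int(round(t / dt))
            if bnd < 1 or bnd > n_steps:
                continue
            for i in protocol.sites[int(k)]:
                stim_boundary.append(bnd)
                stim_neuron.append(int(i))
        stim_boundary = np.asarray(stim_boundary, dtype=np.int64)
        stim_neuron = np.asarray(stim_neuron, dtype=np.int32)
    else:
        stim_boundary = np.empty(0, dtype=np.int64)
        stim_neuron = np.empty(0, dtype=np.int32)

    rng = substream(seed, "init")
    v0 = rng.uniform(p_exc.V_res, p_exc.V_theta, size=n)

    def out_shape(stride_ms, enabled):
        if not enabled:
            return 0, np.empty((0, 0), dtype=np.float32)
        steps = _stride_steps(stride_ms, dt)
        n_samples = (n_steps - warmup_steps) // steps + 1
        return steps, np.empty((n_samples, n), dtype=np.float32)

    vstar_stride, vstar_out = out_shape(vstar_stride_ms, record_vstar)
    v_stride, v_out = out_shape(v_stride_ms, record_v)
    g_stride, gexc_out = out_shape(g_stride_ms, record_g)
    ginh_out = np.empty_like(gexc_out)
    res_stride, res_out = out_shape(resource_stride_ms, record_resources)
    if synapse_sample_edges is not None:
        syn_edges = np.asarray(synapse_sample_edges, dtype=np.int64)
        if res_stride == 0:
            res_stride, res_out = out_shape(resource_stride_ms, True)
        syn_out = np.empty((res_out.shape[0], syn_edges.size, 3), dtype=np.float64)
    else:
        syn_edges = np.empty(0, dtype=np.int64)
        syn_out = np.empty((0, 0, 3), dtype=np.float64)

    stim_delivered = np.zeros(stim_boundary.size, dtype=np.uint8)
    cap = max(100_000, int(n * (duration_ms / 1000.0) * 60) + stim_boundary.size)
    for _attempt in range(8):
        sp_neuron = np.empty(cap, dtype=np.int32)
        sp_boundary = np.empty(cap, dtype=np.int64)
        sp_forced = np.empty(cap, dtype=np.uint8)
        n_sp, overflow = _run_kernel(
            n, n_exc, dt, n_steps, warmup_steps, delay_steps,
            tau_m, rm, ib, ref_steps,
            p_exc.E_L, p_exc.V_theta, p_exc.V_res, p_exc.E_exc, p_exc.E_inh,
            indptr, topo.post, edge_w, edge_U, edge_tau_i, edge_tau_rec,
            edge_tau_facil, sil, stim_boundary, stim_neuron, v0,
            sp_neuron, sp_boundary, sp_forced,
            vstar_stride, vstar_out, v_stride, v_out,
            g_stride, gexc_out, ginh_out,
            res_stride, res_out, syn_edges, syn_out,
            stim_delivered)
        if not overflow:
            break
        cap *= 4
    else:
        raise RuntimeError("spike buffer overflow not resolved")

    def times_of(stride, arr):
        if not stride:
            return None
        return warmup_ms + np.arange(arr.shape[0]) * stride * dt

    # one stim_delivered flag per (event, neuron) pair -> reduce per event
    if protocol is not None and protocol.n_events:
        per_event = []
        pos = 0
        for t, k in zip(protocol.event_times, protocol.event_sites):
            bnd = int(round(t / dt))
            size = len(protocol.sites[int(k)]) if 1 <= bnd <= n_steps else 0
            per_event.append(bool(stim_delivered[pos:pos + size].any()) if size else False)
            pos += size
        stim_ok = np.asarray(per_event, dtype=bool)
    else:
        stim_ok = None

    return SimulationResult(
        n_exc=n_exc, n_inh=topo.n_inh, dt=dt, duration=float(n_steps * dt),
        warmup=float(warmup_ms),
        spike_neuron=sp_neuron[:n_sp].copy(),
        spike_time=sp_boundary[:n_sp] * dt,
        spike_forced=sp_forced[:n_sp].astype(bool),
        silenced=silenced_ids, protocol=protocol, stim_delivered=stim_ok,
        vstar=vstar_out if vstar_stride else None,
        vstar_times=times_of(vstar_stride, vstar_out),
        v=v_out if v_stride else None,
        v_times=times_of(v_stride, v_out),
        g_exc=gexc_out if g_stride else None,
        g_inh=ginh_out if g_stride else None,
        g_times=times_of(g_stride, gexc_out),
        resource_times=times_of(res_stride, res_out) if res_stride else None,
        resources=res_out if res_stride else None,
        synapse_sample_edges=syn_edges if syn_edges.size else None,
        synapse_samples=syn_out if syn_edges.size else None,
        seed=seed,
    )
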