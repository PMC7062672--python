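"""Per-neuron microscopic analyses around network spikes.

The central objects are the first-spike latency of each neuron relative to
each NS peak and the sub-threshold statistics of the shadow star voltage
V* between NSs.  From these follow:

* latency consistency 1/CV(tau) = <-tau> / std(tau) — how reproducibly a
  neuron fires *before* the NS peak;
* sensitivity CV(V*) = std(V*) / (V_theta - <V*>) — how likely a small
  fluctuation of population activity is to recruit the neuron;
* the pioneer criterion CV(tau) < 0.64 and |CV(V*)| > 0.64, which singles
  out neurons that fire early and consistently during NS build-up.

Also here: spike-triggered deviation of population activity, efferent
synaptic-resource densities, closed-form PSP estimates, spike-train power
spectra and pairwise zero-lag correlations (both computed between NSs).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import NeuronParams, exc_params, inh_params
from .dynamics import ActivityTrace, SimulationResult
from .events import NS_EXCLUSION_MS, NetworkSpikeEvent, between_ns_mask
from .topology import NetworkTopology

PIONEER_CV_TAU_MAX = 0.64
PIONEER_CV_VSTAR_MIN = 0.64
LATENCY_T0_MS = -80.0


@dataclass
class RateOrder:
    """Activity ranking of the excitatory population."""

    rates: np.ndarray   # Hz, per excitatory neuron
    rank: np.ndarray    # 1-based sorted ID per neuron (least active = 1)
    order: np.ndarray   # neuron IDs in ascending rate order

    def band(self, lo: int, hi: int) -> np.ndarray:
        """Neuron IDs with sorted ID in [lo, hi] (1-based, inclusive)."""
        return self.order[lo - 1:hi]


def sort_by_rate(result: SimulationResult) -> RateOrder:
    """Stable ascending sort of excitatory neurons by mean firing rate;
    ties are broken by neuron ID."""
    rates = result.per_neuron_rates()[:result.n_exc]
    order = np.argsort(rates, kind="stable")
    rank = np.empty(result.n_exc, dtype=np.int64)
    rank[order] = np.arange(1, result.n_exc + 1)
    return RateOrder(rates=rates, rank=rank, order=order)


@dataclass
class LatencyTable:
    """First-spike latency (ms) of each excitatory neuron for each NS.

    ``latencies[i, k]`` is the latency of neuron i's earliest qualifying
    spike relative to the peak of NS k (negative = before the peak), NaN
    where no spike fell inside the attribution window (t0, forward].
    """

    latencies: np.ndarray  # (n_exc, n_events)
    t0: float
    forward: float

    @property
    def n_events(self) -> int:
        return self.latencies.shape[1]

    def counts(self) -> np.ndarray:
        return np.sum(~np.isnan(self.latencies), axis=1)


def first_spike_latencies(result: SimulationResult,
                          events: Sequence[NetworkSpikeEvent],
                          t0: float = LATENCY_T0_MS,
                          forward: float = NS_EXCLUSION_MS) -> LatencyTable:
    """Attribute spikes to NSs and extract first-spike latencies.

    A spike is attributed to its nearest NS peak; it qualifies when its
    latency lies in (t0, forward].  Forced stimulation spikes are
    excluded.  The earliest qualifying spike per (neuron, NS) defines tau.
    """
    n_exc = result.n_exc
    peaks = np.sort([ev.t_peak for ev in events])
    lat = np.full((n_exc, peaks.size), np.nan)
    if peaks.size == 0:
        return LatencyTable(lat, t0, forward)
    sel = (result.spike_neuron < n_exc) & ~result.spike_forced
    sp_n = result.spike_neuron[sel]
    sp_t = result.spike_time[sel]
    idx = np.searchsorted(peaks, sp_t)
    left = np.clip(idx - 1, 0, peaks.size - 1)
    right = np.clip(idx, 0, peaks.size - 1)
    nearest = np.where(np.abs(sp_t - peaks[left]) <= np.abs(peaks[right] - sp_t),
                       left, right)
    tau = sp_t - peaks[nearest]
    ok = (tau > t0) & (tau <= forward)
    # earliest spike per (neuron, event): process in reverse time order
    order = np.argsort(sp_t, kind="stable")[::-1]
    for q in order:
        if ok[q]:
            lat[sp_n[q], nearest[q]] = tau[q]
    return LatencyTable(lat, t0, forward)


def latency_consistency(table: LatencyTable, min_events: int = 2) -> np.ndarray:
    """Per-neuron 1/CV(tau) = <-tau>/std(tau); NaN where fewer than
    ``min_events`` latencies exist, +inf where std is zero and the mean
    latency is negative (perfectly consistent pioneer)."""
    mean_neg, sd, n = _latency_moments(table)
    out = np.full(table.latencies.shape[0], np.nan)
    valid = n >= min_events
    with np.errstate(divide="ignore", invalid="ignore"):
        out[valid] = np.where(sd[valid] > 0, mean_neg[valid] / sd[valid],
                              np.where(mean_neg[valid] > 0, np.inf, -np.inf))
    return out


def latency_cv(table: LatencyTable, min_events: int = 2) -> np.ndarray:
    """Per-neuron CV(tau) = std(tau)/<-tau> (reciprocal of consistency);
    NaN where undefined, negative where the mean latency is positive."""
    mean_neg, sd, n = _latency_moments(table)
    out = np.full(table.latencies.shape[0], np.nan)
    valid = n >= min_events
    with np.errstate(divide="ignore", invalid="ignore"):
        out[valid] = sd[valid] / mean_neg[valid]
    return out


def _latency_moments(table: LatencyTable):
    lat = table.latencies
    valid = ~np.isnan(lat)
    n = valid.sum(axis=1)
    filled = np.where(valid, lat, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=1) / n
        var = np.where(valid, (lat - mean[:, None]) ** 2, 0.0).sum(axis=1) \
            / np.maximum(n - 1, 1)
    sd = np.sqrt(var)
    mean[n == 0] = np.nan
    sd[n < 2] = np.nan
    return -mean, sd, n


def mean_latency(table: LatencyTable) -> np.ndarray:
    mean_neg, _, n = _latency_moments(table)
    out = np.full(table.latencies.shape[0], np.nan)
    out[n > 0] = -mean_neg[n > 0]
    return out


@dataclass
class StarStats:
    """Between-NS moments of the star voltage per neuron."""

    mean: np.ndarray   # mV
    sd: np.ndarray     # mV
    cv: np.ndarray     # std / (V_theta - mean); negative above threshold
    n_samples: int


def star_voltage_stats(result: SimulationResult,
                       events: Sequence[NetworkSpikeEvent],
                       v_theta: Optional[float] = None) -> StarStats:
    """Moments of V* over samples farther than 35 ms from every NS peak."""
    if result.vstar is None:
        raise ValueError("simulation was run without record_vstar")
    if v_theta is None:
        v_theta = exc_params().V_theta
    mask = between_ns_mask(result.vstar_times, events)
    vs = result.vstar[mask].astype(np.float64)
    mean = vs.mean(axis=0)
    sd = vs.std(axis=0)
    with np.errstate(divide="ignore"):
        cv = sd / (v_theta - mean)
    return StarStats(mean=mean, sd=sd, cv=cv, n_samples=int(mask.sum()))


def identify_pioneers(cv_tau: np.ndarray, cv_vstar: np.ndarray,
                      cv_tau_max: float = PIONEER_CV_TAU_MAX,
                      cv_vstar_min: float = PIONEER_CV_VSTAR_MIN):
    """Pioneer criterion: 0 <= CV(tau) < cv_tau_max and |CV(V*)| > cv_vstar_min.

    Returns (boolean array, fraction of the population).  Neurons with
    undefined CV(tau) (too few latencies, or mean latency not negative)
    are never pioneers.
    """
    cv_tau = np.asarray(cv_tau, dtype=float)
    cv_vstar = np.asarray(cv_vstar, dtype=float)
    with np.errstate(invalid="ignore"):
        is_p = (cv_tau >= 0) & (cv_tau < cv_tau_max) & \
               (np.abs(cv_vstar) > cv_vstar_min)
    is_p &= np.isfinite(cv_tau)
    return is_p, float(is_p.mean())


def spike_triggered_deviation(result: SimulationResult, activity: ActivityTrace,
                              events: Sequence[NetworkSpikeEvent], neuron: int,
                              lags: Optional[np.ndarray] = None) -> tuple:
    """Gamma_i(tau): mean deviation of population activity from its
    temporal mean at lag tau around the neuron's between-NS spikes.

    Negative lags measure sensitivity (activity preceding the spike).
    Returns (lags, Gamma) with NaN when the neuron never spikes between NS.
    """
    if lags is None:
        lags = np.arange(-100.0, 0.5, 1.0)
    lags = np.asarray(lags, dtype=float)
    sp = result.spikes_of(neuron)
    sp = sp[between_ns_mask(sp, events)]
    if sp.size == 0:
        return lags, np.full(lags.size, np.nan)
    a = activity.values
    a_mean = a.mean()
    t0 = activity.times[0]
    gamma = np.empty(lags.size)
    for q, lag in enumerate(lags):
        idx = np.round((sp + lag - t0) / activity.stride).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < a.size)]
        gamma[q] = a[idx].mean() - a_mean if idx.size else np.nan
    return lags, gamma


def fixed_kernel_density(samples: np.ndarray, grid: np.ndarray,
                         bandwidth: float) -> np.ndarray:
    """Gaussian kernel density with a fixed bandwidth (not Scott/Silverman),
    matching the fixed kernel widths used for all densities here."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        return np.zeros(grid.size)
    z = (grid[:, None] - samples[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (samples.size * bandwidth *
                                               np.sqrt(2 * np.pi))


def resource_density(result: SimulationResult,
                     events: Sequence[NetworkSpikeEvent], neuron: int,
                     bandwidth: float = 0.05,
                     grid: Optional[np.ndarray] = None) -> tuple:
    """Density of the neuron's efferent-averaged recovered resources R
    over between-NS sample times (kernel width 0.05).

    Returns (grid, density, samples)."""
    if result.resources is None:
        raise ValueError("simulation was run without record_resources")
    if grid is None:
        grid = np.linspace(0.0, 1.2, 241)
    mask = between_ns_mask(result.resource_times, events)
    samples = result.resources[mask, neuron].astype(float)
    return grid, fixed_kernel_density(samples, grid, bandwidth), samples


def psp_estimates(topo: NetworkTopology, rates_hz: np.ndarray,
                  v_mean: np.ndarray,
                  params: Optional[tuple] = None) -> pd.DataFrame:
    """Closed-form post-synaptic potential estimates per excitatory neuron.

    For every efferent synapse i -> j of an excitatory neuron i firing at
    its between-NS rate nu_i, the single-spike PSP peaks at
    t_max = tau_m tau_I/(tau_m - tau_I) * log(tau_m/tau_I) with amplitude
    W_ji(t_max); the cumulative steady-state effect of Poisson firing is
    <W_ji>_ss.  Depression enters through the factor 1/(1 + U tau_rec nu).
    The driving force uses the target's mean star voltage and is treated
    as constant.  Returns per-neuron means over efferent targets and
    summed variants (mean x N_i).
    """
    p_exc, p_inh = params if params is not None else (exc_params(), inh_params())
    n_exc = topo.n_exc
    src_exc = topo.pre < n_exc
    pre = topo.pre[src_exc]
    post = topo.post[src_exc]
    w = topo.weight[src_exc]
    U = topo.U[src_exc]
    tau_rec_s = topo.tau_rec[src_exc] / 1000.0
    tau_i = 3.0  # ms, synapses from excitatory sources
    tau_i_s = tau_i / 1000.0

    tgt_exc = post < n_exc
    tau_m = np.where(tgt_exc, p_exc.tau_m, p_inh.tau_m)
    r_m = np.where(tgt_exc, p_exc.R_m, p_inh.R_m)
    drive = p_exc.E_exc - v_mean[post]  # mV
    nu = rates_hz[pre]

    t_max = tau_m * tau_i / (tau_m - tau_i) * np.log(tau_m / tau_i)
    shape = np.exp(-t_max / tau_m) - np.exp(-t_max / tau_i)
    depress = 1.0 + U * tau_rec_s * nu
    # MOhm * pS -> 1e-6 (dimensionless); result in mV
    w_single = (tau_i / (tau_m - tau_i)) * U * w * r_m * 1e-6 * drive \
        * shape / depress
    w_ss = r_m * 1e-6 * w * drive * tau_i_s * U * nu / depress

    df = pd.DataFrame({"pre": pre, "w_single_mV": w_single, "w_ss_mV": w_ss})
    agg = df.groupby("pre").agg(
        psp_single_mV=("w_single_mV", "mean"),
        psp_ss_mV=("w_ss_mV", "mean"),
        n_targets=("w_single_mV", "size"),
    )
    out = agg.reindex(np.arange(n_exc), fill_value=0.0)
    out["n_targets"] = out["n_targets"].fillna(0).astype(int)
    out["psp_single_sum_mV"] = out["psp_single_mV"] * out["n_targets"]
    out["psp_ss_sum_mV"] = out["psp_ss_mV"] * out["n_targets"]
    out.index.name = "neuron_id"
    return out


def psp_peak_time(tau_m: float, tau_i: float) -> float:
    """Time to peak (ms) of the double-exponential PSP."""
    return tau_m * tau_i / (tau_m - tau_i) * np.log(tau_m / tau_i)


def _ns_free_spikes(result: SimulationResult,
                    events: Sequence[NetworkSpikeEvent], neuron: int) -> np.ndarray:
    sp = result.spikes_of(neuron)
    return sp[between_ns_mask(sp, events)]


def power_spectrum(result: SimulationResult,
                   events: Sequence[NetworkSpikeEvent],
                   neurons: Optional[Sequence[int]] = None,
                   bin_t_s: float = 20.0, dt_ms: float = 0.1):
    """Per-neuron periodogram of the spike Dirac comb with NSs removed.

    The retained recording is split into disjoint bins of length
    ``bin_t_s``; for each bin, S(f) = |sum_k exp(i 2 pi f t_k)|^2 / T,
    averaged over bins.  For a Poisson train, S(f) tends to the rate at
    high frequency.  Returns (freqs_Hz, S) with S of shape
    (len(neurons), n_freqs), plus the list of neurons used.
    """
    if neurons is None:
        neurons = np.arange(result.n_exc)
    neurons = np.asarray(neurons, dtype=int)
    t0, t1 = result.warmup, result.duration
    bin_len = bin_t_s * 1000.0
    n_bins = int((t1 - t0) // bin_len)
    if n_bins == 0:
        raise ValueError("recording shorter than one spectral bin")
    n_samp = int(round(bin_len / dt_ms))
    freqs = np.fft.rfftfreq(n_samp, d=dt_ms / 1000.0)
    S = np.zeros((neurons.size, freqs.size))
    for q, nid in enumerate(neurons):
        sp = _ns_free_spikes(result, events, nid)
        acc = np.zeros(freqs.size)
        for b in range(n_bins):
            lo = t0 + b * bin_len
            seg = sp[(sp >= lo) & (sp < lo + bin_len)] - lo
            counts = np.bincount((seg / dt_ms).astype(np.int64) % n_samp,
                                 minlength=n_samp)
            acc += np.abs(np.fft.rfft(counts)) ** 2 / bin_t_s
        S[q] = acc / n_bins
    return freqs, S, neurons


def pairwise_correlation(result: SimulationResult,
                         events: Sequence[NetworkSpikeEvent],
                         kernel_ms: float = 0.5, bin_t_s: float = 20.0):
    """Zero-lag correlation between excitatory spike trains, between NSs.

    Spike trains (NSs removed) are regularized with 0.5 ms square kernels
    (equivalently binned at 0.5 ms); for each pair of distinct excitatory
    neurons that both discharge between NSs, the normalized scalar product
    of the two trains is ensemble-averaged over disjoint 20-s bins.
    Returns (mean, sd, n_pairs, C) where C is the condensed pair vector.
    """
    from scipy import sparse

    n_exc = result.n_exc
    t0, t1 = result.warmup, result.duration
    bin_len = bin_t_s * 1000.0
    n_bins = int((t1 - t0) // bin_len)
    if n_bins == 0:
        raise ValueError("recording shorter than one correlation bin")
    n_samp = int(round(bin_len / kernel_ms))

    sel = (result.spike_neuron < n_exc) & ~result.spike_forced
    sp_n = result.spike_neuron[sel]
    sp_t = result.spike_time[sel]
    keep = between_ns_mask(sp_t, events)
    sp_n, sp_t = sp_n[keep], sp_t[keep]

    num = np.zeros((n_exc, n_exc))
    for b in range(n_bins):
        lo = t0 + b * bin_len
        in_bin = (sp_t >= lo) & (sp_t < lo + bin_len)
        cols = ((sp_t[in_bin] - lo) / kernel_ms).astype(np.int64) % n_samp
        x = sparse.coo_matrix(
            (np.ones(cols.size), (sp_n[in_bin], cols)),
            shape=(n_exc, n_samp)).tocsr()
        num += (x @ x.T).toarray()
    num /= n_bins
    diag = np.diag(num).copy()
    active = diag > 0
    denom = np.sqrt(np.outer(diag, diag))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = num / denom
    iu = np.triu_indices(n_exc, k=1)
    pair_ok = active[iu[0]] & active[iu[1]]
    vals = C[iu][pair_ok]
    if vals.size == 0:
        return np.nan, np.nan, 0, vals
    return float(vals.mean()), float(vals.std(ddof=1)), int(vals.size), vals


def compute_neuron_metrics(result: SimulationResult, activity: ActivityTrace,
                           events: Sequence[NetworkSpikeEvent]) -> pd.DataFrame:
    """Aggregate per-excitatory-neuron metrics table.

    Columns: neuron_id, sorted_id, rate_Hz, mean_latency_ms, inv_cv_tau,
    cv_tau, star_mean_mV, star_sd_mV, cv_vstar, is_pioneer.
    """
    ro = sort_by_rate(result)
    table = first_spike_latencies(result, events)
    inv_cv = latency_consistency(table)
    cv_tau = latency_cv(table)
    stars = star_voltage_stats(result, events)
    is_p, _ = identify_pioneers(cv_tau, stars.cv[:result.n_exc])
    return pd.DataFrame({
        "neuron_id": np.arange(result.n_exc),
        "sorted_id": ro.rank,
        "rate_Hz": ro.rates,
        "mean_latency_ms": mean_latency(table),
        "inv_cv_tau": inv_cv,
        "cv_tau": cv_tau,
        "star_mean_mV": stars.mean[:result.n_exc],
        "star_sd_mV": stars.sd[:result.n_exc],
        "cv_vstar": stars.cv[:result.n_exc],
        "is_pioneer": is_p,
    })


def pioneer_fraction(result: SimulationResult, activity: ActivityTrace,
                     events: Sequence[NetworkSpikeEvent]) -> float:
    """Fraction of excitatory neurons satisfying the pioneer criterion."""
    df = compute_neuron_metrics(result, activity, events)
    return float(df["is_pioneer"].mean())
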