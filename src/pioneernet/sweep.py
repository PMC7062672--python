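"""Excitation/inhibition landscape sweeps across connection topologies.

The four mean connection strengths scale as omega_ee = r_E * wbar_ee,
omega_ie = r_E * wbar_ie (excitatory sources) and omega_ei = r_I * wbar_ei,
omega_ii = r_I * wbar_ii (inhibitory sources) relative to a prototypical
network per topology.  Each grid point is simulated for several
realizations; NS statistics, pioneer fractions and a dynamical-regime
label are collected:

* transitional — pronounced all-or-none synchronization events,
  A_max / A_mean >= 30;
* tonic — excitation-dominated: frequent, regular events
  (NS rate > 2 Hz and CV_INSI < 0.3);
* asynchronous — everything else (inhibition-dominated, small events).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import NetworkConfig
from .dynamics import population_activity, simulate
from .events import detect_network_spikes, ns_statistics
from .metrics import pioneer_fraction
from .topology import make_topology

REGIME_RATIO = 30.0
TONIC_NS_RATE_HZ = 2.0
TONIC_CV_MAX = 0.3


@dataclass
class SweepPoint:
    """Summary of one (topology, r_E, r_I, seed) simulation."""

    topology_kind: str
    r_E: float
    r_I: float
    seed: int
    n_ns: int
    t_insi_ms: float
    cv_insi: float
    a_max_over_a_mean: float
    ns_rate_hz: float
    pioneer_fraction: float
    regime: str


def classify_regime(a_max_over_a_mean: float, ns_rate_hz: float,
                    cv_insi: float) -> str:
    if a_max_over_a_mean >= REGIME_RATIO:
        return "transitional"
    if ns_rate_hz > TONIC_NS_RATE_HZ and (np.isfinite(cv_insi)
                                          and cv_insi < TONIC_CV_MAX):
        return "tonic"
    return "asynchronous"


def run_point(kind: str, r_e: float, r_i: float, seed: int,
              duration_ms: float = 102_000.0,
              n_exc: int = 400, n_inh: int = 100,
              compute_pioneers: bool = True) -> SweepPoint:
    """Simulate one network realization and summarize it."""
    cfg = NetworkConfig(n_exc=n_exc, n_inh=n_inh, topology_kind=kind,
                        r_E=r_e, r_I=r_i, seed=seed)
    topo = make_topology(cfg)
    res = simulate(topo, duration_ms, seed=seed,
                   record_vstar=compute_pioneers)
    act = population_activity(res)
    events = detect_network_spikes(act)
    stats = ns_statistics(events, act)
    span_s = res.analysis_span_ms / 1000.0
    frac = pioneer_fraction(res, act, events) if compute_pioneers else np.nan
    return SweepPoint(
        topology_kind=kind, r_E=r_e, r_I=r_i, seed=seed,
        n_ns=len(events), t_insi_ms=stats.t_insi, cv_insi=stats.cv_insi,
        a_max_over_a_mean=stats.a_max_over_a_mean,
        ns_rate_hz=len(events) / span_s,
        pioneer_fraction=frac,
        regime=classify_regime(stats.a_max_over_a_mean,
                               len(events) / span_s, stats.cv_insi),
    )


def run_sweep(grid: Sequence, kinds: Sequence[str], realizations: int = 3,
              duration_ms: float = 102_000.0, seed: int = 0,
              n_exc: int = 400, n_inh: int = 100,
              compute_pioneers: bool = True,
              progress: bool = False) -> pd.DataFrame:
    """Sweep a grid of (r_E, r_I) pairs for each topology kind.

    Returns one row per (kind, r_E, r_I, realization).  Per-point failures
    are recorded with NaN statistics rather than aborting the sweep.
    """
    rows = []
    for kind in kinds:
        for (r_e, r_i) in grid:
            for q in range(realizations):
                point_seed = int(seed + 1000 * q + 7)
                try:
                    pt = run_point(kind, float(r_e), float(r_i), point_seed,
                                   duration_ms=duration_ms, n_exc=n_exc,
                                   n_inh=n_inh,
                                   compute_pioneers=compute_pioneers)
                except Exception:
                    pt = SweepPoint(kind, float(r_e), float(r_i), point_seed,
                                    0, np.nan, np.nan, np.nan, np.nan,
                                    np.nan, "failed")
                rows.append(dataclasses.asdict(pt))
                if progress:
                    print(f"  {kind} rE={r_e} rI={r_i} seed={point_seed}: "
                          f"{rows[-1]['regime']}, NS={rows[-1]['n_ns']}")
    return pd.DataFrame(rows)


def ns_presence(table: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Grid points where at least ``threshold`` of realizations produced
    all-or-none NSs (transitional regime), per topology kind."""
    def frac_with_ns(g):
        return (g["regime"] == "transitional").mean()

    agg = (table.groupby(["topology_kind", "r_E", "r_I"])
           .apply(frac_with_ns, include_groups=False)
           .rename("ns_fraction").reset_index())
    agg["present"] = agg["ns_fraction"] >= threshold
    return agg


def rate_disparity(table: pd.DataFrame) -> pd.DataFrame:
    """NS-rate ratios for all ordered topology pairs at identical (r_E, r_I).

    Only points where both members express NSs contribute.  Returns rows
    (kind_a, kind_b, r_E, r_I, rate_a, rate_b, ratio = rate_a / rate_b).
    """
    mean_rates = (table[table["n_ns"] > 0]
                  .groupby(["topology_kind", "r_E", "r_I"])["ns_rate_hz"]
                  .mean().reset_index())
    rows = []
    kinds = mean_rates["topology_kind"].unique()
    for ka in kinds:
        for kb in kinds:
            if ka == kb:
                continue
            a = mean_rates[mean_rates["topology_kind"] == ka]
            b = mean_rates[mean_rates["topology_kind"] == kb]
            merged = a.merge(b, on=["r_E", "r_I"], suffixes=("_a", "_b"))
            for _, r in merged.iterrows():
                rows.append({
                    "kind_a": ka, "kind_b": kb,
                    "r_E": r["r_E"], "r_I": r["r_I"],
                    "rate_a": r["ns_rate_hz_a"], "rate_b": r["ns_rate_hz_b"],
                    "ratio": r["ns_rate_hz_a"] / r["ns_rate_hz_b"],
                })
    return pd.DataFrame(rows)
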