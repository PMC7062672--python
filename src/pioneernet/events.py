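"""Network-spike detection, fluctuation statistics and NS classification.

A network spike (NS) is a brief, all-or-none synchronization event that
recruits nearly all excitatory neurons.  NSs are detected as maximal
excursions of the excitatory population activity above a high threshold,
half the maximal observed activity; smaller fluctuations are detected with
a low threshold just above the mean.  In the super-critical regime the
distribution of fluctuation peak amplitudes is bimodal — a low mode of
failed ignitions and a high mode of full NSs with an empty gap in between —
and the top of the low mode bounds the network's ignition threshold from
below.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import ActivityTrace, StimulationProtocol
from .config import substream

#: Half-width (ms) of the exclusion window around an NS peak used by all
#: "between NS" analyses.
NS_EXCLUSION_MS = 35.0

SPONTANEOUS = "spontaneous"


@dataclass
class NetworkSpikeEvent:
    """One detected synchronization event."""

    t_peak: float    # ms
    a_max: float     # Hz
    t_onset: float   # ms
    t_offset: float  # ms
    label: str = SPONTANEOUS
    site: int = -1   # stimulation site for evoked events, else -1

    @property
    def duration(self) -> float:
        return self.t_offset - self.t_onset


@dataclass
class ThresholdEstimate:
    """NS-initiation threshold (Hz).  When no high mode of full NSs exists,
    only a lower bound can be stated (even the largest fluctuations failed
    to ignite)."""

    value_hz: float
    lower_bound_only: bool


@dataclass
class FluctuationSummary:
    """Macroscopic summary of one recording."""

    n_events: int
    t_insi: float                   # mean inter-NS interval, ms (NaN if <2)
    cv_insi: float                  # sd/mean of intervals (NaN if <3 events)
    a_max_over_a_mean: float
    a_mean: float                   # Hz
    bimodal: bool
    all_or_none: bool               # a_max/a_mean >= 30
    initiation_threshold: Optional[ThresholdEstimate] = None

    @property
    def ns_rate_hz(self) -> float:
        return 1000.0 / self.t_insi if np.isfinite(self.t_insi) else 0.0


def _excursions(values: np.ndarray, threshold: float):
    """Maximal intervals with values > threshold -> (start, end) index pairs."""
    above = values > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(values))
    return list(zip(starts, ends))


def detect_network_spikes(activity: ActivityTrace,
                          theta_high: Optional[float] = None) -> list:
    """Detect NSs as maximal excursions of A(t) above ``theta_high``
    (default: half the maximal activity of this trace).

    Onset/offset are the successive crossings of the threshold from below
    and from above; the peak is the maximum inside the excursion.
    """
    values, times = activity.values, activity.times
    if values.size == 0 or not values.any():
        return []
    if theta_high is None:
        theta_high = 0.5 * values.max()
    events = []
    for s, e in _excursions(values, theta_high):
        k = s + int(values[s:e].argmax())
        events.append(NetworkSpikeEvent(
            t_peak=float(times[k]), a_max=float(values[k]),
            t_onset=float(times[s]),
            t_offset=float(times[min(e, len(times) - 1)]),
        ))
    return events


def detect_fluctuations(activity: ActivityTrace,
                        theta_low: Optional[float] = None) -> np.ndarray:
    """Peak amplitude (Hz) of every excursion above ``theta_low``
    (default 1.1 x mean activity)."""
    values = activity.values
    if values.size == 0:
        return np.empty(0)
    if theta_low is None:
        theta_low = 1.1 * values.mean()
    return np.array([values[s:e].max() for s, e in _excursions(values, theta_low)])


def peak_times(activity: ActivityTrace, events: Sequence[NetworkSpikeEvent]) -> np.ndarray:
    return np.array([ev.t_peak for ev in events])


def between_ns_mask(times: np.ndarray, events: Sequence[NetworkSpikeEvent],
                    half_width: float = NS_EXCLUSION_MS) -> np.ndarray:
    """Boolean mask of time points farther than ``half_width`` from every
    NS peak."""
    times = np.asarray(times, dtype=float)
    mask = np.ones(times.size, dtype=bool)
    peaks = np.sort([ev.t_peak for ev in events])
    if peaks.size == 0:
        return mask
    idx = np.searchsorted(peaks, times)
    for off in (-1, 0):
        j = np.clip(idx + off, 0, peaks.size - 1)
        mask &= np.abs(times - peaks[j]) > half_width
    return mask


def initiation_threshold(peaks: np.ndarray, a_mean: float,
                         low_mult: float = 10.0,
                         high_mult: float = 40.0) -> ThresholdEstimate:
    """Largest fluctuation peak below the bimodality gap (Hz).

    When no high mode of full NSs exists (no peak above ``high_mult`` times
    the mean) the largest observed peak is returned as a lower bound only.
    The gap is located as the largest ratio between consecutive sorted
    peak values.
    """
    peaks = np.sort(np.asarray(peaks, dtype=float))
    if peaks.size == 0:
        return ThresholdEstimate(0.0, True)
    rel = peaks / a_mean if a_mean > 0 else peaks
    if rel[-1] < high_mult:
        return ThresholdEstimate(float(peaks[-1]), True)
    if peaks.size == 1 or rel[0] >= high_mult:
        # only full NSs observed: no usable low mode
        return ThresholdEstimate(0.0, True)
    ratios = peaks[1:] / peaks[:-1]
    split = int(ratios.argmax())
    return ThresholdEstimate(float(peaks[split]), False)


def ns_statistics(events: Sequence[NetworkSpikeEvent], activity: ActivityTrace,
                  low_mult: float = 10.0, high_mult: float = 40.0) -> FluctuationSummary:
    """Interval statistics, activity ratio and bimodality for one trace.

    Interval statistics (T_INSI, CV_INSI) need at least 2 resp. 3 events
    and are NaN otherwise.  The bimodality flag requires probability mass
    below ``low_mult`` x mean and above ``high_mult`` x mean with an empty
    gap in between; ``all_or_none`` flags A_max/A_mean >= 30.
    """
    peaks_t = np.sort([ev.t_peak for ev in events])
    intervals = np.diff(peaks_t)
    t_insi = float(intervals.mean()) if intervals.size >= 1 else np.nan
    cv = float(intervals.std(ddof=1) / intervals.mean()) if intervals.size >= 2 else np.nan
    a_mean = activity.a_mean
    ratio = activity.a_max / a_mean if a_mean > 0 else np.nan
    fpeaks = detect_fluctuations(activity)
    rel = fpeaks / a_mean if a_mean > 0 else fpeaks
    bimodal = bool(rel.size and (rel < low_mult).any() and (rel > high_mult).any()
                   and not ((rel >= low_mult) & (rel <= high_mult)).any())
    thr = initiation_threshold(fpeaks, a_mean, low_mult, high_mult)
    return FluctuationSummary(
        n_events=len(events), t_insi=t_insi, cv_insi=cv,
        a_max_over_a_mean=float(ratio), a_mean=float(a_mean),
        bimodal=bimodal, all_or_none=bool(ratio >= 30.0),
        initiation_threshold=thr,
    )


@dataclass
class StimulationOutcome:
    """Per-stimulation timing relative to the NS sequence."""

    time: float
    site: int
    since_last_ns: float   # ms, inf if none before
    to_next_ns: float      # ms, inf if none after
    success: bool
    ns_index: int          # index into the event list, -1 if unsuccessful


def classify_ns(events: Sequence[NetworkSpikeEvent],
                protocol: StimulationProtocol,
                window: float = 100.0,
                analysis_span: Optional[tuple] = None,
                surrogate_seed: int = 0):
    """Label NSs as evoked-at-site-k or spontaneous.

    A stimulation is successful when the next NS peak follows within
    ``window`` ms; that NS is labelled evoked at the stimulation site.
    Also returns the (time since last NS, time to next NS) scatter for the
    real stimulations and for an equal number of uniformly random
    surrogate times, whose scatter is continuous rather than clustered.
    """
    peaks = np.sort([ev.t_peak for ev in events])
    order = np.argsort([ev.t_peak for ev in events])

    def timings(times):
        idx = np.searchsorted(peaks, times)
        since = np.where(idx > 0, times - peaks[np.clip(idx - 1, 0, None)], np.inf)
        to_next = np.where(idx < peaks.size,
                           peaks[np.clip(idx, None, peaks.size - 1)] - times, np.inf)
        return since, to_next, idx

    for ev in events:
        ev.label = SPONTANEOUS
        ev.site = -1
    outcomes = []
    if protocol is not None and protocol.n_events:
        since, to_next, idx = timings(protocol.event_times)
        for q, (t, k) in enumerate(zip(protocol.event_times, protocol.event_sites)):
            success = bool(to_next[q] <= window)
            ns_index = -1
            if success:
                ns_index = int(order[idx[q]])
                ev = events[ns_index]
                ev.label = f"evoked_site_{int(k)}"
                ev.site = int(k)
            outcomes.append(StimulationOutcome(
                time=float(t), site=int(k), since_last_ns=float(since[q]),
                to_next_ns=float(to_next[q]), success=success,
                ns_index=ns_index))
    # surrogate scatter
    n_sur = len(outcomes)
    surrogate = np.empty((0, 2))
    if n_sur and analysis_span is not None:
        rng = substream(surrogate_seed, "surrogate")
        ts = np.sort(rng.uniform(analysis_span[0], analysis_span[1], size=n_sur))
        s_since, s_next, _ = timings(ts)
        surrogate = np.column_stack([s_since, s_next])
    return events, outcomes, surrogate
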