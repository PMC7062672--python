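"""Stimulus-site decoding from activity around network spikes.

Four feature sets describe the 100 ms of (synaptically mediated) activity
that follows a stimulation, for a cohort of n neurons:

* spike times  — first spike of each neuron in the window;
* spike order  — rank order of those first spikes (earliest = 1), missing
  spikes filled in at the highest ranks;
* neuronal rates — per-neuron spike count / window;
* temporal rates — cohort-summed counts in 50 successive 2-ms bins.

A linear-kernel SVM trained on a stratified split measures how much each
feature reveals about the stimulated site.  Rank orders are compared with
the spike-order similarity (SOS), an inversion-count statistic:
``SOS = (1 - 2L/(n(n-1))) * 100 %`` where L counts pairwise inversions
between the two orders (0 for identical, n(n-1)/2 for reversed orders).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import substream
from .dynamics import SimulationResult
from .events import NetworkSpikeEvent, SPONTANEOUS

FEATURES = ("spike_time", "spike_order", "neuronal_rates", "temporal_rates")


@dataclass
class DecodingDataset:
    """Per-NS feature vectors with stimulation-site labels.

    ``labels`` holds the site index for evoked NSs and -1 for spontaneous
    ones.  Feature arrays are (n_ns, ...); the k-bin interpolation between
    rate- and spike-based coding is produced on demand by ``kbin_rates``.
    """

    cohort: np.ndarray          # neuron IDs
    labels: np.ndarray          # int, -1 = spontaneous
    anchors: np.ndarray         # ms, window start per NS
    spike_time: np.ndarray      # (n_ns, n) ms relative to anchor; window if missing
    spike_order: np.ndarray     # (n_ns, n) permutation of 1..n
    neuronal_rates: np.ndarray  # (n_ns, n) Hz
    temporal_rates: np.ndarray  # (n_ns, 50)
    window: float = 100.0
    _counts: Optional[np.ndarray] = None  # per-neuron per-bin counts, fine bins

    @property
    def n_ns(self) -> int:
        return int(self.labels.size)

    def feature(self, name: str) -> np.ndarray:
        if name not in FEATURES:
            raise ValueError(f"unknown feature {name!r}")
        x = getattr(self, name)
        return x.reshape(x.shape[0], -1)

    def kbin_rates(self, k: int) -> np.ndarray:
        """Per-neuron spike counts in k bins of window/k ms -> (n_ns, n*k)."""
        if self._counts is None:
            raise ValueError("dataset built without fine-grained counts")
        n_fine = self._counts.shape[2]
        if n_fine % k:
            raise ValueError(f"k={k} must divide {n_fine} fine bins")
        c = self._counts.reshape(self.n_ns, len(self.cohort), k, n_fine // k)
        return c.sum(axis=3).reshape(self.n_ns, -1)

    def evoked(self) -> "DecodingDataset":
        """Subset containing only evoked NSs."""
        sel = self.labels >= 0
        return DecodingDataset(
            cohort=self.cohort, labels=self.labels[sel],
            anchors=self.anchors[sel], spike_time=self.spike_time[sel],
            spike_order=self.spike_order[sel],
            neuronal_rates=self.neuronal_rates[sel],
            temporal_rates=self.temporal_rates[sel], window=self.window,
            _counts=None if self._counts is None else self._counts[sel])


def rank_order(latencies: np.ndarray, window: float = np.inf) -> np.ndarray:
    """Rank order of first-spike latencies: earliest spike gets rank 1.

    ``latencies`` may contain NaN (no spike); missing entries are filled
    in at the highest ranks, in ascending neuron-ID order.  Ties in
    latency are broken by neuron ID.
    """
    lat = np.asarray(latencies, dtype=float)
    key = np.where(np.isnan(lat), np.inf, lat)
    order = np.argsort(key, kind="stable")
    ranks = np.empty(lat.size, dtype=np.int64)
    ranks[order] = np.arange(1, lat.size + 1)
    return ranks


def extract_features(result: SimulationResult,
                     events: Sequence[NetworkSpikeEvent],
                     cohort: Sequence[int], window: float = 100.0,
                     stim_outcomes: Optional[Sequence] = None,
                     n_temporal_bins: int = 50,
                     fine_bins: int = 100) -> DecodingDataset:
    """Build the four feature sets for each labelled NS.

    Evoked NSs anchor the window at their stimulation time; spontaneous
    NSs at t_peak - window (so spontaneous/evoked comparisons remain
    possible).  Forced spikes are excluded throughout.
    """
    cohort = np.asarray(cohort, dtype=int)
    n = cohort.size
    anchor_by_ns = {}
    if stim_outcomes is not None:
        for oc in stim_outcomes:
            if oc.success and oc.ns_index >= 0:
                anchor_by_ns[oc.ns_index] = oc.time
    labels, anchors = [], []
    for k, ev in enumerate(events):
        if ev.label == SPONTANEOUS:
            labels.append(-1)
            anchors.append(ev.t_peak - window)
        else:
            labels.append(ev.site)
            anchors.append(anchor_by_ns.get(k, ev.t_peak - window))
    labels = np.asarray(labels, dtype=np.int64)
    anchors = np.asarray(anchors, dtype=float)
    n_ns = labels.size

    pos_in_cohort = {int(c): q for q, c in enumerate(cohort)}
    sel = ~result.spike_forced & np.isin(result.spike_neuron, cohort)
    sp_n = result.spike_neuron[sel]
    sp_t = result.spike_time[sel]

    spike_time = np.full((n_ns, n), window, dtype=float)
    latency = np.full((n_ns, n), np.nan)
    counts_fine = np.zeros((n_ns, n, fine_bins), dtype=np.int32)
    for k in range(n_ns):
        a = anchors[k]
        in_win = (sp_t > a) & (sp_t <= a + window)
        for nid, t in zip(sp_n[in_win], sp_t[in_win]):
            q = pos_in_cohort[int(nid)]
            rel = t - a
            if np.isnan(latency[k, q]) or rel < latency[k, q]:
                latency[k, q] = rel
                spike_time[k, q] = rel
            b = min(int(rel / window * fine_bins), fine_bins - 1)
            counts_fine[k, q, b] += 1
    spike_order = np.vstack([rank_order(latency[k]) for k in range(n_ns)]) \
        if n_ns else np.empty((0, n), dtype=np.int64)
    neuronal_rates = counts_fine.sum(axis=2) / (window / 1000.0)
    if fine_bins % n_temporal_bins:
        raise ValueError("fine_bins must be a multiple of n_temporal_bins")
    grp = fine_bins // n_temporal_bins
    temporal = counts_fine.sum(axis=1).reshape(n_ns, n_temporal_bins, grp).sum(axis=2)
    return DecodingDataset(
        cohort=cohort, labels=labels, anchors=anchors,
        spike_time=spike_time, spike_order=spike_order,
        neuronal_rates=neuronal_rates.astype(float),
        temporal_rates=temporal.astype(float), window=window,
        _counts=counts_fine)


def classify_sites(dataset: DecodingDataset, feature: str = "spike_order",
                   train_fraction: float = 0.5, repeats: int = 20,
                   seed: int = 0, k_bins: Optional[int] = None,
                   max_iter: int = -1) -> float:
    """Mean test accuracy of a linear-kernel SVM decoding the site label.

    Evoked NSs only; stratified ``train_fraction`` split, repeated
    ``repeats`` times.  Chance level is 1/#sites.
    """
    from sklearn.model_selection import StratifiedShuffleSplit
    from sklearn.svm import SVC

    ds = dataset.evoked()
    if np.unique(ds.labels).size < 2:
        raise ValueError("need at least two stimulation sites with evoked NSs")
    x = ds.kbin_rates(k_bins) if k_bins is not None else ds.feature(feature)
    y = ds.labels
    rng = substream(seed, "classifier")
    splitter = StratifiedShuffleSplit(
        n_splits=repeats, train_size=train_fraction,
        random_state=int(rng.integers(2**31)))
    accs = []
    for train, test in splitter.split(x, y):
        clf = SVC(kernel="linear", max_iter=max_iter)
        clf.fit(x[train], y[train])
        accs.append(clf.score(x[test], y[test]))
    return float(np.mean(accs))


def _inversions(perm: np.ndarray) -> int:
    """Number of pairs (i, j), i<j, with perm[i] > perm[j] (merge count)."""
    a = list(perm)
    n = len(a)
    if n < 2:
        return 0
    buf = a[:]
    count = 0
    width = 1
    while width < n:
        for lo in range(0, n, 2 * width):
            mid = min(lo + width, n)
            hi = min(lo + 2 * width, n)
            i, j, k = lo, mid, lo
            while i < mid and j < hi:
                if a[i] <= a[j]:
                    buf[k] = a[i]
                    i += 1
                else:
                    buf[k] = a[j]
                    count += mid - i
                    j += 1
                k += 1
            buf[k:hi] = a[i:mid] if i < mid else a[j:hi]
        a, buf = buf, a
        width *= 2
    return count


def sos(order_a: Sequence[int], order_b: Sequence[int]) -> float:
    """Spike-order similarity between two rank orders, in percent.

    100 % for identical orders, 0 % for fully reversed ones; invariant
    under relabelling applied to both orders.
    """
    a = np.asarray(order_a, dtype=np.int64)
    b = np.asarray(order_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("orders must be 1-D of equal length")
    n = a.size
    if n < 2:
        raise ValueError("orders must have length >= 2")
    for v in (a, b):
        if not np.array_equal(np.sort(v), np.arange(1, n + 1)):
            raise ValueError("inputs must be permutations of 1..n")
    # relative permutation: order of b along the sequence sorted by a
    rel = b[np.argsort(a)]
    L = _inversions(rel)
    return float((1.0 - 2.0 * L / (n * (n - 1))) * 100.0)


@dataclass
class SOSMatrix:
    """Pairwise SOS between NSs, rows/cols sorted by class (S, E1, E2...)."""

    values: np.ndarray        # (n_ns, n_ns) percent
    labels: np.ndarray        # sorted class label per row
    boundaries: np.ndarray    # cumulative class sizes

    def block_means(self) -> np.ndarray:
        classes = np.unique(self.labels)
        out = np.full((classes.size, classes.size), np.nan)
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                block = self.values[np.ix_(self.labels == ci, self.labels == cj)]
                if i == j:
                    n = block.shape[0]
                    if n > 1:
                        out[i, j] = block[~np.eye(n, dtype=bool)].mean()
                elif block.size:
                    out[i, j] = block.mean()
        return out


def sos_matrix(dataset: DecodingDataset) -> SOSMatrix:
    """All-pairs SOS of the dataset's spike orders, class-sorted
    (spontaneous first, then sites in ascending order)."""
    if dataset.n_ns < 2:
        raise ValueError("need at least two NSs")
    order = np.argsort(dataset.labels, kind="stable")
    labels = dataset.labels[order]
    perms = dataset.spike_order[order]
    m = dataset.n_ns
    vals = np.full((m, m), 100.0)
    for i in range(m):
        for j in range(i + 1, m):
            vals[i, j] = vals[j, i] = sos(perms[i], perms[j])
    classes, counts = np.unique(labels, return_counts=True)
    return SOSMatrix(values=vals, labels=labels,
                     boundaries=np.cumsum(counts))


def class_distance(sos_within: np.ndarray, sos_between: np.ndarray) -> float:
    """Distance between two SOS distributions:
    z = |mu2 - mu1| / (sigma1 + sigma2)."""
    w = np.asarray(sos_within, dtype=float)
    b = np.asarray(sos_between, dtype=float)
    if w.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    s1, s2 = w.std(ddof=0), b.std(ddof=0)
    if s1 + s2 == 0:
        raise ValueError("samples have no spread")
    return float(abs(b.mean() - w.mean()) / (s1 + s2))


def within_between_sos(mat: SOSMatrix, exclude_spontaneous: bool = True):
    """Split the SOS matrix into within-class and between-class samples."""
    labels = mat.labels
    m = labels.size
    iu = np.triu_indices(m, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = mat.values[iu]
    if exclude_spontaneous:
        keep_w = same & (labels[iu[0]] >= 0)
        keep_b = ~same & (labels[iu[0]] >= 0) & (labels[iu[1]] >= 0)
    else:
        keep_w, keep_b = same, ~same
    return vals[keep_w], vals[keep_b]
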