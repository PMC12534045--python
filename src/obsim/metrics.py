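"""Connectivity-based memory measure and network-structure analyses.

The memory of an odor pair is read directly off the synaptic network: a GC
remembers the pair to the extent that the MCs it inhibits coincide with the
MCs the pair activates,

    mu_i = sum_j w_ji * Mbar_j

where ``Mbar`` is the mean steady-state MC response to the two odors.  Each
GC's memory is compared to a null threshold ``theta_mu(i)`` - the mean plus
three standard deviations of ``mu_i`` over degree-preserving reshuffles of
the GC's consolidated partners across all MCs - and the total memory is the
rectified sum

    mu = sum_i [ mu_i - theta_mu(i) ]_+ .

Because the default reshuffle resamples a GC's partners uniformly over all
MCs, its distribution depends on the GC only through its degree: the
shuffled ``mu_i`` is the total of a simple random sample (without
replacement) of ``d`` entries of ``Mbar``.  The exact mean and variance of
that total are available in closed form, which the "analytic" null method
uses; the "mc" method estimates the same moments by Monte-Carlo shuffling.

Learning-induced subnetworks are found by Ward-linkage agglomerative
clustering of GC connectivity columns, with split significance assessed
against top-split distances from degree-preserving shuffled networks,
applied recursively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "gc_memory",
    "null_threshold",
    "total_memory",
    "memory_score",
    "shuffle_degrees_preserved",
    "ClusterReport",
    "cluster_granule_cells",
    "label_learning_cluster",
    "birthdate_composition",
    "survival_fraction_by_birthdate",
    "overwrite_ratio",
]


# ---------------------------------------------------------------------------
# memory measure
# ---------------------------------------------------------------------------

def gc_memory(weights: np.ndarray, mean_mc_response: np.ndarray) -> np.ndarray:
    """Per-GC memory: dot product of each GC's weight column with ``Mbar``.

    ``weights`` may be a single column (length ``n_mc``) or a full
    ``(n_mc, n_gc)`` matrix; the result is a scalar or a per-GC vector.
    """
    w = np.asarray(weights, dtype=float)
    mbar = np.asarray(mean_mc_response, dtype=float)
    if w.shape[0] != mbar.shape[0]:
        raise ValueError("weight rows must match the MC response length")
    if np.any(mbar < 0):
        raise ValueError("mean MC response must be non-negative")
    return mbar @ w


def _sample_moments(mbar: np.ndarray, degree: int) -> tuple[float, float]:
    """Exact mean and SD of the total of a size-``degree`` simple random
    sample (without replacement) from the entries of ``mbar``."""
    n = mbar.size
    mean = degree * mbar.mean()
    if degree in (0, n) or n == 1:
        return mean, 0.0
    pop_var = mbar.var()  # population variance
    var = degree * pop_var * (n - degree) / (n - 1)
    return mean, float(np.sqrt(max(var, 0.0)))


def null_threshold(
    weights: np.ndarray,
    mean_mc_response: np.ndarray,
    n_shuffles: int = 10_000,
    rng: np.random.Generator | None = None,
    method: str = "mc",
    n_sd: float = 3.0,
) -> np.ndarray:
    """Per-GC null memory threshold (mean + 3 SD over reshuffles).

    For each GC, its consolidated partners are resampled uniformly over all
    MCs, preserving its degree.  GCs sharing a degree therefore share a
    threshold, so the shuffle distribution is computed once per distinct
    degree.  ``method="analytic"`` substitutes the exact moments of the
    shuffle ensemble; ``method="mc"`` estimates them from ``n_shuffles``
    draws.  Zero-degree GCs get threshold 0 by convention.
    """
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    if w.shape[0] == 1 and np.asarray(mean_mc_response).size != 1:
        w = w.T
    mbar = np.asarray(mean_mc_response, dtype=float)
    if w.shape[0] != mbar.size:
        raise ValueError("weight rows must match the MC response length")
    degrees = np.rint(w.sum(axis=0)).astype(int)
    theta = np.zeros(w.shape[1])
    if method == "analytic":
        for d in np.unique(degrees):
            if d == 0:
                continue
            mean, sd = _sample_moments(mbar, int(d))
            theta[degrees == d] = mean + n_sd * sd
        return theta
    if method != "mc":
        raise ValueError(f"unknown null method {method!r}")
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if rng is None:
        raise ValueError("Monte-Carlo null threshold requires an rng")
    n = mbar.size
    for d in np.unique(degrees):
        if d == 0:
            continue
        # n_shuffles random d-subsets of the MCs, drawn via random keys
        keys = rng.random((n_shuffles, n))
        subsets = np.argpartition(keys, d - 1, axis=1)[:, :d]
        sums = mbar[subsets].sum(axis=1)
        theta[degrees == d] = sums.mean() + n_sd * sums.std()
    return theta


def total_memory(per_gc_memory: np.ndarray, thresholds: np.ndarray) -> float:
    """Rectified, null-thresholded sum of per-GC memories."""
    mu = np.asarray(per_gc_memory, dtype=float)
    theta = np.asarray(thresholds, dtype=float)
    if mu.shape != theta.shape:
        raise ValueError("per-GC memories and thresholds must align")
    return float(np.maximum(mu - theta, 0.0).sum())


def memory_score(
    weights: np.ndarray,
    mean_mc_response: np.ndarray,
    n_shuffles: int = 10_000,
    rng: np.random.Generator | None = None,
    method: str = "analytic",
) -> float:
    """Total memory of an odor pair from connectivity and mean MC response."""
    mu = gc_memory(weights, mean_mc_response)
    theta = null_threshold(weights, mean_mc_response, n_shuffles=n_shuffles,
                           rng=rng, method=method)
    return total_memory(np.atleast_1d(mu), np.atleast_1d(theta))


# ---------------------------------------------------------------------------
# clustering of GC connectivity
# ---------------------------------------------------------------------------

def shuffle_degrees_preserved(weights: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
    """Reshuffle each GC's consolidated partners uniformly over all MCs."""
    w = np.asarray(weights)
    n_mc, n_gc = w.shape
    out = np.zeros_like(w, dtype=float)
    degrees = np.rint(w.sum(axis=0)).astype(int)
    keys = rng.random((n_gc, n_mc))
    order = np.argsort(keys, axis=1)
    for j in range(n_gc):
        out[order[j, :degrees[j]], j] = 1.0
    return out


@dataclass
class ClusterReport:
    """Result of recursive significance-tested Ward clustering of GCs."""

    labels: np.ndarray                 # per-GC cluster label (0..n_clusters-1)
    n_clusters: int
    splits: list = field(default_factory=list)  # (observed_dist, null_max) accepted
    degrees: np.ndarray | None = None
    learning_label: int | None = None


def _top_split_distance(cols: np.ndarray) -> tuple[np.ndarray, float]:
    z = linkage(cols, method="ward")
    return z, float(z[-1, 2])


def cluster_granule_cells(
    weights: np.ndarray,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    significance: str = "max",
    percentile: float = 99.9,
    min_cluster_size: int = 2,
) -> ClusterReport:
    """Recursive Ward clustering of GC connectivity with shuffle nulls.

    GCs are clustered on their binary weight columns (Euclidean metric).
    The distance between the top two clusters is compared with the same
    quantity computed on ``n_shuffles`` degree-preserving shuffled networks;
    the split is accepted if the observed distance exceeds every shuffled
    one (``significance="max"``) or the given percentile
    (``significance="percentile"``).  Accepted splits are refined
    recursively until no subgroup splits significantly.
    """
    w = np.asarray(weights, dtype=float)
    n_gc = w.shape[1]
    if n_gc < 2:
        raise ValueError("clustering needs at least two GCs")
    if rng is None:
        rng = np.random.default_rng(0)
    if significance not in ("max", "percentile"):
        raise ValueError(f"unknown significance rule {significance!r}")

    labels = np.zeros(n_gc, dtype=int)
    splits: list[tuple[float, float]] = []
    next_label = [1]

    def null_exceeded(group_w: np.ndarray, observed: float) -> tuple[bool, float]:
        dists = np.empty(n_shuffles)
        for s in range(n_shuffles):
            shuffled = shuffle_degrees_preserved(group_w, rng)
            _, dists[s] = _top_split_distance(shuffled.T)
        ref = (dists.max() if significance == "max"
               else float(np.percentile(dists, percentile)))
        return observed > ref, ref

    def recurse(idx: np.ndarray) -> None:
        if idx.size < 2 * min_cluster_size:
            return
        group_w = w[:, idx]
        if not group_w.any():
            return  # all-zero connectivity cannot split
        z, observed = _top_split_distance(group_w.T)
        if observed <= 0:
            return
        ok, ref = null_exceeded(group_w, observed)
        if not ok:
            return
        sub = fcluster(z, t=2, criterion="maxclust")
        if len(np.unique(sub)) < 2:
            return
        splits.append((observed, ref))
        idx_a = idx[sub == 1]
        idx_b = idx[sub == 2]
        labels[idx_b] = next_label[0]
        next_label[0] += 1
        recurse(idx_a)
        recurse(idx_b)

    recurse(np.arange(n_gc))
    # compact labels
    uniq, labels = np.unique(labels, return_inverse=True)
    return ClusterReport(labels=labels, n_clusters=uniq.size, splits=splits,
                         degrees=np.rint(w.sum(axis=0)).astype(int))


def label_learning_cluster(report: ClusterReport, weights: np.ndarray,
                           odor_response: np.ndarray) -> int | None:
    """Identify the "learning" cluster post hoc.

    Among clusters found significant, the learning cluster is the one whose
    GCs' connectivity overlaps most, on average, with the odor-responsive
    MCs (measured by the mean dot product of weight columns with the
    response pattern).  Returns ``None`` for a single-cluster report.
    """
    if report.n_clusters < 2:
        report.learning_label = None
        return None
    w = np.asarray(weights, dtype=float)
    resp = np.asarray(odor_response, dtype=float)
    overlap = resp @ w
    means = [overlap[report.labels == lab].mean()
             for lab in range(report.n_clusters)]
    report.learning_label = int(np.argmax(means))
    return report.learning_label


# ---------------------------------------------------------------------------
# birthdate / survival composition
# ---------------------------------------------------------------------------

#: Default birthdate windows (days relative to enrichment onset).  GCs whose
#: dendrites were still developing at onset are those added during (or just
#: before the end of) enrichment; GCs in their critical period at onset were
#: added up to ``critical_period`` days earlier.
DEFAULT_WINDOWS = {
    "developing": (0, 14),    # added during enrichment
    "critical": (-14, 0),     # in the critical period at onset
    "mature": (-10_000, -14),  # already mature at onset
}


def birthdate_composition(
    labels: np.ndarray,
    birthdates: np.ndarray,
    enrichment_onset: int,
    windows: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Count GCs per cluster label within birthdate windows.

    Windows are half-open intervals ``[lo, hi)`` of birthdate relative to
    enrichment onset.  Returns a tidy frame with counts and within-label
    fractions.
    """
    labels = np.asarray(labels)
    birthdates = np.asarray(birthdates)
    if labels.size == 0:
        raise ValueError("empty GC census")
    if labels.shape != birthdates.shape:
        raise ValueError("labels and birthdates must align")
    if windows is None:
        windows = DEFAULT_WINDOWS
    rel = birthdates - enrichment_onset
    rows = []
    for lab in np.unique(labels):
        in_lab = labels == lab
        n_lab = int(in_lab.sum())
        for name, (lo, hi) in windows.items():
            count = int(np.sum(in_lab & (rel >= lo) & (rel < hi)))
            rows.append({"label": lab, "window": name, "count": count,
                         "fraction": count / n_lab if n_lab else 0.0})
    return pd.DataFrame(rows)


def survival_fraction_by_birthdate(
    census: pd.DataFrame,
    evaluation_day: int,
    bin_width: int = 1,
    min_age: int = 0,
) -> pd.DataFrame:
    """Fraction of each birth cohort still alive at ``evaluation_day``.

    ``census`` is the event log with columns ``day``, ``event`` ("added" /
    "removed"), ``gc_id`` and ``birthdate``.  Cohorts are binned by
    birthdate; GCs younger than ``min_age`` at evaluation are excluded
    (e.g. ``min_age=14`` restricts to GCs already integrated).
    """
    required = {"day", "event", "gc_id", "birthdate"}
    if not required.issubset(census.columns):
        raise ValueError(f"census needs columns {sorted(required)}")
    added = census[census["event"] == "added"]
    removed = census[(census["event"] == "removed")
                     & (census["day"] <= evaluation_day)]
    dead = set(removed["gc_id"])
    rows = []
    eligible = added[added["birthdate"] <= evaluation_day - min_age]
    if eligible.empty:
        return pd.DataFrame(columns=["birthdate_bin", "n_born", "n_alive",
                                     "fraction"])
    bins = (eligible["birthdate"] // bin_width) * bin_width
    for b, group in eligible.groupby(bins):
        alive = (~group["gc_id"].isin(dead)).sum()
        rows.append({"birthdate_bin": int(b), "n_born": len(group),
                     "n_alive": int(alive),
                     "fraction": alive / len(group)})
    return pd.DataFrame(rows)


def overwrite_ratio(trace_with_subsequent: pd.Series,
                    trace_without: pd.Series) -> pd.Series:
    """Memory of an enrichment relative to its no-further-enrichment control.

    Both inputs are memory traces indexed by evaluation day; the result is
    their elementwise ratio, missing (NaN) wherever the reference is zero.
    """
    a = pd.Series(trace_with_subsequent, dtype=float)
    b = pd.Series(trace_without, dtype=float)
    if not a.index.equals(b.index):
        raise ValueError("traces must share their evaluation days")
    ratio = a / b.where(b != 0)
    return ratio
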