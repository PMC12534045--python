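"""Odor stimuli and presentation schedules for enrichment protocols.

Two stimulus families are provided.  Gaussian pairs are mixtures of two
broad Gaussian activity profiles over the (arbitrarily ordered) MC array;
the two pair members share the same components with swapped mixture
weights, making them similar but discriminable.  Sparse pairs are mixtures
of two non-overlapping binary components, each driving 10% of MCs, again
with swapped weights; a fresh pair of components is drawn per enrichment.

A schedule is a list of days; an enrichment day interleaves the two odors
with blank presentations (A, blank, B, blank, ...), and a non-enrichment
day contains the same total number of blank presentations, so every day
carries the same number of plasticity updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "OdorPair",
    "DaySchedule",
    "StimulusSchedule",
    "gaussian_odor_pair",
    "sparse_odor_pair",
    "build_schedule",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with .5 rounding up (so 22.5 -> 23)."""
    return int(np.floor(x + 0.5))


@dataclass
class OdorPair:
    """Two similar MC input vectors sharing mixture components."""

    a: np.ndarray
    b: np.ndarray
    kind: str = "gaussian"           # "gaussian" or "sparse"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("pair members must have equal length")
        if np.any(self.a < 0) or np.any(self.b < 0):
            raise ValueError("odor vectors must be non-negative")


@dataclass
class DaySchedule:
    """One simulated day: an ordered list of presentations.

    Each presentation is an odor vector or ``None`` for a blank.
    """

    presentations: list
    enriched: bool = False
    epoch: str = "blank"   # label, e.g. "enrichment-0"
    pair_id: int | None = None


@dataclass
class StimulusSchedule:
    """Ordered days with epoch labels and the odor pairs they reference."""

    days: list                       # list[DaySchedule]
    pairs: dict = field(default_factory=dict)  # pair_id -> OdorPair

    def __len__(self) -> int:
        return len(self.days)


def gaussian_odor_pair(
    params: ModelParams,
    rng: np.random.Generator | None = None,
    centers: tuple[float, float] | None = None,
    sigma: float | None = None,
    weights: tuple[float, float] = (0.6, 0.4),
    amplitude: float = 0.9,
) -> OdorPair:
    """Pair of two-component Gaussian mixtures over the MC index.

    Defaults place the component centers a third of the array apart with a
    width covering roughly a quarter of the MCs, and a peak drive of about
    ``amplitude``.  The second pair member swaps the mixture weights.
    """
    n = params.n_mc
    if centers is None:
        centers = (n / 3.0, 2.0 * n / 3.0)
    if sigma is None:
        sigma = n / 12.0
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    i = np.arange(n, dtype=float)
    profiles = np.stack([np.exp(-((i - mu) ** 2) / sigma**2) for mu in centers])
    w = np.asarray(weights, dtype=float)
    a = amplitude * (w @ profiles)
    b = amplitude * (w[::-1] @ profiles)
    return OdorPair(a, b, kind="gaussian",
                    meta={"centers": list(centers), "sigma": sigma,
                          "weights": list(weights), "amplitude": amplitude})


def sparse_odor_pair(
    params: ModelParams,
    rng: np.random.Generator,
    weights: tuple[float, float] = (0.6, 0.4),
    amplitude: float = 1.0,
    active_fraction: float = 0.1,
) -> OdorPair:
    """Pair of mixtures of two disjoint random binary components.

    Each component drives ``round(active_fraction * n_mc)`` MCs (half-up
    rounding), and the two components never overlap.  Pair members swap the
    mixture weights.
    """
    n = params.n_mc
    n_active = round_half_up(active_fraction * n)
    if 2 * n_active > n:
        raise ValueError("components would overlap: 2 * component size > n_mc")
    chosen = rng.choice(n, size=2 * n_active, replace=False)
    i1, i2 = np.sort(chosen[:n_active]), np.sort(chosen[n_active:])
    if np.intersect1d(i1, i2).size:  # pragma: no cover - disjoint by construction
        raise AssertionError("sparse components overlap")
    ind1 = np.zeros(n)
    ind2 = np.zeros(n)
    ind1[i1] = 1.0
    ind2[i2] = 1.0
    w = np.asarray(weights, dtype=float)
    a = amplitude * (w[0] * ind1 + w[1] * ind2)
    b = amplitude * (w[1] * ind1 + w[0] * ind2)
    return OdorPair(a, b, kind="sparse",
                    meta={"i1": i1.tolist(), "i2": i2.tolist(),
                          "weights": list(w), "amplitude": amplitude})


def _enrichment_day(pair: OdorPair, params: ModelParams, epoch: str,
                    pair_id: int) -> DaySchedule:
    pres: list = []
    for k in range(params.presentations_per_day):
        pres.append(pair.a if k % 2 == 0 else pair.b)
        pres.append(None)
    return DaySchedule(pres, enriched=True, epoch=epoch, pair_id=pair_id)


def _blank_day(params: ModelParams, epoch: str = "blank") -> DaySchedule:
    return DaySchedule([None] * (2 * params.presentations_per_day),
                       enriched=False, epoch=epoch)


def build_schedule(
    epochs: list[dict],
    params: ModelParams,
    rng: np.random.Generator,
) -> StimulusSchedule:
    """Expand an epoch list into a day-by-day presentation schedule.

    Each epoch is a mapping with ``type`` ("blank" or "enrichment") and
    ``days``; enrichment epochs take either an explicit ``pair``
    (:class:`OdorPair`) or a ``stimulus`` family ("gaussian" or "sparse")
    from which a fresh pair is drawn.  Deterministic given the RNG state.
    """
    days: list[DaySchedule] = []
    pairs: dict[int, OdorPair] = {}
    enrichment_count = 0
    for epoch in epochs:
        kind = epoch.get("type")
        n_days = int(epoch.get("days", 0))
        if n_days < 0:
            raise ValueError("epoch duration must be non-negative")
        if kind == "blank":
            days.extend(_blank_day(params) for _ in range(n_days))
        elif kind == "enrichment":
            pair = epoch.get("pair")
            if pair is None:
                family = epoch.get("stimulus", "gaussian")
                if family == "gaussian":
                    pair = gaussian_odor_pair(params, rng)
                elif family == "sparse":
                    pair = sparse_odor_pair(params, rng)
                else:
                    raise ValueError(f"unknown stimulus family {family!r}")
            pair_id = epoch.get("pair_id", enrichment_count)
            label = epoch.get("label", f"enrichment-{pair_id}")
            pairs[pair_id] = pair
            days.extend(_enrichment_day(pair, params, label, pair_id)
                        for _ in range(n_days))
            enrichment_count += 1
        else:
            raise ValueError(f"unknown epoch type {kind!r}")
    return StimulusSchedule(days=days, pairs=pairs)
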