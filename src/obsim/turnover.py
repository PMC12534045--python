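"""Adult neurogenesis, GC maturation, and activity-dependent apoptosis.

Granule cells are added daily.  A newborn GC's dendritic field (the set of
``n_conn`` MCs it can ever synapse with) is chosen by ranking

    Mtilde_i = [Mbar_i - theta_M]_+ + eps_i,   eps_i ~ U(0, eps_max)

where ``Mbar`` is the mean MC activity over the preceding days, so fields
are biased toward MCs that were active while the cell's dendrites were
developing.  The field is immutable afterwards.  Age-dependent parameters
(plasticity ``p``, excitability ``r``, survival threshold ``G0``) are step
functions of GC age around the critical period, and GCs die stochastically
with probability ``(1 - tanh(5 (G - G0))) / 2`` once per day, where ``G``
is the cell's mean activity that day.  During enrichment a removal signal
raises the survival threshold of young GCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CONSOLIDATED, NONEXISTENT, NetworkState, SynapseMatrix
from .params import ModelParams

__all__ = [
    "GcCensusEvent",
    "resolve_age_parameters",
    "dendritic_field_for_newcomer",
    "add_granule_cells",
    "apoptosis_probability",
    "apoptosis_step",
]


@dataclass(frozen=True)
class GcCensusEvent:
    """One addition or removal in the GC census log."""

    day: int
    event: str      # "added" or "removed"
    gc_id: int
    birthdate: int


def resolve_age_parameters(
    birthdates: np.ndarray,
    current_day: int,
    enriched: bool,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-GC (plasticity, excitability, survival threshold) from age.

    A GC is in its critical period while its age (days since insertion) is
    below ``critical_period``.  Ablation flags replace the step functions:
    ``plasticity_mode`` "fast"/"slow" force a uniform rate, ``freeze_mature``
    zeroes plasticity of mature GCs, and ``age_excitability=False`` gives
    every GC the mature excitability.  The enrichment removal signal (when
    enabled) raises the survival threshold of young GCs on enriched days.
    """
    birthdates = np.asarray(birthdates)
    if np.any(birthdates > current_day):
        raise ValueError("birthdates cannot lie in the future")
    age = current_day - birthdates
    young = age < params.critical_period

    if params.plasticity_mode == "age":
        p = np.where(young, params.p_young, params.p_mature)
    elif params.plasticity_mode == "fast":
        p = np.full(birthdates.shape, params.p_young)
    elif params.plasticity_mode == "slow":
        p = np.full(birthdates.shape, params.p_mature)
    else:  # pragma: no cover - rejected by ModelParams.validate
        raise ValueError(f"unknown plasticity mode {params.plasticity_mode!r}")
    if params.freeze_mature:
        p = np.where(young, p, 0.0)

    if params.age_excitability:
        r = np.where(young, params.r_young, params.r_mature)
    else:
        r = np.full(birthdates.shape, params.r_mature)

    g0_young = (params.g0_young_enriched
                if (enriched and params.removal_signal)
                else params.g0_young_unenriched)
    g0 = np.where(young, g0_young, params.g0_mature)
    return p.astype(float), r.astype(float), g0.astype(float)


def dendritic_field_for_newcomer(
    mc_history_mean: np.ndarray,
    rng: np.random.Generator,
    params: ModelParams,
) -> np.ndarray:
    """Indices of the ``n_conn`` MCs forming a newborn GC's dendritic field.

    With dendritic elaboration disabled the activity term is dropped and the
    field is a uniformly random subset.  Exact ties in the ranking score are
    broken uniformly at random.
    """
    mbar = np.asarray(mc_history_mean, dtype=float)
    if params.n_conn > mbar.size:
        raise ValueError("n_conn cannot exceed the number of MCs")
    score = rng.uniform(0.0, params.eps_max, size=mbar.size)
    if params.dendritic_elaboration:
        score = score + np.maximum(mbar - params.theta_m, 0.0)
    tiebreak = rng.permutation(mbar.size)
    order = np.lexsort((tiebreak, -score))
    return np.sort(order[: params.n_conn])


def _new_columns(state: NetworkState, params: ModelParams, n_new: int,
                 rng: np.random.Generator, n_mc: int):
    mask = np.zeros((n_mc, n_new), dtype=bool)
    syn = np.full((n_mc, n_new), NONEXISTENT, dtype=np.int8)
    mbar = state.history_mean()
    for j in range(n_new):
        field = dendritic_field_for_newcomer(mbar, rng, params)
        mask[field, j] = True
        initial = rng.choice(field, size=params.n_init, replace=False)
        syn[initial, j] = CONSOLIDATED
    return mask, syn


def add_granule_cells(
    state: NetworkState,
    synapses: SynapseMatrix,
    rng: np.random.Generator,
    params: ModelParams,
    n_new: int | None = None,
) -> list[GcCensusEvent]:
    """Insert newborn GCs (default ``n_add``) with fresh dendritic fields.

    Each newcomer starts with ``n_init`` consolidated synapses at uniformly
    random positions within its field; the remaining field sites are
    nonexistent.  Returns the census events; no-ops when neurogenesis is
    disabled.
    """
    if not params.neurogenesis:
        return []
    if n_new is None:
        n_new = params.n_add
    if n_new == 0:
        return []
    mask, syn = _new_columns(state, params, n_new, rng, synapses.n_mc)
    synapses.append_columns(mask, syn)
    ids = np.arange(state.next_gc_id, state.next_gc_id + n_new, dtype=np.int64)
    state.next_gc_id += n_new
    state.gc_id = np.concatenate([state.gc_id, ids])
    state.gc_birthdate = np.concatenate(
        [state.gc_birthdate, np.full(n_new, state.day, dtype=np.int64)])
    state.gc_rates = np.concatenate([state.gc_rates, np.zeros(n_new)])
    return [GcCensusEvent(state.day, "added", int(i), state.day) for i in ids]


def apoptosis_probability(gc_activity, survival_threshold,
                          gain: float = 5.0) -> np.ndarray:
    """Daily removal probability: a falling sigmoid of GC activity.

    Equals 1/2 when activity sits exactly at the survival threshold and
    decreases strictly with activity.
    """
    g = np.asarray(gc_activity, dtype=float)
    g0 = np.asarray(survival_threshold, dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(g0))):
        raise ValueError("non-finite apoptosis inputs")
    return 0.5 * (1.0 - np.tanh(gain * (g - g0)))


def apoptosis_step(
    state: NetworkState,
    synapses: SynapseMatrix,
    gc_daily_activity: np.ndarray,
    enriched: bool,
    rng: np.random.Generator,
    params: ModelParams,
) -> list[GcCensusEvent]:
    """Stochastically remove GCs given their mean activity over the day.

    Survival thresholds are resolved from age and the enrichment flag;
    removals are sampled independently and the corresponding columns deleted
    from the state and synapse matrices.  No-ops when apoptosis is disabled.
    """
    if not params.apoptosis:
        return []
    activity = np.asarray(gc_daily_activity, dtype=float)
    if activity.shape != (state.n_gc,):
        raise ValueError("daily activity length must equal the GC count")
    _, _, g0 = resolve_age_parameters(state.gc_birthdate, state.day, enriched,
                                      params)
    prob = apoptosis_probability(activity, g0, gain=params.apoptosis_gain)
    doomed = np.flatnonzero(rng.random(state.n_gc) < prob)
    if doomed.size == 0:
        return []
    events = [
        GcCensusEvent(state.day, "removed", int(state.gc_id[i]),
                      int(state.gc_birthdate[i]))
        for i in doomed
    ]
    synapses.delete_columns(doomed)
    keep = np.ones(state.n_gc, dtype=bool)
    keep[doomed] = False
    state.gc_id = state.gc_id[keep]
    state.gc_birthdate = state.gc_birthdate[keep]
    state.gc_rates = state.gc_rates[keep]
    return events
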