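"""Calcium-gated structural plasticity of the reciprocal MC-GC synapses.

Each potential synapse follows a three-state Markov chain
(nonexistent <-> unconsolidated <-> consolidated).  Unconsolidated spines
form and retract at constant rates ``alpha``/``beta``; consolidation and
deconsolidation rates depend on a local calcium proxy

    [Ca]_ij = C_pre * r_j * M_i + C_post * G_j

(the steady state of a first-order calcium relaxation driven by pre- and
postsynaptic firing).  The consolidation rate is a sigmoid of calcium above
a threshold; the deconsolidation rate peaks exactly at its threshold:

    R+_ij = R0 + (tanh(g([Ca]_ij - theta+_j)) + 1) / 2
    R-_ij = R0 + d / cosh(g([Ca]_ij - theta-_j))

The per-GC thresholds slide with the mean calcium over the GC's dendritic
field (intracellular competition between synapses):

    theta+-_j = max(theta+-, k * mean_field([Ca]_j))

All four rates are scaled by the GC's age-dependent plasticity rate ``p_j``
and mapped to per-presentation transition probabilities P = 1 - exp(-p*R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (CONSOLIDATED, NONEXISTENT, UNCONSOLIDATED, SynapseMatrix)
from .params import ModelParams

__all__ = [
    "CalciumField",
    "calcium_steady_state",
    "sliding_thresholds",
    "consolidation_rate",
    "deconsolidation_rate",
    "rate_to_probability",
    "plasticity_step",
]


@dataclass
class CalciumField:
    """Calcium proxy at every potential synapse plus per-GC field means.

    ``ca[i, j]`` is meaningful on the dendritic-field mask only; off-mask
    entries are computed from the same formula but never used.
    """

    ca: np.ndarray        # (n_mc, n_gc)
    mean_per_gc: np.ndarray  # (n_gc,) mean over each GC's full dendritic field


def calcium_steady_state(
    mc_rates: np.ndarray,
    gc_rates: np.ndarray,
    excitability: np.ndarray,
    params: ModelParams,
    field_mask: np.ndarray,
) -> CalciumField:
    """Steady-state calcium at every potential synapse.

    Presentations are treated as long compared with the calcium time
    constant, so each presentation uses the relaxed value
    ``C_pre * r_j * M_i + C_post * G_j``.  The per-GC mean is taken over the
    GC's full dendritic field (all potential sites), so it does not jump
    when individual synapses appear or disappear.
    """
    m = np.asarray(mc_rates, dtype=float)
    g = np.asarray(gc_rates, dtype=float)
    r = np.asarray(excitability, dtype=float)
    mask = np.asarray(field_mask, dtype=bool)
    if mask.shape != (m.size, g.size) or r.shape != g.shape:
        raise ValueError("shape mismatch between rates, excitability and mask")
    if np.any(m < 0) or np.any(g < 0):
        raise ValueError("firing rates must be non-negative")
    ca = params.c_pre * np.outer(m, r) + params.c_post * g[np.newaxis, :]
    field_sizes = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(field_sizes > 0,
                        (ca * mask).sum(axis=0) / np.maximum(field_sizes, 1),
                        0.0)
    return CalciumField(ca=ca, mean_per_gc=mean)


def sliding_thresholds(
    ca_mean_per_gc: np.ndarray, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-GC consolidation/deconsolidation thresholds.

    Each threshold is the larger of its global floor and ``k`` times the
    GC's mean field calcium.
    """
    ca_mean = np.asarray(ca_mean_per_gc, dtype=float)
    if np.any(ca_mean < 0):
        raise ValueError("mean calcium must be non-negative")
    scaled = params.k * ca_mean
    return (np.maximum(params.theta_plus, scaled),
            np.maximum(params.theta_minus, scaled))


def consolidation_rate(ca: np.ndarray, theta_plus_j: np.ndarray,
                       params: ModelParams) -> np.ndarray:
    """Sigmoidal consolidation rate, in [R0, R0 + 1]."""
    return params.r0 + 0.5 * (np.tanh(params.g * (ca - theta_plus_j)) + 1.0)


def deconsolidation_rate(ca: np.ndarray, theta_minus_j: np.ndarray,
                         params: ModelParams) -> np.ndarray:
    """Bump-shaped deconsolidation rate, peaking at R0 + d on the threshold."""
    return params.r0 + params.d / np.cosh(params.g * (ca - theta_minus_j))


def rate_to_probability(rate, plasticity_scale) -> np.ndarray:
    """Map a non-negative transition rate to a probability 1 - exp(-p*rate)."""
    rate = np.asarray(rate, dtype=float)
    p = np.asarray(plasticity_scale, dtype=float)
    if np.any(rate < 0):
        raise ValueError("transition rates must be non-negative")
    if np.any(p < 0):
        raise ValueError("plasticity scale must be non-negative")
    return -np.expm1(-p * rate)


def plasticity_step(
    synapses: SynapseMatrix,
    calcium: CalciumField,
    plasticity: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> SynapseMatrix:
    """One stochastic update of every potential synapse (in place).

    All transition probabilities are computed from the pre-step state and
    sampled simultaneously, so the update is order-independent; each synapse
    changes state at most once per step.  From the unconsolidated state the
    two exits (removal with probability from ``beta``, consolidation with
    probability from ``R+``) are sampled from a single uniform draw over
    disjoint intervals.
    """
    state = synapses.state
    if not np.isin(state, (NONEXISTENT, UNCONSOLIDATED, CONSOLIDATED)).all():
        raise ValueError("synapse states must be in {0, 1, 2}")
    mask = synapses.field_mask
    p_j = np.asarray(plasticity, dtype=float)
    if p_j.shape != (synapses.n_gc,):
        raise ValueError("plasticity vector length must equal the GC count")

    theta_plus_j, theta_minus_j = sliding_thresholds(calcium.mean_per_gc, params)
    r_plus = consolidation_rate(calcium.ca, theta_plus_j[np.newaxis, :], params)
    r_minus = deconsolidation_rate(calcium.ca, theta_minus_j[np.newaxis, :], params)

    p_row = p_j[np.newaxis, :]
    p_alpha = rate_to_probability(params.alpha, p_j)[np.newaxis, :]
    p_beta = rate_to_probability(params.beta, p_j)[np.newaxis, :]
    p_plus = rate_to_probability(r_plus, p_row)
    p_minus = rate_to_probability(r_minus, p_row)

    u = rng.random(state.shape)
    new_state = state.copy()

    grow = mask & (state == NONEXISTENT) & (u < p_alpha)
    new_state[grow] = UNCONSOLIDATED

    # unconsolidated: single draw partitioned into removal then consolidation
    exit_u = p_beta + p_plus
    # the two exit probabilities cannot sum above one for sane parameters;
    # guard against pathological settings by renormalizing the partition
    scale = np.where(exit_u > 1.0, 1.0 / np.maximum(exit_u, 1e-300), 1.0)
    uncons = mask & (state == UNCONSOLIDATED)
    retract = uncons & (u < p_beta * scale)
    consolidate = uncons & ~retract & (u < exit_u * scale)
    new_state[retract] = NONEXISTENT
    new_state[consolidate] = CONSOLIDATED

    decons = mask & (state == CONSOLIDATED) & (u < p_minus)
    new_state[decons] = UNCONSOLIDATED

    synapses.state = new_state
    return synapses
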