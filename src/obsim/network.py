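"""Network state and steady-state firing rates of the MC-GC circuit.

The circuit has two layers: excitatory mitral cells (MCs) receiving sensory
input, and inhibitory granule cells (GCs) coupled to MCs through fully
reciprocal synapses.  With ``w`` the binary matrix of consolidated synapses,
``r_j`` the per-GC excitability and ``S_i`` the input drive, the firing
rates at steady state satisfy

    M_i = [ S_i - gamma * sum_j w_ij G_j ]_+
    G_j = r_j * sum_i w_ij M_i

where ``[x]_+`` is the threshold-linear rectifier.  Only these fixed points
matter for plasticity and for the memory measure, so they are computed
directly (an active-set linear solve with a damped-iteration fallback)
rather than by integrating the rate equations in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "SynapseMatrix",
    "NetworkState",
    "compose_input",
    "steady_state_response",
    "SteadyStateError",
    "NONEXISTENT",
    "UNCONSOLIDATED",
    "CONSOLIDATED",
]

# Synapse states of the three-state structural-plasticity Markov chain.
NONEXISTENT = 0     # geometrically possible site, no spine
UNCONSOLIDATED = 1  # silent spine / filopodium, weight 0
CONSOLIDATED = 2    # functional reciprocal synapse, weight 1


class SteadyStateError(RuntimeError):
    """Raised when the fixed-point solver fails to converge."""


@dataclass
class SynapseMatrix:
    """Potential and realized synapses between every (MC, GC) pair.

    ``field_mask[i, j]`` is True where GC ``j``'s dendritic field reaches
    MC ``i`` (exactly ``n_conn`` True entries per column); ``state[i, j]``
    holds the Markov state and may be nonzero only on the mask.  The
    reciprocal weight is 1 iff the synapse is consolidated; a single matrix
    serves both the MC->GC and GC->MC directions.
    """

    field_mask: np.ndarray  # bool, (n_mc, n_gc)
    state: np.ndarray       # int8, (n_mc, n_gc)

    def __post_init__(self) -> None:
        self.field_mask = np.asarray(self.field_mask, dtype=bool)
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.field_mask.shape != self.state.shape:
            raise ValueError("field_mask and state shapes differ")

    @property
    def n_mc(self) -> int:
        return self.field_mask.shape[0]

    @property
    def n_gc(self) -> int:
        return self.field_mask.shape[1]

    @property
    def weights(self) -> np.ndarray:
        """Binary weight matrix (float64): 1 where consolidated."""
        return (self.state == CONSOLIDATED).astype(np.float64)

    def degrees(self) -> np.ndarray:
        """Number of consolidated synapses of each GC."""
        return np.count_nonzero(self.state == CONSOLIDATED, axis=0)

    def validate(self, n_conn: int | None = None) -> None:
        if not np.isin(self.state, (NONEXISTENT, UNCONSOLIDATED, CONSOLIDATED)).all():
            raise ValueError("synapse states must be in {0, 1, 2}")
        if np.any((self.state != NONEXISTENT) & ~self.field_mask):
            raise ValueError("synapse exists outside its GC's dendritic field")
        if n_conn is not None:
            per_gc = self.field_mask.sum(axis=0)
            if self.n_gc and not np.all(per_gc == n_conn):
                raise ValueError("every GC field must contain exactly n_conn MCs")

    def append_columns(self, field_mask: np.ndarray, state: np.ndarray) -> None:
        """Add newly born GCs (columns)."""
        self.field_mask = np.concatenate([self.field_mask, field_mask], axis=1)
        self.state = np.concatenate([self.state, state], axis=1)

    def delete_columns(self, idx: np.ndarray) -> None:
        """Remove GCs (columns) by index."""
        keep = np.ones(self.n_gc, dtype=bool)
        keep[idx] = False
        self.field_mask = self.field_mask[:, keep]
        self.state = self.state[:, keep]

    def copy(self) -> "SynapseMatrix":
        return SynapseMatrix(self.field_mask.copy(), self.state.copy())


@dataclass
class NetworkState:
    """Mutable per-day bookkeeping for one simulated network.

    Keeps the most recent steady-state rates, the per-GC birthdates used to
    resolve age-dependent parameters, and a rolling history of per-day mean
    MC rates that biases the dendritic fields of newborn GCs.
    """

    mc_rates: np.ndarray                  # last computed MC steady state
    gc_rates: np.ndarray                  # last computed GC steady state
    gc_birthdate: np.ndarray              # insertion day of each GC
    gc_id: np.ndarray                     # stable identifier of each GC
    day: int = 0
    next_gc_id: int = 0
    mc_activity_history: list = field(default_factory=list)  # per-day mean MC rate vectors

    @classmethod
    def initial(cls, params: ModelParams) -> "NetworkState":
        """Fresh state with ``n_gc_init`` newborn GCs.

        The initial cohort is inserted at day 0 and matures through the same
        critical-period trajectory as every later cohort, so the network
        prunes and settles into its self-organized operating point during
        the growth epoch instead of starting from a frozen mature census.
        """
        n = params.n_gc_init
        return cls(
            mc_rates=np.zeros(params.n_mc),
            gc_rates=np.zeros(n),
            gc_birthdate=np.zeros(n, dtype=np.int64),
            gc_id=np.arange(n, dtype=np.int64),
            day=0,
            next_gc_id=n,
        )

    @property
    def n_gc(self) -> int:
        return self.gc_birthdate.size

    def ages(self) -> np.ndarray:
        return self.day - self.gc_birthdate

    def record_day_activity(self, mean_mc_rates: np.ndarray,
                            window: int) -> None:
        """Append one day's mean MC rates, keeping at most ``window`` days."""
        if window < 6:
            raise ValueError("activity history window must be >= 6 days")
        self.mc_activity_history.append(np.asarray(mean_mc_rates, dtype=float))
        del self.mc_activity_history[:-window]

    def history_mean(self) -> np.ndarray:
        """Mean MC activity over the stored trailing window (zeros if empty)."""
        if not self.mc_activity_history:
            return np.zeros(self.mc_rates.shape[0])
        return np.mean(self.mc_activity_history, axis=0)


def compose_input(params: ModelParams, odor: np.ndarray | None = None) -> np.ndarray:
    """Total MC drive: spontaneous baseline plus an optional odor pattern.

    Blank presentations (``odor=None`` or an all-zero vector) leave every MC
    with the spontaneous drive only.
    """
    s = np.full(params.n_mc, params.s_spont, dtype=float)
    if odor is not None:
        odor = np.asarray(odor, dtype=float)
        if odor.shape != (params.n_mc,):
            raise ValueError(f"odor must have shape ({params.n_mc},), got {odor.shape}")
        if not np.all(np.isfinite(odor)):
            raise ValueError("odor contains non-finite entries")
        if np.any(odor < 0):
            raise ValueError("odor entries must be non-negative")
        s += odor
    return s


def _damped_iteration(kernel: np.ndarray, s: np.ndarray, tol: float,
                      max_iter: int, relax: float = 0.3) -> np.ndarray:
    m = np.maximum(s, 0.0)
    for _ in range(max_iter):
        target = np.maximum(s - kernel @ m, 0.0)
        resid = np.max(np.abs(target - m)) if m.size else 0.0
        if resid <= tol:
            return target
        m = (1.0 - relax) * m + relax * target
    raise SteadyStateError(
        f"damped fixed-point iteration did not converge: residual {resid:.3e} "
        f"after {max_iter} iterations (tol {tol:.1e})")


def steady_state_response(
    params: ModelParams,
    synapses: SynapseMatrix | np.ndarray,
    excitability: np.ndarray,
    stimulus: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed point of the rectified-linear MC/GC rate equations.

    Parameters
    ----------
    synapses
        Either a :class:`SynapseMatrix` or a binary weight matrix
        ``(n_mc, n_gc)``.
    excitability
        Per-GC excitability ``r_j``.
    stimulus
        Total MC input ``S`` (see :func:`compose_input`).

    Returns
    -------
    (mc_rates, gc_rates)
        ``M`` solves ``M = [S - gamma * W diag(r) W^T M]_+`` and
        ``G = r * (W^T M)``.

    Notes
    -----
    Eliminating ``G`` gives a rectified linear complementarity problem in
    ``M``.  It is solved by active-set iteration: solve the linear system on
    the tentatively active MCs, clamp MCs driven negative, readmit clamped
    MCs whose net input turned positive, and repeat.  If the active set
    cycles, a damped fixed-point iteration is used as fallback.
    """
    w = synapses.weights if isinstance(synapses, SynapseMatrix) else np.asarray(
        synapses, dtype=float)
    s = np.asarray(stimulus, dtype=float)
    r = np.asarray(excitability, dtype=float)
    if s.shape != (w.shape[0],):
        raise ValueError("stimulus length must equal the number of MCs")
    if r.shape != (w.shape[1],):
        raise ValueError("excitability length must equal the number of GCs")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite stimulus or excitability")

    n_mc = w.shape[0]
    if w.shape[1] == 0 or not w.any():
        m = np.maximum(s, 0.0)
        return m, r * (w.T @ m)

    # gamma * W diag(r) W^T, the effective MC->MC inhibition kernel
    kernel = params.gamma * ((w * r) @ w.T)

    active = s > 0
    seen: set[bytes] = set()
    m = None
    for _ in range(2 * n_mc + 10):
        key = active.tobytes()
        if key in seen:
            m = None
            break  # active set cycled; fall back to damped iteration
        seen.add(key)
        m = np.zeros(n_mc)
        idx = np.flatnonzero(active)
        if idx.size:
            a = kernel[np.ix_(idx, idx)] + np.eye(idx.size)
            m[idx] = np.linalg.solve(a, s[idx])
        net = s - kernel @ m
        negative = active & (m < -params.solver_tol)
        reactivate = ~active & (net > params.solver_tol)
        if not negative.any() and not reactivate.any():
            m = np.maximum(m, 0.0)
            break
        active = active & ~negative | reactivate
        m = None
    if m is None:
        m = _damped_iteration(kernel, s, params.solver_tol,
                              params.solver_max_iter)

    resid = np.max(np.abs(np.maximum(s - kernel @ m, 0.0) - m))
    if resid > max(params.solver_tol, 1e-8):
        raise SteadyStateError(f"fixed point residual {resid:.3e} exceeds tolerance")
    g = r * (w.T @ m)
    return m, g
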