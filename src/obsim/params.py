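"""Model parameters for the olfactory-bulb neurogenesis simulator.

All scalar parameters of the mitral-cell (MC) / granule-cell (GC) network
live in a single flat :class:`ModelParams` dataclass so that a run is fully
specified by one mapping that round-trips through YAML/JSON.  Defaults are
the values used for the standard simulations; ablation studies flip the
boolean flags rather than editing rates by hand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

__all__ = ["ModelParams", "PLASTICITY_MODES"]

#: Allowed settings for the plasticity ablation.  ``"age"`` is the full
#: model (fast during the critical period, slow afterwards); ``"fast"`` and
#: ``"slow"`` force the corresponding rate on every GC regardless of age.
PLASTICITY_MODES = ("age", "fast", "slow")


@dataclass
class ModelParams:
    """All tunable parameters of the model.

    Units: firing rates and calcium are dimensionless model units; one
    simulated "day" is one neurogenesis/apoptosis time step containing
    several stimulus presentations.
    """

    # -- network architecture -------------------------------------------------
    n_mc: int = 225          # number of mitral cells
    n_gc_init: int = 900     # initial number of granule cells
    n_add: int = 8           # GCs added per day by adult neurogenesis
    n_conn: int = 30         # size of each GC's dendritic field (potential synapses)
    n_init: int = 10         # consolidated synapses a newborn GC starts with

    # -- rate dynamics --------------------------------------------------------
    gamma: float = 0.004     # inhibitory strength of GC->MC synapses
    s_spont: float = 0.1     # spontaneous sensory drive to every MC
    # Membrane time constants of the rate equations.  Only the fixed points of
    # the rate dynamics enter plasticity and the memory measure, so these are
    # retained for documentation but never used by the fixed-point solver.
    tau_m: float = 1.0
    tau_g: float = 1.0

    # -- structural plasticity ------------------------------------------------
    alpha: float = 1.5       # unconsolidated-spine formation rate (activity-independent)
    beta: float = 1.5        # unconsolidated-spine removal rate
    r0: float = 0.01         # spontaneous consolidation/deconsolidation rate
    g: float = 13.0          # gain of the calcium-dependent rate functions
    d: float = 0.7           # deconsolidation/consolidation rate ratio, in (0, 1]
    c_pre: float = 3.6       # presynaptic calcium-influx coefficient
    c_post: float = 1.1      # postsynaptic calcium-influx coefficient
    tau_ca: float = 3.33     # calcium time constant (presentations are long vs this)
    k: float = 0.95          # sliding-threshold scalar
    theta_plus: float = 1.05  # minimal consolidation threshold
    theta_minus: float = 1.0  # minimal deconsolidation threshold

    # -- dendritic elaboration of newborn GCs ---------------------------------
    theta_m: float = 0.15    # MC activity threshold to bias dendritic growth
    eps_max: float = 1.3     # upper bound of the uniform dendritic noise
    history_window: int = 6  # days of MC activity that bias a newcomer's field

    # -- age profile (step functions of GC age in days) -----------------------
    critical_period: int = 14    # days after insertion during which a GC is young
    p_young: float = 0.2         # plasticity rate, critical period
    p_mature: float = 0.02       # plasticity rate, mature
    r_young: float = 1.5         # excitability, critical period
    r_mature: float = 1.0        # excitability, mature
    g0_young_enriched: float = 0.5    # survival threshold, young GC, enrichment day
    g0_young_unenriched: float = 0.0  # survival threshold, young GC, blank day
    g0_mature: float = -0.45          # survival threshold, mature GC

    # -- apoptosis ------------------------------------------------------------
    apoptosis_gain: float = 5.0  # slope of the survival sigmoid

    # -- solver ---------------------------------------------------------------
    solver_tol: float = 1e-9
    solver_max_iter: int = 10_000

    # -- protocol -------------------------------------------------------------
    presentations_per_day: int = 6  # odor presentations per enrichment day

    # -- memory / clustering analysis ----------------------------------------
    n_shuffles: int = 10_000        # connectivity reshuffles for null distributions
    null_method: str = "analytic"   # "analytic" (exact shuffle moments) or "mc"

    # -- ablation flags -------------------------------------------------------
    neurogenesis: bool = True
    apoptosis: bool = True
    age_excitability: bool = True
    plasticity_mode: str = "age"
    dendritic_elaboration: bool = True
    freeze_mature: bool = False      # p = 0 for mature GCs (frozen connectivity)
    removal_signal: bool = True      # enrichment raises young-GC survival threshold
    double_neurogenesis_during_enrichment: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------------
    def validate(self) -> None:
        pos_ints = ("n_mc", "n_gc_init", "n_conn", "n_init", "critical_period",
                    "history_window", "presentations_per_day", "solver_max_iter")
        for name in pos_ints:
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("n_add", "n_shuffles"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        pos_floats = ("gamma", "alpha", "beta", "r0", "g", "c_pre", "c_post",
                      "tau_ca", "k", "theta_plus", "theta_minus", "eps_max",
                      "solver_tol", "p_young", "r_young", "r_mature",
                      "apoptosis_gain")
        for name in pos_floats:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if not self.p_mature >= 0:
            raise ValueError(f"p_mature must be >= 0, got {self.p_mature!r}")
        if not 0 < self.d <= 1:
            raise ValueError(f"d must be in (0, 1], got {self.d!r}")
        if not self.s_spont >= 0:
            raise ValueError(f"s_spont must be >= 0, got {self.s_spont!r}")
        if not self.theta_m >= 0:
            raise ValueError(f"theta_m must be >= 0, got {self.theta_m!r}")
        if not (self.n_init <= self.n_conn <= self.n_mc):
            raise ValueError(
                f"need n_init <= n_conn <= n_mc, got "
                f"{self.n_init} <= {self.n_conn} <= {self.n_mc}")
        if self.plasticity_mode not in PLASTICITY_MODES:
            raise ValueError(
                f"plasticity_mode must be one of {PLASTICITY_MODES}, "
                f"got {self.plasticity_mode!r}")
        if self.null_method not in ("analytic", "mc"):
            raise ValueError(f"null_method must be 'analytic' or 'mc', "
                             f"got {self.null_method!r}")
        flags = ("neurogenesis", "apoptosis", "age_excitability",
                 "dendritic_elaboration", "freeze_mature", "removal_signal",
                 "double_neurogenesis_during_enrichment")
        for name in flags:
            if not isinstance(getattr(self, name), bool):
                raise ValueError(f"{name} must be boolean")

    # -- (de)serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParams":
        """Build from a flat mapping; unknown keys are an error."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(
                f"unknown parameter(s): {sorted(unknown)}; known parameters "
                f"are {sorted(known)}")
        return cls(**mapping)

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed (validated)."""
        unknown = set(changes) - {f.name for f in fields(self)}
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)
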