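"""Daily simulation loop and the enrichment protocols.

A simulated day consists of several stimulus presentations; each
presentation computes steady-state MC/GC rates, the calcium field, and one
stochastic plasticity update.  At the end of each day the memory of every
tracked odor pair is evaluated, apoptosis removes under-active GCs, and
neurogenesis adds newborn GCs.  Protocols assemble days into growth,
enrichment and post epochs:

* ``perceptual_learning`` - growth, one enrichment, spontaneous decay;
* ``delayed_enrichment`` - the same with a variable growth duration;
* ``reenrichment`` - enrichment, decay until the memory clears, then a
  second enrichment with the same pair (optionally without neurogenesis);
* ``interference`` - two enrichments with different pairs and a gap;
* ``sequential_enrichment`` - many pairs presented one after another.

Randomness is split into independent child streams (stimuli, network
initialization, plasticity, neurogenesis, apoptosis, shuffles) so ablation
variants run on paired noise.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from . import metrics
from .network import NetworkState, SynapseMatrix, compose_input, steady_state_response
from .params import ModelParams
from .plasticity import calcium_steady_state, plasticity_step
from .stimuli import DaySchedule, OdorPair, StimulusSchedule, _blank_day, \
    _enrichment_day, gaussian_odor_pair, sparse_odor_pair
from .turnover import add_granule_cells, apoptosis_step, resolve_age_parameters

__all__ = [
    "ProtocolSpec",
    "ExperimentResult",
    "Simulation",
    "run_protocol",
    "sweep",
    "PROTOCOL_NAMES",
]

PROTOCOL_NAMES = (
    "perceptual_learning",
    "delayed_enrichment",
    "reenrichment",
    "interference",
    "sequential_enrichment",
)


@dataclass
class ProtocolSpec:
    """A named protocol plus its knobs (durations, stimulus family, ...)."""

    name: str
    options: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in PROTOCOL_NAMES:
            raise ValueError(
                f"unknown protocol {self.name!r}; choose from {PROTOCOL_NAMES}")
        for key, value in self.options.items():
            if key.endswith("_days") and value is not None and value < 0:
                raise ValueError(f"{key} must be non-negative")


@dataclass
class ExperimentResult:
    """Everything a protocol run produces."""

    trace: pd.DataFrame          # day, pair_id, memory, n_gc, mode
    census: pd.DataFrame         # day, event, gc_id, birthdate
    params: ModelParams
    seed: int
    protocol: ProtocolSpec | None = None
    pairs: dict = dataclass_field(default_factory=dict)
    extras: dict = dataclass_field(default_factory=dict)
    state: NetworkState | None = None
    synapses: SynapseMatrix | None = None
    runtime_s: float = 0.0


class Simulation:
    """Owns the network state and advances it day by day."""

    def __init__(self, params: ModelParams, seed: int,
                 memory_response_mode: str = "current"):
        if memory_response_mode not in ("current", "naive"):
            raise ValueError("memory_response_mode must be 'current' or 'naive'")
        self.params = params
        self.seed = int(seed)
        self.memory_response_mode = memory_response_mode
        ss = np.random.SeedSequence(self.seed)
        (self.rng_stimuli, self.rng_init, self.rng_plasticity,
         self.rng_neurogenesis, self.rng_apoptosis,
         self.rng_shuffles) = (np.random.default_rng(s) for s in ss.spawn(6))
        self.state = NetworkState.initial(params)
        self.synapses = self._initial_synapses()
        from .turnover import GcCensusEvent
        self.census_events: list = [
            GcCensusEvent(0, "added", int(i), 0) for i in self.state.gc_id]
        self.trace_rows: list[dict] = []
        self.tracked_pairs: dict[int, OdorPair] = {}

    # -- construction ---------------------------------------------------------
    def _initial_synapses(self) -> SynapseMatrix:
        """Neonatal GCs: random dendritic fields, ``n_init`` consolidated
        synapses each (there is no activity history yet to bias fields)."""
        from .turnover import _new_columns
        mask, syn = _new_columns(self.state, self.params,
                                 self.state.n_gc, self.rng_init,
                                 self.params.n_mc)
        return SynapseMatrix(mask, syn)

    # -- the day loop ---------------------------------------------------------
    def run_day(self, day: DaySchedule) -> dict:
        """Run one day's presentations and the end-of-day turnover.

        Order per presentation: compose input, steady-state rates, calcium,
        plasticity.  At day end: memory evaluation of tracked pairs, then
        apoptosis, then neurogenesis.
        """
        params = self.params
        p_j, r_j, _ = resolve_age_parameters(
            self.state.gc_birthdate, self.state.day, day.enriched, params)
        n_pres = len(day.presentations)
        mc_sum = np.zeros(params.n_mc)
        gc_sum = np.zeros(self.state.n_gc)
        for odor in day.presentations:
            s = compose_input(params, odor)
            m, g = steady_state_response(params, self.synapses, r_j, s)
            ca = calcium_steady_state(m, g, r_j, params,
                                      self.synapses.field_mask)
            plasticity_step(self.synapses, ca, p_j, params,
                            self.rng_plasticity)
            mc_sum += m
            gc_sum += g
        mean_mc = mc_sum / max(n_pres, 1)
        mean_gc = gc_sum / max(n_pres, 1)
        self.state.mc_rates = mean_mc
        self.state.gc_rates = mean_gc
        self.state.record_day_activity(mean_mc, params.history_window)

        for pair_id, pair in self.tracked_pairs.items():
            mu = self.evaluate_memory(pair)
            self.trace_rows.append({
                "day": self.state.day, "pair_id": pair_id, "memory": mu,
                "n_gc": self.state.n_gc, "mode": self.memory_response_mode,
            })

        self.census_events.extend(apoptosis_step(
            self.state, self.synapses, mean_gc, day.enriched,
            self.rng_apoptosis, params))
        n_new = params.n_add
        if day.enriched and params.double_neurogenesis_during_enrichment:
            n_new *= 2
        self.census_events.extend(add_granule_cells(
            self.state, self.synapses, self.rng_neurogenesis, params,
            n_new))
        self.state.day += 1
        return {"mean_mc": mean_mc, "mean_gc": mean_gc, "n_gc": self.state.n_gc}

    def run_schedule(self, schedule: StimulusSchedule | list[DaySchedule],
                     track: bool = True) -> None:
        days = schedule.days if isinstance(schedule, StimulusSchedule) else schedule
        if isinstance(schedule, StimulusSchedule) and track:
            self.tracked_pairs.update(schedule.pairs)
        for day in days:
            self.run_day(day)

    # -- memory read-out ------------------------------------------------------
    def pair_response(self, pair: OdorPair) -> np.ndarray:
        """Mean steady-state MC response to the two odors of a pair."""
        params = self.params
        _, r_j, _ = resolve_age_parameters(
            self.state.gc_birthdate, self.state.day, False, params)
        if self.memory_response_mode == "current":
            weights = self.synapses.weights
        else:
            # naive template: inhibition from a degree-matched random network
            weights = metrics.shuffle_degrees_preserved(
                self.synapses.weights, self.rng_shuffles)
        responses = []
        for odor in (pair.a, pair.b):
            m, _ = steady_state_response(
                params, weights, r_j, compose_input(params, odor))
            responses.append(m)
        return np.mean(responses, axis=0)

    def evaluate_memory(self, pair: OdorPair) -> float:
        """Total connectivity-based memory of a pair at the current day."""
        mbar = self.pair_response(pair)
        return metrics.memory_score(
            self.synapses.weights, mbar,
            n_shuffles=self.params.n_shuffles, rng=self.rng_shuffles,
            method=self.params.null_method)

    # -- result assembly ------------------------------------------------------
    def result(self, protocol: ProtocolSpec | None = None,
               extras: dict | None = None,
               runtime_s: float = 0.0) -> ExperimentResult:
        trace = pd.DataFrame(
            self.trace_rows,
            columns=["day", "pair_id", "memory", "n_gc", "mode"])
        census = pd.DataFrame(
            [vars(e) for e in self.census_events],
            columns=["day", "event", "gc_id", "birthdate"])
        return ExperimentResult(
            trace=trace, census=census, params=self.params, seed=self.seed,
            protocol=protocol, pairs=dict(self.tracked_pairs),
            extras=extras or {}, state=self.state, synapses=self.synapses,
            runtime_s=runtime_s)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def _draw_pair(sim: Simulation, stimulus: str) -> OdorPair:
    if stimulus == "gaussian":
        return gaussian_odor_pair(sim.params, sim.rng_stimuli)
    if stimulus == "sparse":
        return sparse_odor_pair(sim.params, sim.rng_stimuli)
    raise ValueError(f"unknown stimulus family {stimulus!r}")


def _enrich_days(sim: Simulation, pair: OdorPair, n_days: int, pair_id: int,
                 label: str) -> list[DaySchedule]:
    return [_enrichment_day(pair, sim.params, label, pair_id)
            for _ in range(n_days)]


def _blanks(sim: Simulation, n_days: int) -> list[DaySchedule]:
    return [_blank_day(sim.params) for _ in range(n_days)]


def _run_perceptual_learning(sim: Simulation, opts: dict) -> dict:
    growth = opts.get("growth_days", 30)
    enrich = opts.get("enrichment_days", 10)
    post = opts.get("post_days", 30)
    pair = opts.get("pair") or _draw_pair(sim, opts.get("stimulus", "gaussian"))
    sim.run_schedule(_blanks(sim, growth))
    sim.tracked_pairs[0] = pair
    onset = sim.state.day
    sim.run_schedule(_enrich_days(sim, pair, enrich, 0, "enrichment-0"))
    offset = sim.state.day
    sim.run_schedule(_blanks(sim, post))
    return {"enrichment_onset": onset, "enrichment_offset": offset}


def _run_reenrichment(sim: Simulation, opts: dict) -> dict:
    growth = opts.get("growth_days", 30)
    enrich = opts.get("enrichment_days", 10)
    max_wait = opts.get("max_wait_days", 120)
    buffer = opts.get("buffer_days", 0)
    post2 = opts.get("post2_days", 0)
    block_neurogenesis = not opts.get("neurogenesis_at_reenrichment", True)
    pair = opts.get("pair") or _draw_pair(sim, opts.get("stimulus", "gaussian"))

    sim.run_schedule(_blanks(sim, growth))
    sim.tracked_pairs[0] = pair
    onset1 = sim.state.day
    sim.run_schedule(_enrich_days(sim, pair, enrich, 0, "enrichment-0"))
    offset1 = sim.state.day

    # spontaneous decay until the memory first clears (plus a buffer)
    clear_day = None
    for _ in range(max_wait):
        sim.run_day(_blank_day(sim.params))
        if sim.trace_rows[-1]["memory"] == 0.0:
            clear_day = sim.trace_rows[-1]["day"]
            break
    if clear_day is None:
        clear_day = sim.state.day - 1  # memory never cleared within max_wait
    sim.run_schedule(_blanks(sim, buffer))

    saved_flag = sim.params.neurogenesis
    if block_neurogenesis:
        sim.params = sim.params.replace(neurogenesis=False)
    onset2 = sim.state.day
    sim.run_schedule(_enrich_days(sim, pair, enrich, 0, "enrichment-0-re"))
    offset2 = sim.state.day
    sim.params = sim.params.replace(neurogenesis=saved_flag)
    sim.run_schedule(_blanks(sim, post2))
    return {"enrichment_onset": onset1, "enrichment_offset": offset1,
            "clear_day": clear_day, "reenrichment_onset": onset2,
            "reenrichment_offset": offset2}


def _mixed_enrichment_day(pairs: list[OdorPair], params: ModelParams,
                          epoch: str, pair_id: int) -> DaySchedule:
    # alternate over all odors of all presented pairs (A1, B1, A2, B2, ...)
    odors = [o for p in pairs for o in (p.a, p.b)]
    pres: list = []
    for k in range(params.presentations_per_day):
        pres.append(odors[k % len(odors)])
        pres.append(None)
    return DaySchedule(pres, enriched=True, epoch=epoch, pair_id=pair_id)


def _run_interference(sim: Simulation, opts: dict) -> dict:
    growth = opts.get("growth_days", 30)
    enrich = opts.get("enrichment_days", 10)
    gap = opts.get("gap_days", 0)
    post = opts.get("post_days", 20)
    keep_first = opts.get("keep_first_during_second", False)
    stimulus = opts.get("stimulus", "sparse")
    pair1 = opts.get("pair1") or _draw_pair(sim, stimulus)
    pair2 = opts.get("pair2") or _draw_pair(sim, stimulus)

    sim.run_schedule(_blanks(sim, growth))
    sim.tracked_pairs[0] = pair1
    onset1 = sim.state.day
    sim.run_schedule(_enrich_days(sim, pair1, enrich, 0, "enrichment-0"))
    sim.run_schedule(_blanks(sim, gap))
    sim.tracked_pairs[1] = pair2
    onset2 = sim.state.day
    if keep_first:
        days = [_mixed_enrichment_day([pair2, pair1], sim.params,
                                      "enrichment-1+0", 1)
                for _ in range(enrich)]
    else:
        days = _enrich_days(sim, pair2, enrich, 1, "enrichment-1")
    sim.run_schedule(days)
    sim.run_schedule(_blanks(sim, post))
    return {"onset_pair0": onset1, "onset_pair1": onset2}


def _run_sequential(sim: Simulation, opts: dict) -> dict:
    growth = opts.get("growth_days", 30)
    n_pairs = opts.get("n_pairs", 25)
    enrich = opts.get("enrichment_days", 10)
    interval = opts.get("interval_days", 10)  # blank days between enrichments
    post = opts.get("post_days", 0)
    stimulus = opts.get("stimulus", "sparse")

    sim.run_schedule(_blanks(sim, growth))
    onsets = {}
    for p in range(n_pairs):
        pair = _draw_pair(sim, stimulus)
        sim.tracked_pairs[p] = pair
        onsets[p] = sim.state.day
        sim.run_schedule(_enrich_days(sim, pair, enrich, p, f"enrichment-{p}"))
        if p < n_pairs - 1:
            sim.run_schedule(_blanks(sim, interval))
    sim.run_schedule(_blanks(sim, post))
    return {"onsets": onsets}


_RUNNERS = {
    "perceptual_learning": _run_perceptual_learning,
    "delayed_enrichment": _run_perceptual_learning,  # growth_days is the knob
    "reenrichment": _run_reenrichment,
    "interference": _run_interference,
    "sequential_enrichment": _run_sequential,
}


def run_protocol(spec: ProtocolSpec, params: ModelParams,
                 seed: int) -> ExperimentResult:
    """Run a named protocol and return its memory trace and census."""
    t0 = time.perf_counter()
    sim = Simulation(params, seed,
                     memory_response_mode=spec.options.get(
                         "memory_response_mode", "current"))
    extras = _RUNNERS[spec.name](sim, spec.options)
    return sim.result(protocol=spec, extras=extras,
                      runtime_s=time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

def sweep(spec: ProtocolSpec, params: ModelParams, grid: dict[str, list],
          seeds: list[int]) -> pd.DataFrame:
    """Run a protocol across a parameter grid and seeds.

    ``grid`` maps :class:`ModelParams` field names to value lists; the
    cartesian product is explored.  Each row records the memory at the first
    pair's enrichment end ("initial"), the memory on the last evaluated day
    ("end"), the final GC count and the runtime.
    """
    import itertools

    for name in grid:
        if not hasattr(params, name):
            raise KeyError(f"unknown parameter {name!r} in sweep grid")
    rows = []
    names = list(grid)
    for values in itertools.product(*(grid[n] for n in names)):
        point = dict(zip(names, values))
        run_params = params.replace(**point)
        for seed in seeds:
            res = run_protocol(spec, run_params, seed)
            first = res.trace[res.trace["pair_id"] == res.trace["pair_id"].min()]
            offset = res.extras.get("enrichment_offset")
            if offset is not None and not first.empty:
                at_end = first[first["day"] == offset - 1]
                initial = float(at_end["memory"].iloc[0]) if len(at_end) else np.nan
            else:
                initial = float(first["memory"].max()) if len(first) else np.nan
            end = float(first["memory"].iloc[-1]) if len(first) else np.nan
            rows.append({**point, "seed": seed, "initial_memory": initial,
                         "end_memory": end,
                         "n_gc": int(res.trace["n_gc"].iloc[-1]) if len(res.trace) else 0,
                         "runtime_s": res.runtime_s})
    return pd.DataFrame(rows)
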