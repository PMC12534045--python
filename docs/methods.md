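# Methods

`obsim` simulates perceptual learning and forgetting in the olfactory bulb
as the interplay of firing-rate dynamics, calcium-dependent structural
synaptic plasticity, and adult neurogenesis. This document defines the model
exactly as implemented.

## 1. Network and activity

The circuit contains `n_mc` mitral cells (MCs, excitatory principal neurons)
and a time-varying population of granule cells (GCs, axonless inhibitory
interneurons). MCs and GCs interact only through *reciprocal dendrodendritic
synapses*: a single synaptic site both excites the GC and inhibits the MC.
Connectivity is therefore one matrix.

Each GC `j` owns a fixed **dendritic field** — a set of `n_conn` MCs it could
ever contact. Within the field, each potential synapse is in one of three
states: *nonexistent*, *unconsolidated* (a silent precursor, weight 0), or
*consolidated* (functional, weight 1). The binary weight matrix `W` holds a 1
exactly where a synapse is consolidated.

Activity is evaluated at the steady state of the rate equations. With
external odor drive `S_i` (sensory input plus a spontaneous floor
`s_spont`), GC excitability `r_j`, and inhibition strength `γ`:

    M_i = [ S_i − γ Σ_j W_ij r_j G_j ]₊        (rectified linear MC rate)
    G_j = r_j Σ_i W_ij M_i                      (linear GC rate)

`steady_state_response` solves this fixed point with an active-set method:
guess the set of active (non-rectified) MCs, solve the resulting linear
system `(I + K) M = S` on that set with `K = γ W diag(r) Wᵀ`, and update the
set until it is self-consistent; cycles fall back to damped iteration. The
solution is verified against the residual of the defining equations.

## 2. Calcium-dependent structural plasticity

Each odor (or blank) presentation updates synapse states stochastically.
The local calcium proxy at site `(i, j)` at the activity fixed point is

    Ca_ij = C_pre · r_j · M_i + C_post · G_j ,

combining presynaptic (MC→GC) and postsynaptic (GC depolarization)
contributions. Transition rates follow sigmoidal threshold rules:

    R⁺(Ca) = R₀ + ½ (tanh g(Ca − θ⁺) + 1)      (consolidation)
    R⁻(Ca) = R₀ + d / cosh g(Ca − θ⁻)          (deconsolidation)

so consolidation is favored at high calcium and deconsolidation peaks in a
band around θ⁻; `R₀` is a small spontaneous rate acting even without odor
drive. The thresholds *slide* with each GC's recent activity:

    θ±_j = max(θ±_floor , k · ⟨Ca⟩_j),   k = 0.95,

where `⟨Ca⟩_j` is the mean calcium over GC `j`'s dendritic field. This
homeostatic rule makes strongly driven GCs harder to potentiate further and
protects weakly driven ones.

Per presentation, a rate `R` becomes a probability `P = 1 − exp(−p_j R)`,
where `p_j` is the GC's age-dependent plasticity. State transitions are
single-step: nonexistent → unconsolidated (rate `α`, scaled like R⁺),
unconsolidated → consolidated (R⁺), unconsolidated → nonexistent (`β`),
consolidated → unconsolidated (R⁻). An enrichment day presents the two
odors of the enriched pair alternately, each followed by a blank
(`2 · presentations_per_day` updates); blank days run the same number of
blank updates so spontaneous turnover has a uniform clock.

## 3. Adult neurogenesis, maturation and apoptosis

Every day `n_add` new GCs are added (optionally doubled during enrichment).
A GC's age sets three properties, with a **critical period** of
`critical_period` (14) days:

| property | young (age < 14) | mature |
|---|---|---|
| plasticity `p` | 0.2 | 0.02 |
| excitability `r` | 1.5 | 1.0 |
| apoptosis threshold `G₀` | 0.5 (enriched) / 0.0 (unenriched) | −0.45 |

Newborn GCs choose their dendritic field by **activity-dependent
elaboration**: MC `i` is scored `U(0, ε_max) + [m̄_i − θ_M]₊`, where `m̄_i`
is the MC's recent mean activity, and the top `n_conn` MCs form the field.
Active regions therefore recruit more new dendrites; disabling
`dendritic_elaboration` yields uniformly random fields.

Each day every GC risks **apoptosis** with probability

    P_kill = ½ (1 − tanh 5 (G − G₀)) ,

where `G` is its mean recent activity. Young cells in an unenriched
environment are culled aggressively (G₀ high), while mature cells survive
unless nearly silent (G₀ = −0.45). Removal deletes the GC's column;
additions and removals are logged in a census for survival analyses.

The initial `n_gc_init` GCs are created newborn on day 0 with random fields,
so the population prunes and settles into its self-organized operating point
during the growth epoch before any enrichment.

## 4. Memory statistic and null thresholds

Learning is quantified from connectivity alone. For an odor pair with mean
MC response `m̄` (average of the steady-state responses to both odors), each
GC's memory is `μ_j = Σ_i W_ij m̄_i` — how concentrated its consolidated
synapses are on responsive MCs. Chance-level concentration is removed with a
degree-preserving shuffle null: under random reassignment of GC `j`'s `d_j`
synapses, `μ_j` is a simple random sample (without replacement) of `d_j`
entries of `m̄`, with exact moments

    E[μ] = d · mean(m̄),   Var[μ] = d · σ²_pop(m̄) · (N − d)/(N − 1).

The threshold is `θ_j = E[μ] + 3 SD[μ]` (computed analytically by default, or
by Monte-Carlo shuffling), and the **total memory** is
`μˢ = Σ_j [μ_j − θ_j]₊`. A naive network scores near zero; learning raises
`μˢ`; forgetting is its decay back toward zero. Memory can be evaluated
against the *current* mean response or the *naive* (pre-learning) one.

GC sub-populations are identified by Ward hierarchical clustering of
connectivity columns, with significance assessed against degree-preserving
shuffles; the "learning" cluster is the one whose synapses concentrate on
the responsive MCs.

## 5. Protocols

All experiments compose a daily loop (presentations → plasticity →
apoptosis → neurogenesis). Provided protocols:

- **perceptual_learning** — growth epoch, 10-day enrichment, blank decay.
- **delayed_enrichment** — enrichment starting later in life.
- **reenrichment** — learn, wait for the memory to clear (or a horizon),
  re-enrich with the same pair; measures *savings* (faster relearning),
  optionally with neurogenesis blocked during re-enrichment.
- **interference** — two pairs enriched in sequence with a gap; tracks both.
- **sequential_enrichment** — a lifetime of `n_pairs` successive
  enrichments; measures life-long-learning capacity and overwriting.

Each run uses a single integer seed expanded into independent streams for
stimuli, initial wiring, plasticity, neurogenesis, apoptosis, and shuffles;
identical seeds reproduce bit-identical results.

## 6. Defaults

225 MCs, 900 initial GCs, 8 GCs added/day, fields of 30 MCs with 10 initial
unconsolidated synapses, γ = 0.004, R₀ = 0.01, g = 13, d = 0.7,
C_pre = 3.6, C_post = 1.1, θ⁺ ≥ 1.05, θ⁻ ≥ 1.0, 6 presentations per day.
Preset variants: `broad_params` (fields of 100, R₀ = 0.005),
`nonneurogenic_params` (no turnover, uniform p = 0.15, R₀ = 0.003),
`scaled_down_params` (100 MCs, 400 GCs — for fast multi-seed tests only).
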