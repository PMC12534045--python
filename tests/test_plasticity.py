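"""Calcium proxy, sliding thresholds and the three-state synapse chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from obsim import (CONSOLIDATED, NONEXISTENT, UNCONSOLIDATED, ModelParams,
                   SynapseMatrix, calcium_steady_state, consolidation_rate,
                   deconsolidation_rate, plasticity_step, rate_to_probability,
                   sliding_thresholds)


# ---------------------------------------------------------------------------
# rate functions (exact formula oracles)
# ---------------------------------------------------------------------------

def test_consolidation_rate_at_threshold(params):
    theta = np.array([1.05])
    val = consolidation_rate(np.array([1.05]), theta, params)
    assert val == pytest.approx(params.r0 + 0.5, abs=1e-15)


def test_deconsolidation_rate_peaks_at_threshold(params):
    theta = np.array([1.0])
    val = deconsolidation_rate(np.array([1.0]), theta, params)
    assert val == pytest.approx(params.r0 + params.d, abs=1e-15)
    # strictly below the peak away from the threshold
    off = deconsolidation_rate(np.array([1.3]), theta, params)
    assert off < val


def test_rate_bounds(params):
    ca = np.linspace(0, 10, 1001)
    theta = np.ones_like(ca)
    r_plus = consolidation_rate(ca, theta, params)
    r_minus = deconsolidation_rate(ca, theta, params)
    assert np.all(r_plus >= params.r0) and np.all(r_plus <= params.r0 + 1)
    # mathematically r_minus > r0 everywhere; far from the threshold the
    # bump underflows to exactly r0 in float64
    assert np.all(r_minus >= params.r0)
    assert np.all(r_minus <= params.r0 + params.d)
    assert np.all(np.diff(r_plus) >= 0)  # consolidation is monotone in calcium


def test_rate_to_probability_limits():
    assert rate_to_probability(0.0, 1.0) == 0.0
    assert rate_to_probability(5.0, 0.0) == 0.0
    assert rate_to_probability(1e9, 1.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        rate_to_probability(-1.0, 1.0)
    with pytest.raises(ValueError):
        rate_to_probability(1.0, -0.5)


@given(st.floats(min_value=0, max_value=50),
       st.floats(min_value=0, max_value=1))
def test_rate_to_probability_is_a_probability(rate, p):
    val = rate_to_probability(rate, p)
    assert 0.0 <= val <= 1.0
    assert val == pytest.approx(1.0 - np.exp(-p * rate), rel=1e-12)


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

def test_calcium_formula_exact(params, rng):
    n_mc, n_gc = 7, 5
    m = rng.uniform(0, 1, n_mc)
    g = rng.uniform(0, 2, n_gc)
    r = rng.uniform(0.5, 1.5, n_gc)
    mask = rng.random((n_mc, n_gc)) < 0.5
    field = calcium_steady_state(m, g, r, params, mask)
    expected = params.c_pre * np.outer(m, r) + params.c_post * g
    assert np.allclose(field.ca, expected, atol=1e-15)


def test_calcium_mean_is_over_the_full_field(params, rng):
    n_mc, n_gc = 10, 4
    m = rng.uniform(0, 1, n_mc)
    g = rng.uniform(0, 1, n_gc)
    r = np.ones(n_gc)
    mask = np.zeros((n_mc, n_gc), dtype=bool)
    mask[:3, 0] = True          # field of GC 0 = MCs 0..2
    mask[:, 1] = True           # full field
    # GC 2 and 3: empty fields -> mean 0 by convention
    field = calcium_steady_state(m, g, r, params, mask)
    ca = params.c_pre * np.outer(m, r) + params.c_post * g
    assert field.mean_per_gc[0] == pytest.approx(ca[:3, 0].mean())
    assert field.mean_per_gc[1] == pytest.approx(ca[:, 1].mean())
    assert field.mean_per_gc[2] == 0.0 and field.mean_per_gc[3] == 0.0


def test_calcium_rejects_negative_rates(params):
    with pytest.raises(ValueError):
        calcium_steady_state(-np.ones(3), np.ones(2), np.ones(2), params,
                             np.ones((3, 2), dtype=bool))


def test_sliding_thresholds_floors_and_scaling(params):
    ca_mean = np.array([0.0, 1.0, 2.0, 10.0])
    tp, tm = sliding_thresholds(ca_mean, params)
    # floors apply at low calcium
    assert tp[0] == params.theta_plus and tm[0] == params.theta_minus
    assert tp[1] == params.theta_plus and tm[1] == params.theta_minus
    # k * mean takes over at high calcium
    assert tp[2] == pytest.approx(params.k * 2.0)
    assert tm[2] == pytest.approx(params.k * 2.0)
    assert tp[3] == pytest.approx(params.k * 10.0)
    with pytest.raises(ValueError):
        sliding_thresholds(np.array([-0.1]), params)


# ---------------------------------------------------------------------------
# stochastic update
# ---------------------------------------------------------------------------

def _uniform_calcium(value, params, mask):
    n_mc, n_gc = mask.shape
    m = np.zeros(n_mc)
    g = np.full(n_gc, value / params.c_post)
    return calcium_steady_state(m, g, np.ones(n_gc), params, mask)


def test_zero_plasticity_freezes_everything(params, tiny_synapses, rng):
    before = tiny_synapses.state.copy()
    ca = _uniform_calcium(1.0, params, tiny_synapses.field_mask)
    for _ in range(20):
        plasticity_step(tiny_synapses, ca, np.zeros(tiny_synapses.n_gc),
                        params, rng)
    assert np.array_equal(tiny_synapses.state, before)


def test_plasticity_respects_field_mask(params, tiny_synapses, rng):
    ca = _uniform_calcium(1.0, params, tiny_synapses.field_mask)
    for _ in range(50):
        plasticity_step(tiny_synapses, ca, np.full(tiny_synapses.n_gc, 0.5),
                        params, rng)
        tiny_synapses.validate()  # states legal and only inside fields


def test_plasticity_rejects_bad_inputs(params, tiny_synapses, rng):
    ca = _uniform_calcium(1.0, params, tiny_synapses.field_mask)
    with pytest.raises(ValueError):
        plasticity_step(tiny_synapses, ca, np.ones(3), params, rng)
    bad = SynapseMatrix(tiny_synapses.field_mask,
                        np.full_like(tiny_synapses.state, 5))
    with pytest.raises(ValueError):
        plasticity_step(bad, ca, np.ones(tiny_synapses.n_gc), params, rng)


def _stationary_from_probs(p01, p10, p12, p21):
    """Stationary distribution of the 3-state chain from step probabilities."""
    t = np.array([[1 - p01, p01, 0.0],
                  [p10, 1 - p10 - p12, p12],
                  [0.0, p21, 1 - p21]])
    evals, evecs = np.linalg.eig(t.T)
    pi = np.real(evecs[:, np.argmax(np.real(evals))])
    return pi / pi.sum()


def test_single_synapse_frequencies_match_stationary(params):
    """Empirical occupancy of one synapse matches the analytic chain."""
    rng = np.random.default_rng(2024)
    p = params.replace(n_mc=1, n_conn=1, n_init=1, n_gc_init=1)
    mask = np.ones((1, 1), dtype=bool)
    syn = SynapseMatrix(mask, np.array([[UNCONSOLIDATED]], dtype=np.int8))
    ca_val = 1.02  # near the deconsolidation threshold: all rates active
    m = np.array([0.0])
    g = np.array([ca_val / p.c_post])
    ca = calcium_steady_state(m, g, np.ones(1), p, mask)
    plast = np.full(1, 0.5)

    n_steps = 30_000
    counts = np.zeros(3)
    for _ in range(n_steps):
        plasticity_step(syn, ca, plast, p, rng)
        counts[syn.state[0, 0]] += 1
    freq = counts / n_steps

    tp, tm = sliding_thresholds(ca.mean_per_gc, p)
    p01 = rate_to_probability(p.alpha, plast[0])
    p10 = rate_to_probability(p.beta, plast[0])
    p12 = rate_to_probability(consolidation_rate(ca.ca, tp, p), plast[0])[0, 0]
    p21 = rate_to_probability(deconsolidation_rate(ca.ca, tm, p), plast[0])[0, 0]
    pi = _stationary_from_probs(p01, p10, p12, p21)

    # tolerance: 4 x iid binomial SE (autocorrelation is mild at these rates)
    for k in range(3):
        se = np.sqrt(pi[k] * (1 - pi[k]) / n_steps)
        assert abs(freq[k] - pi[k]) < 6 * se + 0.01, (k, freq, pi)


def test_unconsolidated_fraction_without_consolidation(params):
    """With consolidation off (calcium far below threshold, negligible R0),
    the 0<->1 chain settles at alpha / (alpha + beta) = 1/2 occupancy."""
    rng = np.random.default_rng(7)
    p = params.replace(r0=1e-12)
    n = 2000
    mask = np.ones((1, n), dtype=bool)
    syn = SynapseMatrix(mask, np.zeros((1, n), dtype=np.int8))
    ca = calcium_steady_state(np.zeros(1), np.zeros(n), np.ones(n), p, mask)
    plast = np.full(n, 0.5)
    for _ in range(100):  # long enough to mix
        plasticity_step(syn, ca, plast, p, rng)
    frac = (syn.state == UNCONSOLIDATED).mean()
    expected = p.alpha / (p.alpha + p.beta)
    assert expected == 0.5
    assert abs(frac - expected) < 4 * np.sqrt(0.25 / n)
    assert not (syn.state == CONSOLIDATED).any()


def test_transitions_are_single_step(params, rng):
    """A synapse never jumps two states in one update."""
    p = params
    n = 500
    mask = np.ones((1, n), dtype=bool)
    state = np.array([[NONEXISTENT, UNCONSOLIDATED, CONSOLIDATED][j % 3]
                      for j in range(n)], dtype=np.int8)[np.newaxis, :]
    syn = SynapseMatrix(mask, state.copy())
    ca = _uniform_calcium(1.0, p, mask)
    for _ in range(30):
        before = syn.state.copy()
        plasticity_step(syn, ca, np.full(n, 1.0), p, rng)
        assert np.abs(syn.state.astype(int) - before.astype(int)).max() <= 1
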