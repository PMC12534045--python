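"""Memory statistic, shuffle nulls, clustering and composition analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest

from obsim import (birthdate_composition, cluster_granule_cells,
                   gc_memory, generate_fixture, label_learning_cluster,
                   memory_score, null_threshold, overwrite_ratio,
                   survival_fraction_by_birthdate, total_memory)
from obsim.metrics import _sample_moments, shuffle_degrees_preserved


# ---------------------------------------------------------------------------
# per-GC memory
# ---------------------------------------------------------------------------

def test_gc_memory_is_the_scalar_product(rng):
    w = (rng.random((10, 6)) < 0.4).astype(float)
    mbar = rng.uniform(0, 1, 10)
    mu = gc_memory(w, mbar)
    assert mu.shape == (6,)
    assert np.allclose(mu, mbar @ w)


def test_gc_memory_zero_column(rng):
    w = np.zeros((5, 3))
    assert np.allclose(gc_memory(w, rng.uniform(0, 1, 5)), 0.0)


def test_gc_memory_rejects_mismatch(rng):
    with pytest.raises(ValueError):
        gc_memory(np.zeros((5, 3)), np.zeros(4))
    with pytest.raises(ValueError):
        gc_memory(np.zeros((5, 3)), -np.ones(5))


# ---------------------------------------------------------------------------
# shuffle-null threshold
# ---------------------------------------------------------------------------

def _enumerated_threshold(mbar, degree, n_sd=3.0):
    sums = [mbar[list(c)].sum()
            for c in itertools.combinations(range(mbar.size), degree)]
    sums = np.array(sums)
    return sums.mean() + n_sd * sums.std()


def test_analytic_moments_match_enumeration(rng):
    mbar = rng.uniform(0, 1, 7)
    for degree in (1, 2, 3, 5):
        sums = np.array([mbar[list(c)].sum() for c in
                         itertools.combinations(range(7), degree)])
        mean, sd = _sample_moments(mbar, degree)
        assert mean == pytest.approx(sums.mean(), rel=1e-12)
        assert sd == pytest.approx(sums.std(), rel=1e-12)


def test_shuffle_null_enumeration_fixture():
    fx = generate_fixture("shuffle_enum")
    mbar, w = fx["mbar"], fx["weights"]
    expected = _enumerated_threshold(mbar, fx["degree"])
    analytic = null_threshold(w, mbar, method="analytic")[0]
    assert analytic == pytest.approx(expected, rel=1e-12)
    mc = null_threshold(w, mbar, method="mc", n_shuffles=10_000,
                        rng=np.random.default_rng(5))[0]
    assert mc == pytest.approx(expected, rel=0.02)


def test_null_threshold_per_degree_and_conventions(rng):
    mbar = rng.uniform(0, 1, 12)
    w = np.zeros((12, 4))
    w[:3, 0] = 1
    w[2:5, 1] = 1   # same degree as GC 0 -> same threshold
    w[:6, 2] = 1
    # GC 3 keeps degree zero -> threshold 0 by convention
    theta = null_threshold(w, mbar, method="analytic")
    assert theta[0] == theta[1]
    assert theta[2] != theta[0]
    assert theta[3] == 0.0


def test_null_threshold_requires_rng_for_mc(rng):
    w = np.ones((4, 1))
    with pytest.raises(ValueError):
        null_threshold(w, np.ones(4), method="mc")
    with pytest.raises(ValueError):
        null_threshold(w, np.ones(4), method="bogus", rng=rng)
    with pytest.raises(ValueError):
        null_threshold(w, np.ones(4), method="mc", n_shuffles=1, rng=rng)


def test_total_memory_clips_at_thresholds():
    mu = np.array([1.0, 2.0, 0.5])
    theta = np.array([1.5, 1.0, 0.5])
    assert total_memory(mu, theta) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        total_memory(mu, theta[:2])


# ---------------------------------------------------------------------------
# invariances and null calibration
# ---------------------------------------------------------------------------

def test_memory_invariant_under_gc_relabeling(rng):
    w = (rng.random((20, 15)) < 0.3).astype(float)
    mbar = rng.uniform(0, 1, 20)
    perm = rng.permutation(15)
    assert memory_score(w, mbar) == pytest.approx(
        memory_score(w[:, perm], mbar))


def test_memory_invariant_under_consistent_mc_permutation(rng):
    w = (rng.random((20, 15)) < 0.3).astype(float)
    mbar = rng.uniform(0, 1, 20)
    perm = rng.permutation(20)
    assert memory_score(w, mbar) == pytest.approx(
        memory_score(w[perm], mbar[perm]))


def test_shuffle_preserves_degrees(rng):
    w = (rng.random((30, 20)) < 0.3).astype(float)
    shuffled = shuffle_degrees_preserved(w, rng)
    assert np.array_equal(shuffled.sum(axis=0), w.sum(axis=0))
    assert set(np.unique(shuffled)) <= {0.0, 1.0}


def test_null_calibration_suppresses_chance_similarity(rng):
    """Random degree-matched connectivity carries (almost) no memory.

    The 3-SD threshold leaves only a small chance-level tail: the average
    random-network memory is a tiny fraction of that of a network whose GCs
    actually concentrate their synapses on the responsive MCs, and a large
    share of random draws scores exactly zero.  (With hundreds of GCs the
    per-GC false-positive rate of a 3-SD cut makes *strictly* zero draws the
    majority but not a near-certainty.)
    """
    n_mc, n_gc, degree = 225, 400, 10
    # a heterogeneous response profile similar to a broad odor pair
    i = np.arange(n_mc)
    mbar = 0.5 * np.exp(-((i - 75) ** 2) / 18.0**2) \
        + 0.3 * np.exp(-((i - 150) ** 2) / 18.0**2) + 0.03

    top = np.argsort(mbar)[-degree:]
    w_specific = np.zeros((n_mc, n_gc))
    w_specific[np.ix_(top, range(n_gc))] = 1.0
    specific = memory_score(w_specific, mbar)
    assert specific > 0

    totals = []
    for _ in range(100):
        w = np.zeros((n_mc, n_gc))
        for j in range(n_gc):
            w[rng.choice(n_mc, size=degree, replace=False), j] = 1.0
        totals.append(memory_score(w, mbar))
    totals = np.array(totals)
    assert totals.mean() < 0.02 * specific
    assert np.median(totals) < 0.01 * specific
    assert (totals == 0.0).mean() > 0.10


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_clustering_recovers_planted_blocks(rng):
    fx = generate_fixture("planted_clusters")
    report = cluster_granule_cells(fx["weights"], n_shuffles=200, rng=rng)
    assert report.n_clusters >= 2
    labels, truth = report.labels, fx["labels"]
    # best label matching over the two planted groups
    agreement = max(np.mean((labels == a) == (truth == 1))
                    for a in np.unique(labels))
    assert agreement >= 0.95
    lab = label_learning_cluster(report, fx["weights"], fx["responsive_mc"])
    in_learning = labels == lab
    assert np.mean(in_learning == (truth == 1)) >= 0.95


def test_clustering_reports_none_on_shuffles(rng):
    fx = generate_fixture("planted_clusters")
    shuffled = shuffle_degrees_preserved(fx["weights"], rng)
    report = cluster_granule_cells(shuffled, n_shuffles=200, rng=rng)
    assert report.n_clusters == 1
    assert label_learning_cluster(report, shuffled, fx["responsive_mc"]) is None


def test_clustering_trivial_cases(rng):
    report = cluster_granule_cells(np.zeros((10, 8)), n_shuffles=50, rng=rng)
    assert report.n_clusters == 1
    with pytest.raises(ValueError):
        cluster_granule_cells(np.zeros((10, 1)), rng=rng)
    with pytest.raises(ValueError):
        cluster_granule_cells(np.zeros((10, 8)), significance="magic", rng=rng)


# ---------------------------------------------------------------------------
# composition bookkeeping
# ---------------------------------------------------------------------------

def test_birthdate_composition_reproduces_rule():
    birthdates = np.array([-30, -10, -5, 2, 5, 12])
    labels = np.array([0, 0, 1, 1, 1, 0])
    comp = birthdate_composition(labels, birthdates, enrichment_onset=0)
    get = lambda lab, win: int(
        comp[(comp.label == lab) & (comp.window == win)]["count"].iloc[0])
    assert get(1, "developing") == 2   # born on days 2 and 5
    assert get(1, "critical") == 1     # born on day -5
    assert get(0, "mature") == 1       # born on day -30
    assert get(0, "developing") == 1   # born on day 12
    fr = comp[(comp.label == 1) & (comp.window == "developing")]
    assert fr["fraction"].iloc[0] == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        birthdate_composition(labels, birthdates[:-1], 0)


def test_survival_fraction_without_removals():
    census = pd.DataFrame([
        {"day": 0, "event": "added", "gc_id": i, "birthdate": 0}
        for i in range(5)])
    out = survival_fraction_by_birthdate(census, evaluation_day=30)
    assert np.allclose(out["fraction"], 1.0)


def test_survival_fraction_counts_removals_and_min_age():
    rows = [{"day": 0, "event": "added", "gc_id": i, "birthdate": 0}
            for i in range(4)]
    rows += [{"day": 20, "event": "added", "gc_id": 10 + i, "birthdate": 20}
             for i in range(2)]
    rows.append({"day": 5, "event": "removed", "gc_id": 0, "birthdate": 0})
    rows.append({"day": 40, "event": "removed", "gc_id": 1, "birthdate": 0})
    census = pd.DataFrame(rows)
    out = survival_fraction_by_birthdate(census, evaluation_day=25)
    # at day 25 only the day-0 cohort is older than min_age 0 + both cohorts
    by_bin = {int(r.birthdate_bin): r.fraction for r in out.itertuples()}
    assert by_bin[0] == pytest.approx(3 / 4)  # removal on day 40 not counted
    assert by_bin[20] == pytest.approx(1.0)
    out14 = survival_fraction_by_birthdate(census, evaluation_day=25,
                                           min_age=14)
    assert set(out14["birthdate_bin"]) == {0}
    with pytest.raises(ValueError):
        survival_fraction_by_birthdate(pd.DataFrame({"day": []}), 10)


def test_overwrite_ratio_conventions():
    ref = pd.Series([2.0, 1.0, 0.0], index=[1, 2, 3])
    with_sub = pd.Series([1.0, 1.0, 5.0], index=[1, 2, 3])
    ratio = overwrite_ratio(with_sub, ref)
    assert ratio[1] == pytest.approx(0.5)
    assert ratio[2] == pytest.approx(1.0)
    assert np.isnan(ratio[3])
    identical = overwrite_ratio(ref[:2], ref[:2])
    assert np.allclose(identical, 1.0)
    with pytest.raises(ValueError):
        overwrite_ratio(with_sub, ref[:2])
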