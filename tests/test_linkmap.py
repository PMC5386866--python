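import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sibmap import linkmap as lm


def arr(values):
    return np.array(values, dtype=np.int8)


# -- two-point --------------------------------------------------------------


def test_twopoint_zero_recombinants_lod():
    a = arr([0, 1] * 10)
    est = lm.twopoint(a, a)
    assert est.rhat == 0.0
    assert est.lod == pytest.approx(20 * math.log10(2), abs=1e-9)  # ~6.02


def test_twopoint_two_of_twenty():
    a = arr([0] * 10 + [1] * 10)
    b = a.copy()
    b[0] ^= 1
    b[10] ^= 1
    est = lm.twopoint(a, b)
    assert est.rhat == pytest.approx(0.10)
    assert est.n_informative == 20


def test_twopoint_independent_markers_null():
    a = arr([0, 1] * 10)
    b = arr([0] * 10 + [1] * 10)
    est = lm.twopoint(a, b)
    assert est.rhat == 0.5
    assert est.lod == 0.0


def test_twopoint_phase_min_rule_symmetric():
    a = arr([0, 0, 0, 1, 1, 1])
    b = arr([1, 1, 1, 0, 0, 0])  # perfect repulsion = coupling after flip
    est = lm.twopoint(a, b)
    assert est.rhat == 0.0
    assert est.flipped


def test_twopoint_no_informative_raises():
    a = arr([-1, -1])
    with pytest.raises(lm.LinkageError):
        lm.twopoint(a, arr([0, 1]))


def test_pairwise_matches_scalar(rng):
    M = rng.integers(-1, 2, size=(6, 40)).astype(np.int8)
    rhat, lod, n = lm.pairwise_estimates(M)
    for i in range(6):
        for j in range(i + 1, 6):
            if n[i, j] == 0:
                continue
            est = lm.twopoint(M[i], M[j])
            assert rhat[i, j] == pytest.approx(est.rhat)
            assert lod[i, j] == pytest.approx(est.lod, abs=1e-9)
            assert n[i, j] == est.n_informative
    assert np.allclose(rhat, rhat.T, equal_nan=True)


# -- grouping ---------------------------------------------------------------


def test_group_two_linked_markers():
    lod = np.array([[0.0, 8.0], [8.0, 0.0]])
    assert lm.group(lod) == [[0, 1]]


def test_group_threshold_infinite_all_singletons():
    lod = np.full((4, 4), 10.0)
    np.fill_diagonal(lod, 0.0)
    assert lm.group(lod, lod_threshold=np.inf) == [[0], [1], [2], [3]]


def test_group_recovers_simulated_lg_count(small_pop):
    ids, M = lm.transmission_matrix(small_pop.table, "maternal")
    rhat, lod, n = lm.pairwise_estimates(M)
    groups = lm.group(np.where(n > 0, lod, 0.0))
    assert sum(1 for g in groups if len(g) > 1) == 2


# -- Kosambi ----------------------------------------------------------------


def test_kosambi_closed_forms():
    assert lm.kosambi_d(0.0) == 0.0
    assert lm.kosambi_d(0.25) == pytest.approx(25 * math.log(3))  # ~27.465
    assert lm.kosambi_r(10.0) == pytest.approx(0.5 * math.tanh(0.2))  # ~0.0987


def test_kosambi_out_of_domain():
    with pytest.raises(ValueError):
        lm.kosambi_d(0.5)
    with pytest.raises(ValueError):
        lm.kosambi_r(-1.0)


@settings(max_examples=100, deadline=None)
@given(st.floats(min_value=0.0, max_value=0.49))
def test_kosambi_mutual_inverse(r):
    assert lm.kosambi_r(lm.kosambi_d(r)) == pytest.approx(r, abs=1e-12)


# -- ordering ---------------------------------------------------------------


def test_order_three_markers_exhaustive():
    r = np.array([[0.0, 0.05, 0.10],
                  [0.05, 0.0, 0.05],
                  [0.10, 0.05, 0.0]])
    ids = ["A", "B", "C"]
    order = lm.order_markers(r, ids)
    # oracle: best of the 3 distinct linear orders
    best = min(
        ([0, 1, 2], [0, 2, 1], [1, 0, 2]),
        key=lambda o: r[o[0], o[1]] + r[o[1], o[2]],
    )
    got = [ids[i] for i in order]
    assert got in (list("ABC"), list("CBA"))
    assert lm._sarf(order, r) == pytest.approx(lm._sarf(best, r))


def test_order_two_markers_canonical():
    r = np.array([[0.0, 0.1], [0.1, 0.0]])
    assert [lm.order_markers(r, ["B", "A"])[i] for i in range(2)] == [1, 0]


def test_order_recovers_simulated_order(small_pop):
    sim = small_pop
    ids, M = lm.transmission_matrix(sim.table, "maternal")
    rhat, lod, n = lm.pairwise_estimates(M)
    groups = lm.group(np.where(n > 0, lod, 0.0))
    tm = sim.truth.true_maps["maternal"]
    tp = tm.position_of()
    members = groups[0]
    sub_ids = [ids[i] for i in members]
    order = lm.order_markers(rhat[np.ix_(members, members)], sub_ids)
    true_pos = [tp[sub_ids[i]][1] for i in order]
    rho = abs(np.corrcoef(np.argsort(np.argsort(true_pos)), range(len(true_pos)))[0, 1])
    assert rho > 0.999


# -- distances --------------------------------------------------------------


def test_regression_two_markers_single_interval():
    r = np.array([[0.0, 0.1], [0.1, 0.0]])
    lod = np.array([[0.0, 5.0], [5.0, 0.0]])
    pos = lm.regression_distances([0, 1], r, lod)
    assert pos[0] == 0.0
    assert pos[1] == pytest.approx(25 * math.log(1.2 / 0.8))  # ~10.14 cM


def test_regression_recovers_additive_distances():
    true = np.array([0.0, 4.0, 9.0, 15.0, 22.0, 30.0])
    m = len(true)
    r = np.zeros((m, m))
    lod = np.full((m, m), 10.0)
    for i in range(m):
        for j in range(m):
            if i != j:
                r[i, j] = lm.kosambi_r(abs(true[i] - true[j]))
    pos = lm.regression_distances(list(range(m)), r, lod, window=3)
    assert np.sqrt(np.mean((pos - true) ** 2)) < 0.1


def test_regression_zero_r_bin_all_equal():
    m = 3
    r = np.zeros((m, m))
    lod = np.full((m, m), 10.0)
    pos = lm.regression_distances(list(range(m)), r, lod)
    assert np.allclose(pos, 0.0)


# -- cleaning ---------------------------------------------------------------


def _noisy_marker_setup(rng, error_rate=0.15):
    from sibmap import synthdata as sd
    from sibmap.pipeline_io import GenotypeTable, MarkerRecord

    cfg = sd.SimConfig(n_lg=1, lg_lengths=[60.0], n_progeny=200,
                       marker_density=0.5, seed=31)
    sim = sd.simulate_population(cfg)
    records = list(sim.table.records)
    # corrupt one maternal marker heavily
    victim = next(r for r in records if r.seg_code == "lmxll"
                  and 20 < sim.truth.true_maps["maternal"].position_of()[r.marker_id][1] < 40)
    calls = list(victim.calls)
    flip = {"ll": "lm", "lm": "ll"}
    for i in range(len(calls)):
        if rng.random() < error_rate and calls[i] in flip:
            calls[i] = flip[calls[i]]
    records[records.index(victim)] = MarkerRecord(victim.marker_id, "lmxll", calls)
    return GenotypeTable(sim.table.progeny, records), victim.marker_id


def test_clean_removes_noisy_marker(rng):
    table, victim = _noisy_marker_setup(rng)
    gmap, info = lm.map_parent(table, "maternal")
    assert victim in info["removed"]


def test_clean_thresholds_infinite_identity(small_pop):
    gmap, info = lm.map_parent(
        small_pop.table, "maternal",
        fit_max=np.inf, stress_max=np.inf, stress_cm_max=np.inf,
    )
    assert info["removed"] == {}


def test_clean_noiseless_zero_removals(small_pop):
    _, info = lm.map_parent(small_pop.table, "maternal")
    assert info["removed"] == {}


def test_clean_never_increases_length(rng):
    table, _ = _noisy_marker_setup(rng)
    loose, _ = lm.map_parent(table, "maternal",
                             fit_max=np.inf, stress_max=np.inf, stress_cm_max=np.inf)
    strict, _ = lm.map_parent(table, "maternal")
    assert strict.total_length <= loose.total_length + 1e-9


# -- invariants -------------------------------------------------------------


def test_rhat_symmetric_and_relabel_invariant(rng):
    a = rng.integers(0, 2, 50).astype(np.int8)
    b = rng.integers(0, 2, 50).astype(np.int8)
    e1 = lm.twopoint(a, b)
    e2 = lm.twopoint(b, a)
    e3 = lm.twopoint(a ^ 1, b)  # allele relabeling
    assert e1.rhat == e2.rhat == e3.rhat
    assert e1.lod == pytest.approx(e3.lod)
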