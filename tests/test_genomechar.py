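import math

import numpy as np
import pytest

from sibmap import genomechar as gc
from sibmap.codes import MISSING
from sibmap.pipeline_io import GeneticMap, MarkerRecord, PhasedLG


def uni_record(n0, n1, seg="lmxll"):
    calls = (["ll"] * n0 + ["lm"] * n1) if seg == "lmxll" else (["nn"] * n0 + ["np"] * n1)
    return MarkerRecord("M1", seg, calls)


def make_phased(phases, positions=None, lg="LG1"):
    phases = np.array(phases, dtype=np.int8)
    if positions is None:
        positions = np.arange(phases.shape[1], dtype=float)
    return PhasedLG(lg, [f"M{j}" for j in range(phases.shape[1])], positions, phases)


# -- chi-square -------------------------------------------------------------


def test_chi2_balanced():
    chi2, p = gc.sd_chi2(uni_record(50, 50))
    assert chi2 == 0.0 and p == 1.0


def test_chi2_40_60_distorted_at_10pct():
    chi2, p = gc.sd_chi2(uni_record(40, 60))
    assert chi2 == pytest.approx(4.0)
    assert p == pytest.approx(math.erfc(math.sqrt(2.0)), abs=1e-10)  # ~0.0455
    assert p < 0.1


def test_chi2_55_45_not_distorted():
    chi2, p = gc.sd_chi2(uni_record(45, 55))
    assert chi2 == pytest.approx(1.0)
    assert p == pytest.approx(math.erfc(math.sqrt(0.5)), abs=1e-10)  # ~0.317
    assert p > 0.1


def test_chi2_no_informative_calls_skipped():
    rec = MarkerRecord("M1", "lmxll", [MISSING] * 4)
    assert gc.sd_chi2(rec) is None


def test_chi2_hk_pooled_alleles():
    rec = MarkerRecord("M1", "hkxhk", ["hh"] * 25 + ["hk"] * 50 + ["kk"] * 25)
    chi2, p = gc.sd_chi2(rec)
    assert chi2 == 0.0


# -- SDR calling ------------------------------------------------------------


def _scan(pvals, positions, alpha=0.1):
    pvals = np.asarray(pvals, dtype=float)
    return gc.SDScan([f"M{i}" for i in range(len(pvals))],
                     np.asarray(positions, dtype=float),
                     np.zeros(len(pvals)), pvals, alpha)


def test_no_distortion_no_sdr():
    scan = _scan([0.5] * 10, np.arange(10))
    assert gc.find_sdrs(scan) == []


def test_six_consecutive_within_gap_one_sdr():
    pv = [0.5, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.5]
    pos = [0, 1, 2, 3, 3.5, 4, 5, 10]
    assert gc.find_sdrs(_scan(pv, pos)) == [(1.0, 5.0)]


def test_run_broken_by_large_gap():
    pv = [0.01] * 6
    pos = [0, 1, 2, 10, 11, 12]  # 8 cM gap splits the run
    assert gc.find_sdrs(_scan(pv, pos), min_run=3) == [(0.0, 2.0), (10.0, 12.0)]


def test_short_run_not_reported():
    pv = [0.01] * 4 + [0.5] * 4
    assert gc.find_sdrs(_scan(pv, np.arange(8))) == []


# -- RF profiles ------------------------------------------------------------


def test_rf_profile_hand_enumeration():
    rows = [[0, 0, 0, 0], [0, 0, 1, 1], [0, 1, 1, 1], [1, 1, 1, 0]]
    prof = gc.rf_profile(make_phased(rows))
    assert np.isnan(prof.rf_from_start[0])
    assert prof.rf_from_start[1:].tolist() == [0.25, 0.50, 0.75]
    assert prof.rf_from_end[:-1].tolist() == [0.75, 0.50, 0.25]
    assert np.isnan(prof.rf_from_end[-1])


def test_rf_profile_zero_recombinants():
    prof = gc.rf_profile(make_phased([[0, 0, 0], [1, 1, 1]]))
    assert np.nansum(prof.rf_from_start) == 0.0


def test_rf_profile_opposite_anchor_consistency(small_pop):
    prof = gc.rf_profile(small_pop.truth.true_phases["maternal"]["LG1"])
    assert prof.rf_from_start[-1] == pytest.approx(prof.rf_from_end[0])


def test_rf_profile_saturates_with_distance():
    from sibmap import synthdata as sd

    cfg = sd.SimConfig(n_lg=1, lg_lengths=[150.0], n_progeny=300,
                       marker_density=0.4, seed=61)
    sim = sd.simulate_population(cfg)
    prof = gc.rf_profile(sim.truth.true_phases["maternal"]["LG1"])
    # early markers low, far markers approaching 0.5
    assert np.nanmean(prof.rf_from_start[1:5]) < 0.15
    assert np.nanmean(prof.rf_from_start[-5:]) > 0.35


def test_rf_profile_needs_three_markers():
    with pytest.raises(ValueError):
        gc.rf_profile(make_phased([[0, 1]]))


def test_rf_profile_anchor_shifts_when_terminal_mostly_missing():
    rows = np.array([[-1, 0, 0, 1], [-1, 0, 1, 1], [0, 1, 1, 1], [-1, 0, 0, 0]],
                    dtype=np.int8)
    prof = gc.rf_profile(make_phased(rows))
    assert np.isnan(prof.rf_from_start[1])  # anchor moved to second marker


# -- centromere spans -------------------------------------------------------


def test_centromere_toy_intersection_between_markers():
    rows = [[0, 0, 0, 0], [0, 0, 1, 1], [0, 1, 1, 1], [1, 1, 1, 0]]
    prof = gc.rf_profile(make_phased(rows, positions=[0.0, 1.0, 2.0, 3.0]))
    span = gc.centromere_span(prof, rf_threshold=0.45)
    assert span.intersection == pytest.approx(1.5)


def test_centromere_no_crossing_undetermined():
    # all recombination at the far end: rf_from_start stays below rf_from_end
    rows = [[0, 0, 0, 1], [0, 0, 0, 1], [0, 0, 0, 0], [0, 0, 0, 0]]
    prof = gc.rf_profile(make_phased(rows))
    span = gc.centromere_span(prof)
    assert span.classification == "undetermined"
    assert span.intersection is None


def test_centromere_mirror_symmetry():
    from sibmap import synthdata as sd

    cfg = sd.SimConfig(n_lg=1, lg_lengths=[60.0], n_progeny=200, marker_density=1.0,
                       suppression_width=10.0, suppression_factor=0.2, seed=71)
    sim = sd.simulate_population(cfg)
    phased = sim.truth.true_phases["maternal"]["LG1"]
    span = gc.centromere_span(gc.rf_profile(phased), rf_threshold=0.35)
    mirrored = PhasedLG(
        phased.lg,
        phased.marker_ids[::-1],
        60.0 - phased.positions[::-1],
        phased.phases[:, ::-1],
        phased.progeny,
    )
    span_m = gc.centromere_span(gc.rf_profile(mirrored), rf_threshold=0.35)
    assert span_m.intersection == pytest.approx(60.0 - span.intersection, abs=1e-6)
    assert span_m.span_start == pytest.approx(60.0 - span.span_end, abs=1e-6)
    assert span_m.span_end == pytest.approx(60.0 - span.span_start, abs=1e-6)


def test_centromere_uniform_lg_metacentric():
    from sibmap import synthdata as sd

    cfg = sd.SimConfig(n_lg=1, lg_lengths=[100.0], n_progeny=300,
                       marker_density=0.6, seed=81)
    sim = sd.simulate_population(cfg)
    prof = gc.rf_profile(sim.truth.true_phases["maternal"]["LG1"])
    span = gc.centromere_span(prof, rf_threshold=0.35)
    assert span.classification == "metacentric"
    assert 30.0 < span.intersection < 70.0


# -- collinearity -----------------------------------------------------------


def test_collinearity_identical_orders():
    pos = {f"M{i}": float(i) for i in range(10)}
    rho, n = gc.collinearity_lg(pos, dict(pos))
    assert rho == pytest.approx(1.0)
    assert n == 10


def test_collinearity_adjacent_swap_oracle():
    a = {m: float(i) for i, m in enumerate("ABCDE")}
    b = dict(a)
    b["B"], b["C"] = b["C"], b["B"]
    rho, n = gc.collinearity_lg(a, b)
    # rho = 1 - 6 * sum d^2 / (n(n^2-1)) with sum d^2 = 2
    assert rho == pytest.approx(1 - 6 * 2 / (5 * 24))  # 0.9
    assert n == 5


def test_collinearity_reversed_map_aligned():
    a = {m: float(i) for i, m in enumerate("ABCDE")}
    b = {m: 10.0 - p for m, p in a.items()}
    rho, _ = gc.collinearity_lg(a, b)
    assert rho == pytest.approx(1.0)


def test_collinearity_too_few_shared():
    assert gc.collinearity_lg({"A": 0.0}, {"A": 1.0}) is None


def test_collinearity_pairs_lgs_by_shared_markers():
    map_a = GeneticMap([("LG1", "A", 0.0), ("LG1", "B", 5.0),
                        ("LG2", "C", 0.0), ("LG2", "D", 5.0)])
    map_b = GeneticMap([("LGx", "C", 0.0), ("LGx", "D", 4.0),
                        ("LGy", "A", 0.0), ("LGy", "B", 6.0)])
    out = gc.collinearity(map_a, map_b)
    assert out[("LG1", "LGy")][0] == pytest.approx(1.0)
    assert out[("LG2", "LGx")][0] == pytest.approx(1.0)


# -- maternal/paternal comparison -------------------------------------------


def test_paired_compare_identical_zero():
    res = gc.maternal_paternal_compare([1.0, 0.8, 0.9], [1.0, 0.8, 0.9])
    assert res.mean_difference == 0.0
    assert res.t_statistic == 0.0
    assert res.p_value == 1.0
    assert res.fraction_maternal_ge == 1.0


def test_paired_compare_constant_shift_degenerate():
    mat = np.full(36, 1.0) + 0.18
    pat = np.full(36, 1.0)
    res = gc.maternal_paternal_compare(mat, pat)
    assert math.isinf(res.t_statistic)
    assert res.p_value == 0.0
    assert res.mean_difference == pytest.approx(0.18)


def test_paired_compare_matches_scipy():
    from scipy import stats

    rng = np.random.default_rng(5)
    a = rng.normal(1.1, 0.1, 12)
    b = rng.normal(1.0, 0.1, 12)
    res = gc.maternal_paternal_compare(a, b)
    ref = stats.ttest_rel(a, b)
    assert res.t_statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)


def test_paired_compare_needs_two_pairs():
    with pytest.raises(ValueError):
        gc.maternal_paternal_compare([1.0], [0.9])


# -- coancestry -------------------------------------------------------------


FOUNDERS = {"F1": (None, None), "F2": (None, None), "F3": (None, None), "F4": (None, None)}


def test_self_coancestry_non_inbred():
    ped = dict(FOUNDERS)
    assert gc.coancestry(ped, "F1", "F1") == 0.5


def test_parent_offspring():
    ped = dict(FOUNDERS)
    ped["X"] = ("F1", "F2")
    assert gc.coancestry(ped, "X", "F1") == 0.25


def test_full_sibs():
    ped = dict(FOUNDERS)
    ped["X"] = ("F1", "F2")
    ped["Y"] = ("F1", "F2")
    assert gc.coancestry(ped, "X", "Y") == 0.25


def test_inbred_self_coancestry():
    ped = dict(FOUNDERS)
    ped["X"] = ("F1", "F2")
    ped["Y"] = ("F1", "F2")
    ped["Z"] = ("X", "Y")  # full-sib mating
    assert gc.coancestry(ped, "Z", "Z") == 0.5 * (1 + 0.25)


def test_coancestry_symmetric_and_bounded():
    ped = dict(FOUNDERS)
    ped["X"] = ("F1", "F2")
    ped["Y"] = ("F2", "F3")
    ped["Z"] = ("X", "Y")
    for a in ped:
        for b in ped:
            f_ab = gc.coancestry(ped, a, b)
            assert f_ab == gc.coancestry(ped, b, a)
            assert 0.0 <= f_ab <= 1.0


def test_pedigree_cycle_rejected():
    ped = {"A": ("B", None), "B": ("A", None)}
    with pytest.raises(gc.PedigreeError):
        gc.coancestry(ped, "A", "B")


def test_missing_parent_is_unknown_founder():
    ped = {"A": (None, None), "B": ("A", None)}
    assert gc.coancestry(ped, "A", "B") == 0.25


# -- null-scan invariant ----------------------------------------------------


def test_null_scan_fraction_distorted_near_alpha():
    from sibmap import synthdata as sd

    cfg = sd.SimConfig(n_lg=12, lg_lengths=[90.0] * 12, n_progeny=200,
                       marker_density=0.4, seed=91)
    sim = sd.simulate_population(cfg)
    gmap = sim.truth.true_maps["maternal"]
    fracs = []
    for lg in gmap.lgs():
        scan = gc.sd_scan(list(sim.table), gmap, lg, alpha=0.1, parent="maternal")
        fracs.append(float(scan.distorted.mean()))
    from scipy import stats

    # discrete binomial tail at n=200: P(|X-100| >= 12)
    p_expected = 2 * stats.binom.sf(111, 200, 0.5)
    mean = float(np.mean(fracs))
    se_blocks = float(np.std(fracs, ddof=1) / math.sqrt(len(fracs)))
    assert abs(mean - p_expected) <= 3 * se_blocks + 0.01
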