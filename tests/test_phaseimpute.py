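import numpy as np
import pytest

from sibmap import phaseimpute as pi
from sibmap.codes import MISSING
from sibmap.linkmap import kosambi_r
from sibmap.pipeline_io import GeneticMap, GenotypeTable, MarkerRecord, PhasedLG


def make_phased(phases, positions=None, lg="LG1"):
    phases = np.array(phases, dtype=np.int8)
    if positions is None:
        positions = np.arange(phases.shape[1], dtype=float)
    return PhasedLG(lg, [f"M{j}" for j in range(phases.shape[1])], positions, phases)


# -- assign_phase -----------------------------------------------------------


def _uni_table(calls_by_marker, progeny=None):
    n = len(next(iter(calls_by_marker.values())))
    progeny = progeny or [f"P{i}" for i in range(n)]
    recs = [MarkerRecord(m, "lmxll", c) for m, c in calls_by_marker.items()]
    return GenotypeTable(progeny, recs)


def test_assign_phase_coupling_same_label():
    table = _uni_table({
        "A": ["ll", "ll", "lm", "lm"] * 5,
        "B": ["ll", "ll", "lm", "lm"] * 5,
    })
    gmap = GeneticMap([("LG1", "A", 0.0), ("LG1", "B", 5.0)])
    phased = pi.assign_phase(gmap, table, "maternal")["LG1"]
    assert np.array_equal(phased.phases[:, 0], phased.phases[:, 1])


def test_assign_phase_detects_flipped_marker(small_pop):
    sim = small_pop
    gmap = sim.truth.true_maps["maternal"]
    records = []
    flip = {"ll": "lm", "lm": "ll"}
    flipped_id = None
    anchor = next(m for m in gmap.lg_markers("LG1"))
    n_seen = 0
    for rec in sim.table:
        if rec.seg_code == "lmxll" and rec.lg == "LG1":
            n_seen += 1
        # flip a mid-LG marker, never the anchor (flipping the anchor merely
        # complements the whole matrix)
        if (rec.seg_code == "lmxll" and flipped_id is None and rec.lg == "LG1"
                and rec.marker_id != anchor and n_seen > 10):
            # flip every call: pure orientation change, phases must re-align
            records.append(MarkerRecord(rec.marker_id, rec.seg_code,
                                        [flip.get(c, c) for c in rec.calls]))
            flipped_id = rec.marker_id
        else:
            records.append(rec)
    flipped_table = GenotypeTable(sim.table.progeny, records)
    orig = pi.assign_phase(gmap, sim.table, "maternal")["LG1"]
    new = pi.assign_phase(gmap, flipped_table, "maternal")["LG1"]
    assert np.array_equal(orig.phases, new.phases)


def test_assign_phase_single_marker_anchor_a():
    table = _uni_table({"A": ["ll", "lm", "ll", "lm"]})
    gmap = GeneticMap([("LG1", "A", 0.0)])
    phased = pi.assign_phase(gmap, table, "maternal")["LG1"]
    assert np.array_equal(phased.phases[:, 0], [0, 1, 0, 1])


def test_assign_phase_ambiguous_excluded():
    table = _uni_table({
        "A": ["ll", "ll", "lm", "lm"],
        "B": ["ll", "lm", "ll", "lm"],  # exactly 50% mismatch with A
    })
    gmap = GeneticMap([("LG1", "A", 0.0), ("LG1", "B", 1.0)])
    phased = pi.assign_phase(gmap, table, "maternal")["LG1"]
    assert (phased.phases[:, 1] == -1).all()


# -- imputation -------------------------------------------------------------


def test_impute_flanks_agree_one_cm():
    phased = make_phased([[0, -1, 0]], positions=[0.0, 1.0, 2.0])
    out = pi.impute_missing(phased)
    assert out.phases[0, 1] == 0
    r = kosambi_r(1.0)
    posterior = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
    assert posterior > 0.999


def test_impute_flanks_disagree_equidistant_left_missing():
    phased = make_phased([[0, -1, 1]], positions=[0.0, 1.0, 2.0])
    out = pi.impute_missing(phased)
    assert out.phases[0, 1] == -1


def test_impute_terminal_single_flank():
    phased = make_phased([[-1, 0, 0]], positions=[0.0, 1.0, 2.0])
    out = pi.impute_missing(phased)
    # single flank at r = kosambi_r(1.0) ~ 0.01 -> posterior 0.99 >= 0.95
    assert out.phases[0, 0] == 0


def test_impute_both_flanks_missing_left_missing():
    phased = make_phased([[-1, -1, -1]])
    out = pi.impute_missing(phased)
    assert (out.phases == -1).all()


def test_impute_monotone_never_touches_observed(noisy_pop):
    phased = pi.assign_phase(
        noisy_pop.truth.true_maps["maternal"], noisy_pop.table, "maternal"
    )["LG1"]
    out = pi.impute_missing(phased)
    obs = phased.phases >= 0
    assert np.array_equal(out.phases[obs], phased.phases[obs])
    assert (out.phases >= 0).sum() >= obs.sum()


def test_impute_accuracy_on_simulated_missing(noisy_pop):
    sim = noisy_pop
    ok = n = 0
    for lg in ("LG1", "LG2"):
        phased = pi.assign_phase(sim.truth.true_maps["maternal"], sim.table, "maternal")[lg]
        truth = sim.truth.true_phases["maternal"][lg]
        obs = phased.phases >= 0
        flip = (phased.phases[obs] == truth.phases[obs]).mean() < 0.5
        out = pi.impute_missing(phased)
        new = (out.phases >= 0) & ~obs
        est = out.phases[new] ^ (1 if flip else 0)
        ok += int((est == truth.phases[new]).sum())
        n += int(new.sum())
    assert n > 500
    assert ok / n >= 0.99


# -- hk resolution and splitting --------------------------------------------


def test_resolve_hk_homozygotes_trivial():
    mat = make_phased([[0, 0], [1, 1], [0, 0]], positions=[0.0, 2.0])
    pat = make_phased([[0, 0], [0, 0], [1, 1]], positions=[0.0, 2.0])
    rec = MarkerRecord("X", "hkxhk", ["hh", "kk", MISSING])
    res = pi.resolve_hk(rec, 1.0, 1.0, mat, pat)
    assert res[0] == ("h", "h")
    assert res[1] == ("k", "k")
    assert res[2] == (None, None)


def test_resolve_hk_uses_flank_posteriors():
    # progeny0: hh anchors orientation (phase 0 carries h in both parents)
    # progeny1: hk with maternal phase 0 (h) and paternal phase 1 (k)
    # progeny2: kk anchors the reverse
    mat = make_phased([[0, 0], [0, 0], [1, 1]], positions=[0.0, 2.0])
    pat = make_phased([[0, 0], [1, 1], [1, 1]], positions=[0.0, 2.0])
    rec = MarkerRecord("X", "hkxhk", ["hh", "hk", "kk"])
    res = pi.resolve_hk(rec, 1.0, 1.0, mat, pat)
    assert res[1] == ("h", "k")


def test_resolve_hk_ambiguous_left_missing():
    mat = make_phased([[0, 0], [0, 1]], positions=[0.0, 2.0])
    pat = make_phased([[0, 0], [1, 0]], positions=[0.0, 2.0])
    rec = MarkerRecord("X", "hkxhk", ["hh", "hk"])
    res = pi.resolve_hk(rec, 1.0, 1.0, mat, pat)
    assert res[1] == (None, None)


def test_split_abxcd_recoding():
    rec = MarkerRecord("X", "abxcd", ["ac", "ad", "bc", "bd", MISSING])
    mat, pat = pi.split_biparental(rec)
    assert mat.marker_id == "X_m" and mat.seg_code == "lmxll"
    assert pat.marker_id == "X_p" and pat.seg_code == "nnxnp"
    assert mat.calls == ["ll", "ll", "lm", "lm", MISSING]
    assert pat.calls == ["nn", "np", "nn", "np", MISSING]


def test_split_hk_cardinality():
    rec = MarkerRecord("X", "hkxhk", ["hh", "hk", "kk"])
    resolved = [("h", "h"), ("h", "k"), ("k", "k")]
    mat, pat = pi.split_biparental(rec, resolved)
    assert len(mat.calls) == len(pat.calls) == 3
    assert MISSING not in mat.calls


def test_split_hk_requires_resolution():
    rec = MarkerRecord("X", "hkxhk", ["hk"])
    with pytest.raises(ValueError):
        pi.split_biparental(rec)


def test_split_markers_recover_true_linkage(biparental_pop):
    """Split biparental markers sit at their true positions: two-point r to a
    neighboring uniparental marker matches the map expectation."""
    from sibmap import linkmap as lm

    sim = biparental_pop
    meta = {m["id"]: m for m in sim.marker_meta}
    table = sim.table
    ab = next(r for r in table if r.seg_code == "abxcd")
    mat_split, _ = pi.split_biparental(ab)
    uni = min(
        (r for r in table if r.seg_code == "lmxll"),
        key=lambda r: abs(meta[r.marker_id]["cm"] - meta[ab.marker_id]["cm"]),
    )
    lut = {"ll": 0, "lm": 1, MISSING: -1}
    est = lm.twopoint(
        np.array([lut[c] for c in mat_split.calls], dtype=np.int8),
        np.array([lut[c] for c in uni.calls], dtype=np.int8),
    )
    d = abs(meta[ab.marker_id]["cm"] - meta[uni.marker_id]["cm"])
    r_true = (1 - np.exp(-2 * d / 100)) / 2
    se = np.sqrt(max(r_true, 0.005) * (1 - r_true) / est.n_informative)
    assert abs(est.rhat - r_true) < 4 * se + 1e-9
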