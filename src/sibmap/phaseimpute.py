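"""Phase assignment, linkage-informed imputation, hk resolution and
biparental marker splitting.

Phase is propagated along an ordered LG (first marker anchored to A) by
choosing, for each marker, the orientation predominantly in coupling with
its predecessor.  Imputation is first-order Markov: a missing phase is
filled from its two nearest informative flanks via interval recombination
probabilities (Kosambi r from map distances) and accepted only when the
posterior for one phase reaches ``posterior_min``.  Observed entries are
never overwritten.
"""

from __future__ import annotations

import logging

import numpy as np

from sibmap.codes import MISSING, PARENT_ALLELES, TRANSMISSION, UNIPARENTAL_ALLELE_INDEX
from sibmap.linkmap import kosambi_r
from sibmap.pipeline_io import GeneticMap, GenotypeTable, MarkerRecord, PhasedLG

log = logging.getLogger("sibmap")


# ---------------------------------------------------------------------------
# phase assignment
# ---------------------------------------------------------------------------


def assign_phase(
    gmap: GeneticMap,
    table: GenotypeTable,
    parent: str,
    lg: str | None = None,
) -> dict[str, PhasedLG]:
    """Phase the uniparental markers of *parent* along each LG of *gmap*.

    Returns one :class:`PhasedLG` per LG.  Markers equally coupled and
    repulsed to their anchor are flagged ambiguous and left unphased
    (all-missing column), so downstream stages skip them.
    """
    want = "lmxll" if parent == "maternal" else "nnxnp"
    lut = UNIPARENTAL_ALLELE_INDEX[want]
    by_id = {rec.marker_id: rec for rec in table if rec.seg_code == want}
    out: dict[str, PhasedLG] = {}
    for lg_name in gmap.lgs():
        if lg is not None and lg_name != lg:
            continue
        ids = [m for m in gmap.lg_markers(lg_name) if m in by_id]
        if not ids:
            continue
        pos_of = {r[1]: r[2] for r in gmap.lg_rows(lg_name)}
        positions = np.array([pos_of[m] for m in ids])
        raw = np.array(
            [[lut.get(c, -1) if c != MISSING else -1 for c in by_id[m].calls] for m in ids],
            dtype=np.int8,
        )
        phases = np.full_like(raw, -1)
        prev = None  # last successfully phased column
        for k in range(len(ids)):
            col = raw[k]
            if prev is None:
                phases[k] = col  # anchored: allele index 0 == phase A
                if (col >= 0).any():
                    prev = k
                continue
            ok = (col >= 0) & (phases[prev] >= 0)
            n = int(ok.sum())
            if n == 0:
                log.warning("marker %s has no overlap with anchor; left unphased", ids[k])
                continue
            mism = int((col[ok] != phases[prev][ok]).sum())
            if 2 * mism == n:
                log.warning("marker %s ambiguous phase (50%% mismatch); excluded", ids[k])
                continue
            flip = mism > n - mism
            phases[k] = np.where(col >= 0, col ^ int(flip), -1)
            prev = k
        out[lg_name] = PhasedLG(lg_name, ids, positions, phases.T, list(table.progeny))
    return out


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def _flank_posterior(
    row: np.ndarray, positions: np.ndarray, j: int, left_of: np.ndarray, right_of: np.ndarray
) -> float:
    """P(phase A at column j) from nearest non-missing flanks of one progeny row."""
    lik = np.ones(2)
    informative = False
    li = left_of[j]
    if li >= 0:
        r = kosambi_r(positions[j] - positions[li])
        obs = row[li]
        lik *= np.array([1 - r, r]) if obs == 0 else np.array([r, 1 - r])
        informative = True
    ri = right_of[j]
    if ri >= 0:
        r = kosambi_r(positions[ri] - positions[j])
        obs = row[ri]
        lik *= np.array([1 - r, r]) if obs == 0 else np.array([r, 1 - r])
        informative = True
    if not informative:
        return 0.5
    return float(lik[0] / lik.sum())


def _flank_indices(row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each column, index of nearest non-missing column strictly left/right."""
    m = len(row)
    left = np.full(m, -1, dtype=int)
    last = -1
    for j in range(m):
        left[j] = last
        if row[j] >= 0:
            last = j
    right = np.full(m, -1, dtype=int)
    nxt = -1
    for j in range(m - 1, -1, -1):
        right[j] = nxt
        if row[j] >= 0:
            nxt = j
    return left, right


def posterior_phase_a(phased: PhasedLG, cm: float) -> np.ndarray:
    """Per-progeny P(phase A) at an arbitrary position, from flanking markers."""
    positions = np.append(phased.positions, cm)
    order = np.argsort(positions, kind="stable")
    j = int(np.where(order == phased.n_markers)[0][0])
    out = np.empty(phased.n_progeny)
    for i in range(phased.n_progeny):
        row = np.append(phased.phases[i], -1)[order]
        left_of, right_of = _flank_indices(row)
        out[i] = _flank_posterior(row, positions[order], j, left_of, right_of)
    return out


def impute_missing(phased: PhasedLG, posterior_min: float = 0.95) -> PhasedLG:
    """Fill missing phases whose flank posterior reaches *posterior_min*.

    Monotone: observed entries are untouched and missingness only decreases.
    """
    out = phased.copy()
    for i in range(out.n_progeny):
        row = phased.phases[i]
        if (row >= 0).all():
            continue
        left_of, right_of = _flank_indices(row)
        for j in np.nonzero(row < 0)[0]:
            p_a = _flank_posterior(row, phased.positions, j, left_of, right_of)
            if p_a >= posterior_min:
                out.phases[i, j] = 0
            elif 1 - p_a >= posterior_min:
                out.phases[i, j] = 1
    return out


# ---------------------------------------------------------------------------
# hk resolution and biparental splitting
# ---------------------------------------------------------------------------


def _orient(calls: list[str], hom_allele_of: dict[str, str], post_a: np.ndarray,
            alleles: tuple[str, str]) -> int:
    """Pick the phase orientation (0: phase A carries alleles[0]) that best
    matches the homozygous progeny calls."""
    votes = 0
    n = 0
    for i, call in enumerate(calls):
        allele = hom_allele_of.get(call)
        if allele is None:
            continue
        n += 1
        expect_a = allele == alleles[0]  # orientation 0 predicts phase A
        p = post_a[i] if expect_a else 1 - post_a[i]
        votes += 1 if p >= 0.5 else -1
    return 0 if votes >= 0 else 1


def resolve_hk(
    record: MarkerRecord,
    cm_maternal: float,
    cm_paternal: float,
    maternal_phased: PhasedLG,
    paternal_phased: PhasedLG,
    posterior_min: float = 0.95,
) -> list[tuple[str | None, str | None]]:
    """Assign parental origin to the alleles of an ``hkxhk`` marker.

    ``hh``/``kk`` calls resolve trivially.  For ``hk`` calls the two origin
    assignments (maternal h / paternal k and the reverse) are scored by the
    product of each parent's flanking phase posteriors; the winner is kept
    only when its normalized posterior reaches *posterior_min*, otherwise
    the call stays missing.
    """
    if record.seg_code != "hkxhk":
        raise ValueError("resolve_hk expects an hkxhk record")
    post_m = posterior_phase_a(maternal_phased, cm_maternal)
    post_p = posterior_phase_a(paternal_phased, cm_paternal)
    hom = {"hh": "h", "kk": "k"}
    o_m = _orient(record.calls, hom, post_m, ("h", "k"))
    o_p = _orient(record.calls, hom, post_p, ("h", "k"))

    def p_allele(post_a: float, orient: int, allele: str) -> float:
        p_first = post_a if orient == 0 else 1 - post_a
        return p_first if allele == "h" else 1 - p_first

    out: list[tuple[str | None, str | None]] = []
    for i, call in enumerate(record.calls):
        if call == MISSING:
            out.append((None, None))
        elif call in hom:
            out.append((hom[call], hom[call]))
        else:  # hk: maternal h & paternal k, or maternal k & paternal h
            p1 = p_allele(post_m[i], o_m, "h") * p_allele(post_p[i], o_p, "k")
            p2 = p_allele(post_m[i], o_m, "k") * p_allele(post_p[i], o_p, "h")
            tot = p1 + p2
            if tot > 0 and p1 / tot >= posterior_min:
                out.append(("h", "k"))
            elif tot > 0 and p2 / tot >= posterior_min:
                out.append(("k", "h"))
            else:
                out.append((None, None))
    return out


def split_biparental(
    record: MarkerRecord,
    resolved: list[tuple[str | None, str | None]] | None = None,
) -> tuple[MarkerRecord, MarkerRecord]:
    """Split a biparental marker into maternal lmxll and paternal nnxnp markers.

    ``efxeg`` and ``abxcd`` markers resolve directly from their calls;
    ``hkxhk`` markers need the *resolved* origin list from :func:`resolve_hk`.
    Marker ids are suffixed ``_m`` / ``_p``.
    """
    if record.seg_code == "hkxhk" and resolved is None:
        raise ValueError("hkxhk split requires resolved parental origins")
    mat_alleles, pat_alleles = PARENT_ALLELES[record.seg_code]
    mat_lut = {mat_alleles[0]: "ll", mat_alleles[1]: "lm"}
    pat_lut = {pat_alleles[0]: "nn", pat_alleles[1]: "np"}
    mat_calls, pat_calls = [], []
    trans = TRANSMISSION.get(record.seg_code, {})
    for i, call in enumerate(record.calls):
        pair: tuple[str | None, str | None]
        if call == MISSING:
            pair = (None, None)
        elif record.seg_code == "hkxhk" and call == "hk":
            pair = resolved[i] if resolved is not None else (None, None)
        else:
            pair = trans[call]
        mat_calls.append(mat_lut[pair[0]] if pair[0] is not None else MISSING)
        pat_calls.append(pat_lut[pair[1]] if pair[1] is not None else MISSING)
    return (
        MarkerRecord(record.marker_id + "_m", "lmxll", mat_calls, lg=record.lg),
        MarkerRecord(record.marker_id + "_p", "nnxnp", pat_calls, lg=record.lg),
    )
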