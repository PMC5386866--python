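"""Genome characterization: segregation-distortion scan and SDR calling,
RF_M centromere placement, map collinearity, maternal/paternal
recombination comparison and pedigree coancestry.

The chi-square scan tests transmitted-allele counts against 1:1 with one
degree of freedom for every marker type.  RF_M is the proportion of
offspring whose gametic phase at marker m_n differs from a terminal
marker m_0; the bidirectional curves intersect near the centromere of a
metacentric chromosome when pericentromeric recombination is suppressed,
and each span extends outward from the intersection to the first marker
with RF_M >= 0.45 in both directions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from sibmap.codes import MISSING, UNIPARENTAL_ALLELE_INDEX
from sibmap.pipeline_io import GeneticMap, MarkerRecord, PhasedLG

log = logging.getLogger("sibmap")


# ---------------------------------------------------------------------------
# segregation distortion
# ---------------------------------------------------------------------------


def _allele_counts(record: MarkerRecord, parent: str) -> tuple[int, int] | None:
    """Transmitted-allele counts (allele0, allele1) of one parent, or None
    when the code does not expose that parent's transmissions unambiguously."""
    seg = record.seg_code
    if seg in UNIPARENTAL_ALLELE_INDEX:
        if (seg == "lmxll") != (parent == "maternal"):
            return None
        lut = UNIPARENTAL_ALLELE_INDEX[seg]
        c0 = sum(1 for c in record.calls if c != MISSING and lut[c] == 0)
        c1 = sum(1 for c in record.calls if c != MISSING and lut[c] == 1)
        return c0, c1
    if seg == "hkxhk":
        # h and k transmissions pooled over both parents (hk origin ambiguous)
        h = sum(2 if c == "hh" else (1 if c == "hk" else 0) for c in record.calls)
        k = sum(2 if c == "kk" else (1 if c == "hk" else 0) for c in record.calls)
        return (h, k)
    if seg == "efxeg":
        if parent == "maternal":
            e = sum(1 for c in record.calls if c in ("ee", "eg"))
            f = sum(1 for c in record.calls if c in ("ef", "fg"))
            return e, f
        e = sum(1 for c in record.calls if c in ("ee", "ef"))
        g = sum(1 for c in record.calls if c in ("eg", "fg"))
        return e, g
    if seg == "abxcd":
        if parent == "maternal":
            return (
                sum(1 for c in record.calls if c in ("ac", "ad")),
                sum(1 for c in record.calls if c in ("bc", "bd")),
            )
        return (
            sum(1 for c in record.calls if c in ("ac", "bc")),
            sum(1 for c in record.calls if c in ("ad", "bd")),
        )
    raise ValueError(seg)


def sd_chi2(record: MarkerRecord, parent: str | None = None) -> tuple[float, float] | None:
    """1-df chi-square of transmitted-allele counts against 1:1.

    For biparental markers with *parent* unset the more significant of the
    two per-parent tests is returned (pooled alleles for ``hkxhk``).
    Returns None when no informative calls exist (marker skipped).
    """
    parents = [parent] if parent else ["maternal", "paternal"]
    best: tuple[float, float] | None = None
    for par in parents:
        counts = _allele_counts(record, par)
        if counts is None:
            continue
        n = counts[0] + counts[1]
        if n == 0:
            continue
        exp = n / 2.0
        chi2 = (counts[0] - exp) ** 2 / exp + (counts[1] - exp) ** 2 / exp
        p = float(stats.chi2.sf(chi2, df=1))
        if best is None or p < best[1]:
            best = (float(chi2), p)
    return best


@dataclass
class SDScan:
    marker_ids: list[str]
    positions: np.ndarray
    chi2: np.ndarray
    pvalues: np.ndarray
    alpha: float = 0.1

    @property
    def distorted(self) -> np.ndarray:
        return self.pvalues < self.alpha


def sd_scan(
    records: list[MarkerRecord], gmap: GeneticMap, lg: str, alpha: float = 0.1,
    parent: str | None = None,
) -> SDScan:
    """Chi-square scan along one LG of a map."""
    by_id = {r.marker_id: r for r in records}
    ids, pos, chi, pv = [], [], [], []
    pos_of = {r[1]: r[2] for r in gmap.lg_rows(lg)}
    for m in gmap.lg_markers(lg):
        rec = by_id.get(m)
        if rec is None:
            continue
        res = sd_chi2(rec, parent)
        if res is None:
            log.warning("marker %s: no informative calls; skipped in SD scan", m)
            continue
        ids.append(m)
        pos.append(pos_of[m])
        chi.append(res[0])
        pv.append(res[1])
    return SDScan(ids, np.array(pos), np.array(chi), np.array(pv), alpha)


def find_sdrs(
    scan: SDScan, min_run: int = 5, max_gap_cm: float = 5.0
) -> list[tuple[float, float]]:
    """Maximal runs of >= min_run consecutive distorted markers with
    inter-marker gaps <= max_gap_cm, as (start cM, end cM) intervals."""
    flags = scan.distorted
    out: list[tuple[float, float]] = []
    i = 0
    n = len(flags)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and flags[j + 1]
            and scan.positions[j + 1] - scan.positions[j] <= max_gap_cm
        ):
            j += 1
        if j - i + 1 >= min_run:
            out.append((float(scan.positions[i]), float(scan.positions[j])))
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# RF_M profiles and centromere spans
# ---------------------------------------------------------------------------


@dataclass
class RFProfile:
    lg: str
    marker_ids: list[str]
    positions: np.ndarray
    rf_from_start: np.ndarray  # nan at the anchor itself
    rf_from_end: np.ndarray
    n_informative_start: np.ndarray = field(default_factory=lambda: np.array([]))
    n_informative_end: np.ndarray = field(default_factory=lambda: np.array([]))


def _rf_against(phases: np.ndarray, anchor: int) -> tuple[np.ndarray, np.ndarray]:
    ref = phases[:, anchor]
    ok = (ref[:, None] >= 0) & (phases >= 0)
    n = ok.sum(axis=0).astype(float)
    diff = ((phases != ref[:, None]) & ok).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rf = np.where(n > 0, diff / np.maximum(n, 1), np.nan)
    rf[anchor] = np.nan
    return rf, n


def rf_profile(phased: PhasedLG, max_anchor_missing: float = 0.5) -> RFProfile:
    """Bidirectional RF_M curves from both terminal markers.

    A terminal marker with more than *max_anchor_missing* missing calls is
    replaced by the next marker inward (logged).
    """
    if phased.n_markers < 3:
        raise ValueError("rf_profile needs at least 3 markers")
    missing_frac = (phased.phases < 0).mean(axis=0)
    start = 0
    while start < phased.n_markers - 1 and missing_frac[start] > max_anchor_missing:
        log.warning("%s: terminal marker %s >50%% missing; anchoring at next marker",
                    phased.lg, phased.marker_ids[start])
        start += 1
    end = phased.n_markers - 1
    while end > 0 and missing_frac[end] > max_anchor_missing:
        log.warning("%s: terminal marker %s >50%% missing; anchoring at previous marker",
                    phased.lg, phased.marker_ids[end])
        end -= 1
    rf_s, n_s = _rf_against(phased.phases, start)
    rf_e, n_e = _rf_against(phased.phases, end)
    return RFProfile(phased.lg, list(phased.marker_ids), phased.positions.copy(),
                     rf_s, rf_e, n_s, n_e)


@dataclass
class CentromereSpan:
    lg: str
    span_start: float | None
    span_end: float | None
    intersection: float | None
    classification: str  # metacentric | acrocentric | undetermined


def centromere_span(
    profile: RFProfile,
    rf_threshold: float = 0.45,
    central_fraction: float = 0.6,
) -> CentromereSpan:
    """Centromere span from the crossing of the two RF_M curves.

    The intersection is where the linearly interpolated curves first cross;
    the span extends outward to the first marker with directional RF_M >=
    *rf_threshold* on each side.  A missing boundary truncates the span at
    the LG end and the LG is classified undetermined; otherwise the LG is
    metacentric when the intersection lies within the central
    *central_fraction* of the LG, else acrocentric.
    """
    pos = profile.positions
    s, e = profile.rf_from_start, profile.rf_from_end
    interior = np.nonzero(~(np.isnan(s) | np.isnan(e)))[0]
    if len(interior) == 0:
        return CentromereSpan(profile.lg, None, None, None, "undetermined")
    # intersection is located on monotone (isotonic) fits of the two curves,
    # which keeps the crossing stable when sampling noise makes the raw
    # curves wiggle around each other near the recombination-poor plateau;
    # the 0.45 span rule below still uses the raw per-marker values
    from scipy.optimize import isotonic_regression

    w_s = profile.n_informative_start[interior] if len(profile.n_informative_start) else None
    w_e = profile.n_informative_end[interior] if len(profile.n_informative_end) else None
    s_fit = isotonic_regression(s[interior], weights=w_s, increasing=True).x
    e_fit = isotonic_regression(e[interior], weights=w_e, increasing=False).x
    d = s_fit - e_fit
    inter_x: float | None = None
    zero = np.isclose(d, 0.0, atol=1e-12)
    if zero.any():
        # midpoint of the first zero run of the monotone difference curve
        run = np.nonzero(zero)[0]
        stop = run[0]
        while stop + 1 < len(d) and zero[stop + 1]:
            stop += 1
        inter_x = float((pos[interior[run[0]]] + pos[interior[stop]]) / 2.0)
    elif d[0] > 0:
        inter_x = float(pos[interior[0]])
        log.info("%s: curves cross before the first interior marker", profile.lg)
    else:
        above = np.nonzero(d > 0)[0]
        if len(above):
            b = int(above[0])
            a = b - 1
            xa, xb = pos[interior[a]], pos[interior[b]]
            inter_x = float(xa + (xb - xa) * (-d[a]) / (d[b] - d[a]))
    if inter_x is None:
        log.info("%s: RF_M curves never cross; centromere undetermined", profile.lg)
        return CentromereSpan(profile.lg, None, None, None, "undetermined")

    # refine by a weighted local-linear fit of the raw difference curve
    # around the isotonic crossing; the raw first-crossing alone is unstable
    # at realistic population sizes
    raw_d = s[interior] - e[interior]
    x_all = pos[interior]
    near = np.abs(x_all - inter_x) <= 15.0
    if near.sum() >= 6:
        xs, ys = x_all[near], raw_d[near]
        coeffs = np.polyfit(xs, ys, 1)
        if coeffs[0] > 1e-6:
            x_lin = -coeffs[1] / coeffs[0]
            inter_x = float(np.clip(x_lin, inter_x - 10.0, inter_x + 10.0))

    span_start = span_end = None
    left = np.nonzero((pos <= inter_x) & (e >= rf_threshold))[0]
    if len(left):
        span_start = float(pos[left[-1]])
    right = np.nonzero((pos >= inter_x) & (s >= rf_threshold))[0]
    if len(right):
        span_end = float(pos[right[0]])

    lo, hi = float(pos.min()), float(pos.max())
    if span_start is None or span_end is None:
        return CentromereSpan(
            profile.lg,
            span_start if span_start is not None else lo,
            span_end if span_end is not None else hi,
            inter_x,
            "undetermined",
        )
    length = hi - lo
    margin = (1.0 - central_fraction) / 2.0
    central = (lo + margin * length, hi - margin * length)
    cls = "metacentric" if central[0] <= inter_x <= central[1] else "acrocentric"
    return CentromereSpan(profile.lg, span_start, span_end, inter_x, cls)


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------


def collinearity_lg(
    pos_a: dict[str, float], pos_b: dict[str, float]
) -> tuple[float, int] | None:
    """Spearman rho (orientation-aligned) and shared-marker count, or None
    when fewer than 2 shared markers exist."""
    shared = sorted(set(pos_a) & set(pos_b))
    if len(shared) < 2:
        return None
    a = np.array([pos_a[m] for m in shared])
    b = np.array([pos_b[m] for m in shared])
    rho = stats.spearmanr(a, b).statistic
    if np.isnan(rho):  # all-tied degenerate input
        rho = 1.0
    if rho < 0:
        log.info("orientation flip applied in collinearity comparison")
        rho = -rho
    return float(rho), len(shared)


def collinearity(map_a: GeneticMap, map_b: GeneticMap) -> dict[tuple[str, str], tuple[float, int]]:
    """Per-LG-pair Spearman rho + shared counts; LGs paired by majority
    shared markers."""
    pos_b_all: dict[str, tuple[str, float]] = map_b.position_of()
    out: dict[tuple[str, str], tuple[float, int]] = {}
    for lg_a in map_a.lgs():
        counts: dict[str, int] = {}
        for m in map_a.lg_markers(lg_a):
            hit = pos_b_all.get(m)
            if hit:
                counts[hit[0]] = counts.get(hit[0], 0) + 1
        if not counts:
            continue
        lg_b = max(sorted(counts), key=lambda k: counts[k])
        pos_a = {r[1]: r[2] for r in map_a.lg_rows(lg_a)}
        pos_b = {r[1]: r[2] for r in map_b.lg_rows(lg_b)}
        res = collinearity_lg(pos_a, pos_b)
        if res is None:
            log.warning("LG pair %s/%s has <2 shared markers; NA", lg_a, lg_b)
            continue
        out[(lg_a, lg_b)] = res
    return out


# ---------------------------------------------------------------------------
# maternal vs paternal recombination
# ---------------------------------------------------------------------------


@dataclass
class PairedCompareResult:
    mean_difference: float
    t_statistic: float
    p_value: float
    n_pairs: int
    fraction_maternal_ge: float


def maternal_paternal_compare(
    maternal_means, paternal_means
) -> PairedCompareResult:
    """Paired two-sided t-test of per-LG mean recombination events.

    Zero-variance nonzero differences degenerate to t = +/-inf, P = 0.
    """
    a = np.asarray(maternal_means, dtype=float)
    b = np.asarray(paternal_means, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 maternal/paternal LG pairs")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd <= 1e-12 * max(1.0, abs(mean)):
        sd = 0.0
    if sd == 0:
        t = 0.0 if mean == 0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0 else 0.0
    else:
        t = mean / (sd / math.sqrt(n))
        p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return PairedCompareResult(float(mean), float(t), p, n, float((d >= 0).mean()))


# ---------------------------------------------------------------------------
# coancestry
# ---------------------------------------------------------------------------


class PedigreeError(ValueError):
    pass


def coancestry(
    pedigree: dict[str, tuple[str | None, str | None]], id_a: str, id_b: str
) -> float:
    """Kinship coefficient by the standard recursion.

    f(x, x) = 0.5 (1 + f(sire, dam)); f(x, y) = 0.5 (f(sire_x, y) +
    f(dam_x, y)) recursing on the younger (descendant-side) individual.
    Distinct founders are unrelated and non-inbred; a missing parent is an
    unknown founder.
    """
    depth_memo: dict[str, int] = {}

    def depth(x: str | None, stack: frozenset = frozenset()) -> int:
        if x is None or x not in pedigree:
            return 0
        if x in stack:
            raise PedigreeError(f"pedigree cycle at {x}")
        if x not in depth_memo:
            s, d = pedigree[x]
            depth_memo[x] = 1 + max(depth(s, stack | {x}), depth(d, stack | {x}))
        return depth_memo[x]

    memo: dict[tuple[str, str], float] = {}

    def f(x: str | None, y: str | None) -> float:
        if x is None or y is None:
            return 0.0
        key = (x, y) if x <= y else (y, x)
        if key in memo:
            return memo[key]
        sx = pedigree.get(x, (None, None))
        sy = pedigree.get(y, (None, None))
        if x == y:
            val = 0.5 * (1.0 + f(sx[0], sx[1]))
        else:
            # recurse on the individual with greater pedigree depth so the
            # partner is never its descendant
            if depth(x) >= depth(y):
                val = 0.5 * (f(sx[0], y) + f(sx[1], y))
            else:
                val = 0.5 * (f(x, sy[0]) + f(x, sy[1]))
        memo[key] = val
        return val

    for ind in pedigree:
        depth(ind)  # cycle check up front
    return f(id_a, id_b)
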