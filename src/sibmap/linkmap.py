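"""Pseudo-testcross linkage mapping: two-point estimation, LOD grouping,
marker ordering, Kosambi/regression distances and iterative cleaning.

One map is built per parent per population from the markers informative
for that parent (uniparental markers, plus split biparental markers once
phaseimpute has resolved them).  Ordering minimizes the sum of adjacent
recombination fractions (SARF) with a minimum-spanning-tree seriation
seed polished by deterministic 2-opt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from sibmap import codes
from sibmap.codes import MISSING
from sibmap.pipeline_io import GeneticMap, GenotypeTable, ValidationError

log = logging.getLogger("sibmap")

_LOG10_2 = np.log10(2.0)


class LinkageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# call matrices
# ---------------------------------------------------------------------------


def transmission_matrix(table: GenotypeTable, parent: str) -> tuple[list[str], np.ndarray]:
    """Allele-index matrix (markers x progeny, int8, -1 missing) for the
    uniparental markers of *parent*."""
    want = "lmxll" if parent == "maternal" else "nnxnp"
    ids, rows = [], []
    lut = codes.UNIPARENTAL_ALLELE_INDEX[want]
    for rec in table:
        if rec.seg_code != want:
            continue
        ids.append(rec.marker_id)
        rows.append([lut.get(c, -1) if c != MISSING else -1 for c in rec.calls])
    return ids, np.array(rows, dtype=np.int8).reshape(len(ids), -1)


# ---------------------------------------------------------------------------
# two-point estimation
# ---------------------------------------------------------------------------


@dataclass
class TwoPointEstimate:
    marker_a: str
    marker_b: str
    rhat: float
    lod: float
    n_informative: int
    flipped: bool  # True when the repulsion phase assignment minimized r


def _lod(r: float, n: int, n_rec: int) -> float:
    if n == 0:
        return 0.0
    if r <= 0.0:
        return 0.0 if n_rec > 0 else n * _LOG10_2
    if r >= 0.5:
        return 0.0
    return n_rec * np.log10(r) + (n - n_rec) * np.log10(1.0 - r) + n * _LOG10_2


def twopoint(
    calls_a: np.ndarray, calls_b: np.ndarray, marker_a: str = "A", marker_b: str = "B"
) -> TwoPointEstimate:
    """Two-point r/LOD for a uniparental marker pair.

    Phase is resolved per pair by taking the assignment (coupling or
    repulsion) that minimizes the recombinant count, capping r at 0.5.
    """
    a = np.asarray(calls_a, dtype=np.int8)
    b = np.asarray(calls_b, dtype=np.int8)
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        raise LinkageError(f"no informative progeny for pair {marker_a}/{marker_b}")
    diff = int((a[ok] != b[ok]).sum())
    n_rec = min(diff, n - diff)
    r = min(n_rec / n, 0.5)
    return TwoPointEstimate(marker_a, marker_b, r, float(_lod(r, n, n_rec)), n, diff > n - diff)


def pairwise_estimates(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized all-pairs (rhat, lod, n_informative) for one parent's markers."""
    m = matrix.shape[0]
    obs = (matrix >= 0).astype(np.float64)
    one = np.where(matrix == 1, 1.0, 0.0)
    zer = np.where(matrix == 0, 1.0, 0.0)
    n_inf = obs @ obs.T
    diff = one @ zer.T + zer @ one.T
    with np.errstate(invalid="ignore", divide="ignore"):
        n_rec = np.minimum(diff, n_inf - diff)
        rhat = np.where(n_inf > 0, n_rec / np.maximum(n_inf, 1), np.nan)
        rhat = np.minimum(rhat, 0.5)
        lod = np.where(
            (rhat > 0) & (rhat < 0.5),
            n_rec * np.log10(np.maximum(rhat, 1e-12))
            + (n_inf - n_rec) * np.log10(np.maximum(1 - rhat, 1e-12))
            + n_inf * _LOG10_2,
            0.0,
        )
        lod = np.where((rhat == 0) & (n_inf > 0), n_inf * _LOG10_2, lod)
        lod = np.where(rhat >= 0.5, 0.0, lod)
    np.fill_diagonal(rhat, 0.0)
    np.fill_diagonal(lod, 0.0)
    return rhat, lod, n_inf.astype(int)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def group(lod: np.ndarray, lod_threshold: float = 5.0) -> list[list[int]]:
    """Connected components of the LOD > threshold graph.

    Returns groups sorted by decreasing size (ties by smallest member
    index); singletons are returned too (callers report them unplaced).
    """
    adj = csr_matrix(np.asarray(lod) > lod_threshold)
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


# ---------------------------------------------------------------------------
# Kosambi mapping function
# ---------------------------------------------------------------------------


def kosambi_d(r) -> np.ndarray | float:
    """Map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction outside [0, 0.5)")
    out = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(out) if out.ndim == 0 else out


def kosambi_r(d) -> np.ndarray | float:
    """Inverse mapping function: r = tanh(d/50)/2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    out = 0.5 * np.tanh(d / 50.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# ordering (SARF, MST seriation + 2-opt)
# ---------------------------------------------------------------------------


def _sarf(order: list[int], rhat: np.ndarray) -> float:
    return float(sum(rhat[order[i], order[i + 1]] for i in range(len(order) - 1)))


def _mst_path_seed(rhat: np.ndarray) -> list[int]:
    """Seed order: diameter path of the MST, off-path nodes inserted greedily."""
    m = rhat.shape[0]
    if m <= 2:
        return list(range(m))
    dist = np.where(np.isnan(rhat), 0.5, rhat) + 1e-9
    np.fill_diagonal(dist, 0.0)
    mst = minimum_spanning_tree(csr_matrix(dist)).toarray()
    adj: dict[int, list[int]] = {i: [] for i in range(m)}
    for i, j in zip(*np.nonzero(mst)):
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))

    def farthest(start: int) -> tuple[int, dict[int, int]]:
        parent = {start: start}
        frontier, last = [start], start
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in parent:
                        parent[v] = u
                        nxt.append(v)
                        last = v
            frontier = sorted(nxt)
        return last, parent

    a, _ = farthest(0)
    b, parent = farthest(a)
    path = [b]
    while path[-1] != a:
        path.append(parent[path[-1]])
    order = list(path)
    remaining = [i for i in range(m) if i not in set(order)]
    for node in remaining:
        best, best_cost = 0, np.inf
        for pos in range(len(order) + 1):
            left = rhat[order[pos - 1], node] if pos > 0 else 0.0
            right = rhat[node, order[pos]] if pos < len(order) else 0.0
            gap = rhat[order[pos - 1], order[pos]] if 0 < pos < len(order) else 0.0
            cost = left + right - gap
            if cost < best_cost - 1e-12:
                best_cost, best = cost, pos
        order.insert(best, node)
    return order


def _two_opt(order: list[int], rhat: np.ndarray, max_passes: int = 60) -> list[int]:
    m = len(order)
    for _ in range(max_passes):
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                # reversing order[i:j+1] changes only the two boundary edges
                before = 0.0
                after = 0.0
                if i > 0:
                    before += rhat[order[i - 1], order[i]]
                    after += rhat[order[i - 1], order[j]]
                if j < m - 1:
                    before += rhat[order[j], order[j + 1]]
                    after += rhat[order[i], order[j + 1]]
                if after < before - 1e-12:
                    order[i : j + 1] = reversed(order[i : j + 1])
                    improved = True
        if not improved:
            break
    return order


def _ext_cost(order: list[int], lo: int, hi: int, rhat: np.ndarray, lag: int = 3) -> float:
    """Lag-weighted local cost of pairs with index distance <= lag touching
    positions [lo, hi]."""
    m = len(order)
    cost = 0.0
    for i in range(max(0, lo - lag), min(hi + 1, m)):
        for k in range(1, lag + 1):
            j = i + k
            if j >= m or (j < lo and i < lo) or (i > hi and j > hi):
                continue
            r = rhat[order[i], order[j]]
            if not np.isnan(r):
                cost += r / k
    return cost


def _tie_polish(order: list[int], rhat: np.ndarray, lag: int = 3, max_passes: int = 20) -> list[int]:
    """Adjacent-swap polish breaking SARF ties with lag-weighted context.

    A swap is applied when it strictly lowers SARF, or leaves SARF unchanged
    while lowering the lag-weighted pair cost — resolving the arbitrary
    ordering of (nearly) cosegregating neighbors using more distant markers.
    """
    m = len(order)
    for _ in range(max_passes):
        changed = False
        for k in range(m - 1):
            lo, hi = k, k + 1
            sarf_before = _sarf(order[max(0, k - 1): k + 3], rhat)
            ext_before = _ext_cost(order, lo, hi, rhat, lag)
            order[k], order[k + 1] = order[k + 1], order[k]
            sarf_after = _sarf(order[max(0, k - 1): k + 3], rhat)
            ext_after = _ext_cost(order, lo, hi, rhat, lag)
            if sarf_after < sarf_before - 1e-12 or (
                abs(sarf_after - sarf_before) <= 1e-12 and ext_after < ext_before - 1e-12
            ):
                changed = True
            else:
                order[k], order[k + 1] = order[k + 1], order[k]
        if not changed:
            break
    return order


def order_markers(rhat: np.ndarray, marker_ids: list[str]) -> list[int]:
    """Order a linkage group by SARF minimization; deterministic.

    An MST-seriation seed is polished by 2-opt, then SARF ties are broken
    with a lag-weighted adjacent-swap pass.  Orientation is canonicalized so
    the lexicographically smaller terminal marker id comes first.
    """
    m = len(marker_ids)
    if m < 2:
        return list(range(m))
    if np.isnan(rhat).all():
        raise LinkageError("disconnected two-point graph within group")
    order = _tie_polish(_two_opt(_mst_path_seed(rhat), rhat), rhat)
    if marker_ids[order[-1]] < marker_ids[order[0]]:
        order = order[::-1]
    return order


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def regression_distances(
    order: list[int],
    rhat: np.ndarray,
    lod: np.ndarray,
    window: int = 3,
    n_inf: np.ndarray | None = None,
) -> np.ndarray:
    """Map positions for a fixed order by weighted least squares over
    pairwise Kosambi distances within an index window.

    Weights are inverse variances of the pairwise distance estimates,
    evaluated at the *fitted* distances (one reweighting pass), keeping the
    weights independent of the per-pair sampling noise.  Adjacent increments
    are solved directly; negatives are clamped to 0 and the first marker
    sits at 0 cM.
    """
    m = len(order)
    if m == 1:
        return np.zeros(1)
    rows, rhs, pair_n = [], [], []
    for i in range(m - 1):
        for j in range(i + 1, min(i + 1 + window, m)):
            r = rhat[order[i], order[j]]
            if np.isnan(r) or r >= 0.5:
                continue
            n = float(n_inf[order[i], order[j]]) if n_inf is not None else 1.0
            coef = np.zeros(m - 1)
            coef[i:j] = 1.0
            rows.append(coef)
            rhs.append(kosambi_d(r))
            pair_n.append(max(n, 1.0))
    if not rows:
        raise LinkageError("window too small to connect order")
    A = np.array(rows)
    d = np.array(rhs)
    n_arr = np.array(pair_n)
    touched = (A > 0).any(axis=0)
    if not touched.all():
        log.warning("regression window leaves gaps; falling back to adjacent chaining")
        inc = np.zeros(m - 1)
        for i in range(m - 1):
            r = rhat[order[i], order[i + 1]]
            inc[i] = kosambi_d(min(r, 0.499999)) if not np.isnan(r) else 0.0
        return np.concatenate([[0.0], np.cumsum(inc)])

    def solve(weights: np.ndarray) -> np.ndarray:
        w = np.sqrt(weights)
        inc, *_ = np.linalg.lstsq(A * w[:, None], d * w, rcond=None)
        return inc

    inc = solve(n_arr)  # pass 1: weight by informative count only
    # pass 2: inverse variance at fitted distances
    d_fit = np.maximum(A @ inc, 0.0)
    r_fit = np.clip(kosambi_r(d_fit), 1e-4, 0.49)
    var = (100.0 / (1.0 - 4.0 * r_fit**2)) ** 2 * r_fit * (1.0 - r_fit) / n_arr
    inc = solve(1.0 / var)
    inc = np.maximum(inc, 0.0)
    return np.concatenate([[0.0], np.cumsum(inc)])


# ---------------------------------------------------------------------------
# nearest-neighbor diagnostics and iterative cleaning
# ---------------------------------------------------------------------------


@dataclass
class CleanDiagnostics:
    marker_id: str
    nn_fit: float
    nn_stress: float
    nn_stress_cm: float


def _diagnostics(
    order: list[int],
    positions: np.ndarray,
    rhat: np.ndarray,
    marker_ids: list[str],
    flank: int = 2,
) -> list[CleanDiagnostics]:
    m = len(order)
    out = []
    for pos_idx in range(m):
        i = order[pos_idx]
        # nn_fit: triangle excess over the immediate neighbors (two-point cM)
        nn_fit = 0.0
        if 0 < pos_idx < m - 1:
            left, right = order[pos_idx - 1], order[pos_idx + 1]
            trip = [rhat[left, i], rhat[i, right], rhat[left, right]]
            if all(not np.isnan(r) and r < 0.5 for r in trip):
                nn_fit = max(0.0, kosambi_d(trip[0]) + kosambi_d(trip[1]) - kosambi_d(trip[2]))
        stresses, stresses_cm = [], []
        for off in range(1, flank + 1):
            for j_idx in (pos_idx - off, pos_idx + off):
                if not 0 <= j_idx < m or j_idx == pos_idx:
                    continue
                j = order[j_idx]
                r = rhat[i, j]
                if np.isnan(r):
                    continue
                d_map = abs(positions[pos_idx] - positions[j_idx])
                r_map = kosambi_r(d_map)
                stresses.append(abs(r - r_map))
                stresses_cm.append(abs(kosambi_d(min(r, 0.499999)) - d_map))
        out.append(
            CleanDiagnostics(
                marker_ids[i],
                nn_fit,
                float(np.mean(stresses)) if stresses else 0.0,
                float(np.mean(stresses_cm)) if stresses_cm else 0.0,
            )
        )
    return out


def clean_iterative(
    order: list[int],
    rhat: np.ndarray,
    lod: np.ndarray,
    marker_ids: list[str],
    fit_max: float = 2.0,
    stress_max: float = 0.035,
    stress_cm_max: float = 3.5,
    window: int = 3,
    n_inf: np.ndarray | None = None,
) -> tuple[list[int], np.ndarray, dict[str, str]]:
    """Iteratively drop the worst nearest-neighbor offender and re-fit.

    Returns the cleaned order, positions and a {marker: criterion} log of
    removals.
    """
    removed: dict[str, str] = {}
    order = list(order)
    while len(order) >= 2:
        positions = regression_distances(order, rhat, lod, window, n_inf)
        diags = _diagnostics(order, positions, rhat, marker_ids)
        worst, worst_score, worst_reason = None, 0.0, ""
        for diag in diags:
            score = max(
                diag.nn_fit / fit_max if fit_max > 0 else 0.0,
                diag.nn_stress / stress_max if stress_max > 0 else 0.0,
                diag.nn_stress_cm / stress_cm_max if stress_cm_max > 0 else 0.0,
            )
            if score > 1.0 and score > worst_score + 1e-12:
                worst, worst_score = diag.marker_id, score
                if diag.nn_fit > fit_max:
                    worst_reason = f"nn_fit {diag.nn_fit:.2f} > {fit_max}"
                elif diag.nn_stress > stress_max:
                    worst_reason = f"nn_stress {diag.nn_stress:.4f} > {stress_max}"
                else:
                    worst_reason = f"nn_stress_cm {diag.nn_stress_cm:.2f} > {stress_cm_max}"
        if worst is None:
            return order, positions, removed
        removed[worst] = worst_reason
        idx = marker_ids.index(worst)
        order = [i for i in order if i != idx]
        order = _two_opt(order, rhat)
    positions = (
        regression_distances(order, rhat, lod, window, n_inf)
        if len(order) > 1
        else np.zeros(len(order))
    )
    if not order:
        log.warning("clean_iterative removed all markers")
    return order, positions, removed


def _collapse_cosegregating(
    order: list[int],
    rhat: np.ndarray,
    lod: np.ndarray,
    n_inf: np.ndarray,
    window: int,
) -> np.ndarray:
    """Positions for an order where runs of cosegregating markers (adjacent
    r = 0 with informative overlap) collapse onto a single coordinate."""
    m = len(order)
    if m == 1:
        return np.zeros(1)
    cluster_of = np.zeros(m, dtype=int)
    rep_of_cluster = [0]
    for k in range(1, m):
        rep = order[rep_of_cluster[-1]]
        r = rhat[rep, order[k]]
        if (not np.isnan(r)) and r == 0.0 and n_inf[rep, order[k]] > 0:
            cluster_of[k] = cluster_of[k - 1]
        else:
            cluster_of[k] = cluster_of[k - 1] + 1
            rep_of_cluster.append(k)
    reps = [order[k] for k in rep_of_cluster]
    if len(reps) == 1:
        return np.zeros(m)
    rep_pos = regression_distances(list(range(len(reps))),
                                   rhat[np.ix_(reps, reps)],
                                   lod[np.ix_(reps, reps)],
                                   window,
                                   n_inf[np.ix_(reps, reps)])
    return rep_pos[cluster_of]


# ---------------------------------------------------------------------------
# high-level: one parent map
# ---------------------------------------------------------------------------


def map_parent(
    table: GenotypeTable,
    parent: str,
    lod_threshold: float = 5.0,
    fit_max: float = 2.0,
    stress_max: float = 0.035,
    stress_cm_max: float = 3.5,
    window: int = 3,
    min_group_size: int = 2,
) -> tuple[GeneticMap, dict]:
    """Build one parental map from uniparental markers.

    Returns the map plus a diagnostics dict (groups, unplaced singletons,
    removed markers).
    """
    ids, matrix = transmission_matrix(table, parent)
    if not ids:
        raise LinkageError(f"no uniparental markers for {parent}")
    rhat, lod, n_inf = pairwise_estimates(matrix)
    # pairs with zero informative progeny are excluded from grouping
    lod = np.where(n_inf > 0, lod, 0.0)
    groups = group(lod, lod_threshold)
    rows: list[tuple] = []
    info: dict = {"unplaced": [], "removed": {}, "n_groups": 0}
    lg_no = 0
    for members in groups:
        if len(members) < min_group_size:
            info["unplaced"].extend(ids[i] for i in members)
            continue
        lg_no += 1
        lg = f"LG{lg_no}"
        sub = np.ix_(members, members)
        sub_ids = [ids[i] for i in members]
        order = order_markers(rhat[sub], sub_ids)
        order, positions, removed = clean_iterative(
            order, rhat[sub], lod[sub], sub_ids,
            fit_max=fit_max, stress_max=stress_max, stress_cm_max=stress_cm_max,
            window=window, n_inf=n_inf[sub],
        )
        info["removed"].update({m: f"{lg}: {why}" for m, why in removed.items()})
        # cosegregating neighbors (r = 0) share one exact position: solve
        # distances over cluster representatives and broadcast
        positions = _collapse_cosegregating(order, rhat[sub], lod[sub], n_inf[sub], window)
        for pos_idx, i in enumerate(order):
            rows.append((lg, sub_ids[i], float(positions[pos_idx])))
    info["n_groups"] = lg_no
    if not rows:
        raise LinkageError("no linkage groups retained")
    return GeneticMap(rows), info
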