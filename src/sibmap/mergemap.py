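"""Composite-map construction: linear programming on marker intervals.

Component parental maps are merged per consensus LG by minimizing the mean
absolute error between marker intervals in the component maps and the
composite, subject to the (conflict-resolved) marker order constraints.
The maximum interval size ``k`` is swept from 1 to ``k_max`` and the value
minimizing the mean per-component RMSE is kept per LG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from sibmap.pipeline_io import GeneticMap

log = logging.getLogger("sibmap")


class MergeError(ValueError):
    pass


@dataclass
class IntervalDatum:
    u: str
    v: str  # v follows u in the source map
    distance: float
    source: int  # component map index


@dataclass
class LGMergeDiagnostics:
    lg: str
    k: int
    rmse: dict[int, float]
    deletions: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class CompositeMap:
    map: GeneticMap
    diagnostics: list[LGMergeDiagnostics]
    sources: dict[str, list[int]]  # marker -> component map indices containing it

    def to_json_dict(self) -> dict:
        return {
            "lgs": [
                {
                    "lg": d.lg,
                    "k": d.k,
                    "rmse": {str(c): round(v, 6) for c, v in d.rmse.items()},
                    "deleted_constraints": [list(t) for t in d.deletions],
                }
                for d in self.diagnostics
            ]
        }


# ---------------------------------------------------------------------------
# consensus LG assignment
# ---------------------------------------------------------------------------


def assign_consensus_lgs(maps: list[GeneticMap]) -> list[list[tuple[int, str]]]:
    """Group component LGs sharing markers into consensus LGs.

    Connected components of the shared-marker graph over (map index, lg)
    nodes; a component LG bridging two groups follows the majority of its
    shared markers.  Groups are ordered by total marker count (descending).
    """
    g = nx.Graph()
    marker_home: dict[str, list[tuple[int, str]]] = {}
    for ci, gm in enumerate(maps):
        for lg in gm.lgs():
            g.add_node((ci, lg))
            for m in gm.lg_markers(lg):
                marker_home.setdefault(m, []).append((ci, lg))
    for homes in marker_home.values():
        for a, b in zip(homes, homes[1:]):
            if g.has_edge(a, b):
                g[a][b]["w"] += 1
            else:
                g.add_edge(a, b, w=1)
    comps = [sorted(c) for c in nx.connected_components(g)]

    # stable numbering: follow the first component map's LG order, then others
    lg_rank = {
        (ci, lg): (ci, li)
        for ci, gm in enumerate(maps)
        for li, lg in enumerate(gm.lgs())
    }
    comps.sort(key=lambda c: min(lg_rank[node] for node in c))
    if all(len(c) == 1 for c in comps) and len(maps) > 1:
        raise MergeError("cannot anchor LG: no shared markers across components")
    return comps


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------


def build_constraints(
    component_lgs: list[tuple[list[str], np.ndarray]], k: int
) -> tuple[list[IntervalDatum], dict[tuple[str, str], float]]:
    """Interval data and order-arc weights for one consensus LG.

    ``component_lgs``: per component, the ordered marker list and positions.
    For each component and each marker pair separated by at most *k*
    positions, emits one interval datum and one order arc; arc weights count
    supporting components (used by conflict resolution).
    """
    if k < 1:
        raise MergeError(f"k must be >= 1, got {k}")
    data: list[IntervalDatum] = []
    arcs: dict[tuple[str, str], float] = {}
    for ci, (markers, positions) in enumerate(component_lgs):
        for i in range(len(markers)):
            for j in range(i + 1, min(i + k + 1, len(markers))):
                d = float(positions[j] - positions[i])
                data.append(IntervalDatum(markers[i], markers[j], d, ci))
                arcs[(markers[i], markers[j])] = arcs.get((markers[i], markers[j]), 0.0) + 1.0
    return data, arcs


def resolve_conflicts(
    arcs: dict[tuple[str, str], float],
    data: list[IntervalDatum],
) -> tuple[nx.DiGraph, list[tuple[str, str]]]:
    """Break order cycles by deleting minimum-weight arcs.

    Weight is the number of supporting components; ties go to the arc with
    the smaller summed supporting interval distance, then lexicographic.
    Deletions are logged and returned.
    """
    dist_support: dict[tuple[str, str], float] = {}
    for datum in data:
        key = (datum.u, datum.v)
        dist_support[key] = dist_support.get(key, 0.0) + datum.distance
    dag = nx.DiGraph()
    for (u, v), w in arcs.items():
        dag.add_edge(u, v, w=w)
    deletions: list[tuple[str, str]] = []
    while True:
        try:
            cycle = nx.find_cycle(dag)
        except nx.NetworkXNoCycle:
            break
        victim = min(
            ((u, v) for u, v, *_ in cycle),
            key=lambda e: (dag[e[0]][e[1]]["w"], dist_support.get(e, 0.0), e),
        )
        dag.remove_edge(*victim)
        deletions.append(victim)
        log.info("order conflict: deleted arc %s -> %s", *victim)
    return dag, deletions


# ---------------------------------------------------------------------------
# LP solve
# ---------------------------------------------------------------------------


def lp_solve(
    markers: list[str],
    dag: nx.DiGraph,
    data: list[IntervalDatum],
    deleted: set[tuple[str, str]] | None = None,
) -> dict[str, float]:
    """Positions minimizing mean |composite interval - component interval|.

    L1 objective via slack reformulation; among optima, a canonical solution
    is selected by a second solve minimizing the sum of positions (pushing
    the first marker to 0 and degenerate intervals to their lower ends).
    """
    deleted = deleted or set()
    idx = {m: i for i, m in enumerate(markers)}
    n = len(markers)
    data = [d for d in data if (d.u, d.v) not in deleted]
    nd = len(data)
    # variables: x (n), p (nd), q (nd); x_v - x_u + p - q = d
    c = np.concatenate([np.zeros(n), np.ones(2 * nd) / max(nd, 1)])
    rows, cols, vals = [], [], []
    rhs_eq = np.empty(nd)
    for t, datum in enumerate(data):
        rows += [t, t, t, t]
        cols += [idx[datum.v], idx[datum.u], n + t, n + nd + t]
        vals += [1.0, -1.0, 1.0, -1.0]
        rhs_eq[t] = datum.distance
    a_eq = coo_matrix((vals, (rows, cols)), shape=(nd, n + 2 * nd))
    # order constraints: x_u - x_v <= 0 for arcs u -> v
    ub_rows, ub_cols, ub_vals = [], [], []
    arcs = list(dag.edges())
    for t, (u, v) in enumerate(arcs):
        ub_rows += [t, t]
        ub_cols += [idx[u], idx[v]]
        ub_vals += [1.0, -1.0]
    a_ub = coo_matrix((ub_vals, (ub_rows, ub_cols)), shape=(len(arcs), n + 2 * nd))
    b_ub = np.zeros(len(arcs))
    res = linprog(c, A_eq=a_eq, b_eq=rhs_eq, A_ub=a_ub, b_ub=b_ub,
                  bounds=(0, None), method="highs")
    if not res.success:
        raise MergeError(f"LP infeasible/failed: {res.message}\narcs={arcs[:20]}...")
    z_star = res.fun
    # canonicalization: among optima minimize total of positions
    from scipy.sparse import vstack as sp_vstack

    c2 = np.concatenate([np.ones(n), np.zeros(2 * nd)])
    a_ub2 = sp_vstack([a_ub, coo_matrix(c.reshape(1, -1))])
    b_ub2 = np.concatenate([b_ub, [z_star + 1e-9]])
    res2 = linprog(c2, A_eq=a_eq, b_eq=rhs_eq, A_ub=a_ub2, b_ub=b_ub2,
                   bounds=(0, None), method="highs")
    if res2.success:
        x = res2.x[:n]
    else:  # pragma: no cover - canonicalization is best-effort
        x = res.x[:n]
    x = x - x.min() if n else x
    x = np.round(x, 6)  # strip canonicalization epsilon; cM precision
    return {m: float(x[idx[m]]) for m in markers}


# ---------------------------------------------------------------------------
# per-LG merge and k selection
# ---------------------------------------------------------------------------


def _consensus_order(
    positions: dict[str, float], component_lgs: list[tuple[list[str], np.ndarray]]
) -> list[str]:
    """Sort by consensus position; ties by mean normalized component rank, then id."""
    mean_rank: dict[str, float] = {}
    for markers, _pos in component_lgs:
        m = len(markers)
        for i, mk in enumerate(markers):
            r = i / max(m - 1, 1)
            mean_rank.setdefault(mk, 0.0)
            mean_rank[mk] += r
    return sorted(positions, key=lambda mk: (round(positions[mk], 9), mean_rank.get(mk, 0.0), mk))


def merge_lg(
    component_lgs: list[tuple[list[str], np.ndarray]], k: int
) -> tuple[dict[str, float], list[tuple[str, str]]]:
    """Merge one consensus LG at a fixed k; returns positions and deletions."""
    markers: list[str] = []
    for ms, _ in component_lgs:
        for m in ms:
            if m not in markers:
                markers.append(m)
    data, arcs = build_constraints(component_lgs, k)
    dag, deletions = resolve_conflicts(arcs, data)
    positions = lp_solve(markers, dag, data, deleted=set(deletions))
    return positions, deletions


def rmse_vs_components(
    positions: dict[str, float], component_lgs: list[tuple[list[str], np.ndarray]]
) -> dict[int, float]:
    out: dict[int, float] = {}
    for ci, (markers, pos) in enumerate(component_lgs):
        diffs = [positions[m] - p for m, p in zip(markers, pos) if m in positions]
        if diffs:
            out[ci] = float(np.sqrt(np.mean(np.square(diffs))))
    return out


def select_k(
    component_lgs: list[tuple[list[str], np.ndarray]],
    k_max: int = 10,
    lg: str = "LG",
) -> tuple[dict[str, float], LGMergeDiagnostics]:
    """Sweep k = 1..k_max; keep the k minimizing mean RMSE (ties: smaller k)."""
    best = None
    for k in range(1, k_max + 1):
        positions, deletions = merge_lg(component_lgs, k)
        rmse = rmse_vs_components(positions, component_lgs)
        mean_rmse = float(np.mean(list(rmse.values()))) if rmse else 0.0
        if best is None or mean_rmse < best[0] - 1e-9:
            best = (mean_rmse, k, positions, rmse, deletions)
    assert best is not None
    _, k, positions, rmse, deletions = best
    return positions, LGMergeDiagnostics(lg, k, rmse, deletions)


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------


def merge_maps(maps: list[GeneticMap], k_max: int = 10) -> CompositeMap:
    """Merge component maps into a composite map, one consensus LG at a time."""
    if not maps:
        raise MergeError("no component maps")
    groups = assign_consensus_lgs(maps)
    rows: list[tuple] = []
    diagnostics: list[LGMergeDiagnostics] = []
    sources: dict[str, list[int]] = {}
    for gi, comp in enumerate(groups, start=1):
        lg_name = f"LG{gi}"
        component_lgs = []
        for ci, lg in comp:
            markers = maps[ci].lg_markers(lg)
            component_lgs.append((markers, maps[ci].lg_positions(lg)))
            for m in markers:
                sources.setdefault(m, []).append(ci)
        positions, diag = select_k(component_lgs, k_max=k_max, lg=lg_name)
        diag.lg = lg_name
        diagnostics.append(diag)
        for m in _consensus_order(positions, component_lgs):
            rows.append((lg_name, m, positions[m]))
    return CompositeMap(GeneticMap(rows), diagnostics, sources)
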