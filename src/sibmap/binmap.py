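"""Residual genotyping-error detection, marker binning and recombination
event counting on phased data.

A bin collapses cosegregating markers (identical phase vectors over the
progeny, with missing entries wildcard-matching) to a single position, so
the bin count per LG reflects the number of distinct gamete breakpoint
classes observed in the population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from sibmap.phaseimpute import impute_missing
from sibmap.pipeline_io import PhasedLG

log = logging.getLogger("sibmap")


@dataclass
class Bin:
    bin_id: str
    members: list[str]
    representative: str
    position: float


@dataclass
class BinMapResult:
    lg: str
    bins: list[Bin]
    counts: np.ndarray  # per-progeny phase-change counts (-1: all-missing row)
    flagged: list[tuple[int, int]] = field(default_factory=list)  # (progeny, marker)

    @property
    def mean_events(self) -> float:
        ok = self.counts >= 0
        return float(self.counts[ok].mean()) if ok.any() else float("nan")


# ---------------------------------------------------------------------------
# error detection
# ---------------------------------------------------------------------------


def detect_errors(
    phased: PhasedLG, window: int = 2, reimpute: bool = True, posterior_min: float = 0.95
) -> tuple[PhasedLG, list[tuple[int, int]]]:
    """Flag singleton phase flips (double phase change within *window* on both
    sides), set them missing and optionally re-impute.

    A call is flagged when its nearest non-missing neighbors within the
    window on each side agree with each other but differ from the call.
    """
    out = phased.copy()
    flagged: list[tuple[int, int]] = []
    phases = phased.phases
    n, m = phases.shape
    for i in range(n):
        row = phases[i]
        obs = np.nonzero(row >= 0)[0]
        if len(obs) < 3:
            continue
        for j in obs:
            v = row[j]
            left = [row[l] for l in range(max(0, j - window), j) if row[l] >= 0]
            right = [row[r] for r in range(j + 1, min(m, j + window + 1)) if row[r] >= 0]
            if any(l != v and l in right for l in left):
                flagged.append((i, int(j)))
    for i, j in flagged:
        out.phases[i, j] = -1
    if reimpute and flagged:
        out = impute_missing(out, posterior_min=posterior_min)
        # a re-imputed value restoring the flagged call would be circular;
        # flanks now agree so imputation fills the consensus phase
    return out, flagged


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def make_bins(phased: PhasedLG) -> list[Bin]:
    """Greedy positional scan: a marker joins the current bin when its phase
    vector is compatible with the bin consensus (missing wildcards), else a
    new bin starts.  Deterministic in map order; representative is the
    lowest marker id."""
    bins: list[Bin] = []
    consensus: np.ndarray | None = None
    current: list[int] = []

    def flush() -> None:
        nonlocal current
        if not current:
            return
        members = sorted(phased.marker_ids[j] for j in current)
        rep = members[0]
        rep_pos = phased.positions[phased.marker_ids.index(rep)]
        bins.append(Bin(f"{phased.lg}.{len(bins) + 1}", members, rep, float(rep_pos)))
        current = []

    for j in range(phased.n_markers):
        col = phased.phases[:, j]
        if consensus is None:
            consensus = col.copy()
            current = [j]
            continue
        both = (consensus >= 0) & (col >= 0)
        if np.array_equal(consensus[both], col[both]):
            current.append(j)
            consensus = np.where(consensus >= 0, consensus, col)
        else:
            flush()
            consensus = col.copy()
            current = [j]
    flush()
    return bins


# ---------------------------------------------------------------------------
# recombination counting
# ---------------------------------------------------------------------------


def count_recombinations(phased: PhasedLG) -> np.ndarray:
    """Phase changes between consecutive non-missing entries, per progeny.

    All-missing rows get -1 and are excluded from means (logged).
    """
    counts = np.empty(phased.n_progeny, dtype=int)
    for i in range(phased.n_progeny):
        row = phased.phases[i]
        obs = row[row >= 0]
        if len(obs) == 0:
            counts[i] = -1
            log.warning("progeny %s all-missing on %s; excluded from mean",
                        phased.progeny[i], phased.lg)
        else:
            counts[i] = int(np.count_nonzero(np.diff(obs)))
    return counts


def correct_table(
    table,
    gmap,
    parent: str,
    window: int = 2,
    posterior_min: float = 0.95,
):
    """Return a copy of *table* with singleton phase flips in *parent*'s
    uniparental markers set missing and re-imputed.

    Phases the table along *gmap*, flags singletons, and writes corrected
    calls back through each marker's observed phase-to-call mapping.  Used
    between mapping rounds so close double "crossovers" (indistinguishable
    from genotyping errors at marker resolution) do not distort ordering.
    """
    from sibmap.codes import MISSING, UNIPARENTAL_ALLELE_INDEX
    from sibmap.phaseimpute import assign_phase
    from sibmap.pipeline_io import GenotypeTable, MarkerRecord

    want = "lmxll" if parent == "maternal" else "nnxnp"
    tokens = {v: k for k, v in UNIPARENTAL_ALLELE_INDEX[want].items()}
    phased = assign_phase(gmap, table, parent)
    new_calls: dict[str, list[str]] = {}
    for lg, pl in phased.items():
        corrected, flagged = detect_errors(pl, window=window, posterior_min=posterior_min)
        if not flagged:
            continue
        raw = pl.phases
        for j, marker in enumerate(pl.marker_ids):
            col_flags = [i for (i, jj) in flagged if jj == j]
            if not col_flags:
                continue
            # orientation: majority mapping between assigned phase and call
            rec = next(r for r in table if r.marker_id == marker)
            flip = 0
            votes = sum(
                1 if raw[i, j] == UNIPARENTAL_ALLELE_INDEX[want].get(rec.calls[i], -9)
                else -1
                for i in range(pl.n_progeny)
                if raw[i, j] >= 0 and rec.calls[i] != MISSING
            )
            flip = 0 if votes >= 0 else 1
            calls = new_calls.setdefault(marker, list(rec.calls))
            for i in col_flags:
                v = int(corrected.phases[i, j])
                calls[i] = tokens[v ^ flip] if v >= 0 else MISSING
    if not new_calls:
        return table
    records = [
        MarkerRecord(r.marker_id, r.seg_code, new_calls.get(r.marker_id, r.calls),
                     phase=r.phase, lg=r.lg)
        for r in table
    ]
    return GenotypeTable(table.progeny, records)


def bin_map(
    phased: PhasedLG, window: int = 2, correct_errors: bool = True
) -> BinMapResult:
    """Error-correct, bin and count recombination events for one LG."""
    flagged: list[tuple[int, int]] = []
    if correct_errors:
        phased, flagged = detect_errors(phased, window=window)
    bins = make_bins(phased)
    counts = count_recombinations(phased)
    return BinMapResult(phased.lg, bins, counts, flagged)
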