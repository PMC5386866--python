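"""Truth-annotated simulator for full-sib outcross populations.

Meiosis model: chiasma count per bivalent is Poisson with mean
2 * L / 100 scaled by a piecewise-constant crossover-intensity profile
(a suppression window around the centromere multiplies intensity by a
factor in [0, 1]); chiasma positions are drawn from the normalized
profile.  Each chiasma exchanges the distal segments of exactly two of
the four chromatids — one carrying grandparental phase A and one phase B
at that point, chosen uniformly — so there is no chromatid interference
and a random gamete recombines per Haldane's function of distance.

Paternal gametes can be drawn from a finite pool of tetrads (sampling
with replacement across tetrads, without replacement within a tetrad
until exhausted) to emulate pollen shed as intact tetrads; maternal
gametes always come from independent meioses.  Viability selection at
configured loci is applied before missing/error noise, and noise touches
only the observed genotype tables, never the recorded truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from sibmap.codes import MISSING
from sibmap.pipeline_io import GeneticMap, GenotypeTable, MarkerRecord, PhasedLG

DEFAULT_LG_LENGTH = 100.0


class ConfigError(ValueError):
    pass


@dataclass
class SDLocus:
    """Viability locus: gametes of *parent* carrying *allele* (phase 0/1) at
    ``cm`` on ``lg`` survive with probability ``survival``; others always."""

    lg: int
    cm: float
    allele: int = 1
    survival: float = 1.0
    parent: str = "maternal"


@dataclass
class SimConfig:
    n_lg: int = 12
    lg_lengths: Sequence[float] | None = None
    n_progeny: int = 150
    marker_density: float = 1.0  # informative markers per cM per parent
    type_mix: dict[str, float] = field(
        default_factory=lambda: {"lmxll": 0.5, "nnxnp": 0.5}
    )
    missing_rate: float = 0.0
    error_rate: float = 0.0
    maternal_rate_scale: float = 1.0
    paternal_rate_scale: float = 1.0
    tetrad_pool_size: int | None = None  # None: unlimited (independent meioses)
    centromere_pos: Sequence[float] | None = None  # default: LG midpoints
    suppression_width: float = 0.0
    suppression_factor: float = 1.0
    sd_loci: Sequence[SDLocus] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lg_lengths is None:
            self.lg_lengths = [DEFAULT_LG_LENGTH] * self.n_lg
        self.lg_lengths = list(self.lg_lengths)
        if len(self.lg_lengths) != self.n_lg:
            raise ConfigError("lg_lengths must have n_lg entries")
        if any(length <= 0 for length in self.lg_lengths):
            raise ConfigError("lg_lengths must be positive")
        for name, rate in (
            ("missing_rate", self.missing_rate),
            ("error_rate", self.error_rate),
            ("suppression_factor", self.suppression_factor),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} {rate} outside [0, 1]")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("type_mix must sum to 1")
        if self.centromere_pos is None:
            self.centromere_pos = [length / 2 for length in self.lg_lengths]
        self.centromere_pos = list(self.centromere_pos)
        if len(self.centromere_pos) != self.n_lg:
            raise ConfigError("centromere_pos must have n_lg entries")
        for c, length in zip(self.centromere_pos, self.lg_lengths):
            lo, hi = c - self.suppression_width / 2, c + self.suppression_width / 2
            if self.suppression_width > 0 and (lo < 0 or hi > length):
                raise ConfigError("suppression window extends outside LG")
        for locus in self.sd_loci:
            if not 0.0 <= locus.survival <= 1.0:
                raise ConfigError("survival probability outside [0, 1]")
            if not 0 <= locus.lg < self.n_lg:
                raise ConfigError("sd locus LG out of range")
        if self.tetrad_pool_size is not None and self.tetrad_pool_size < 1:
            raise ConfigError("tetrad_pool_size must be >= 1 or None")


# ---------------------------------------------------------------------------
# intensity profiles
# ---------------------------------------------------------------------------


@dataclass
class IntensityProfile:
    """Piecewise-constant crossover intensity over [0, L] (genetic coords)."""

    breaks: np.ndarray  # length k+1, [0 ... L]
    rates: np.ndarray  # length k, nonnegative

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ConfigError("intensity must be nonnegative")

    @property
    def mass(self) -> float:
        return float(np.sum(np.diff(self.breaks) * self.rates))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        widths = np.diff(self.breaks)
        weights = widths * self.rates
        total = weights.sum()
        if total <= 0 or n == 0:
            return np.empty(0)
        seg = rng.choice(len(weights), size=n, p=weights / total)
        u = rng.random(n)
        return self.breaks[seg] + u * widths[seg]


def make_profile(
    lg_length: float,
    centromere: float | None = None,
    suppression_width: float = 0.0,
    suppression_factor: float = 1.0,
) -> IntensityProfile:
    if lg_length <= 0:
        raise ConfigError("LG length must be positive")
    if suppression_width <= 0 or centromere is None:
        return IntensityProfile(np.array([0.0, lg_length]), np.array([1.0]))
    lo = centromere - suppression_width / 2
    hi = centromere + suppression_width / 2
    return IntensityProfile(
        np.array([0.0, lo, hi, lg_length]),
        np.array([1.0, suppression_factor, 1.0]),
    )


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


@dataclass
class Tetrad:
    """Four chromatids of one meiosis on one LG.

    Each chromatid is a piecewise phase function: ``starts[i]`` (ascending,
    first 0.0) and ``labels[i]`` (0/1 grandparental phase per segment).
    """

    starts: list[np.ndarray]
    labels: list[np.ndarray]
    chiasmata: np.ndarray
    crossovers: list[np.ndarray]  # per chromatid, positions of phase changes

    def phase_at(self, chromatid: int, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.starts[chromatid], positions, side="right") - 1
        return self.labels[chromatid][idx].astype(np.int8)


def simulate_meiosis(
    lg_length: float,
    intensity: IntensityProfile | None = None,
    rng: np.random.Generator | None = None,
    rate_scale: float = 1.0,
    haplotypes: tuple[int, int] = (0, 1),
) -> Tetrad:
    """One meiosis: Poisson chiasmata placed by the intensity profile, each
    exchanging one phase-0 with one phase-1 chromatid (uniformly chosen)."""
    if lg_length < 0:
        raise ConfigError("nonpositive LG length")
    rng = rng if rng is not None else np.random.default_rng()
    intensity = intensity if intensity is not None else make_profile(max(lg_length, 1e-9))
    if lg_length == 0:
        n_chi = 0
        chiasmata = np.empty(0)
    else:
        mean = 2.0 * intensity.mass / 100.0 * rate_scale
        n_chi = int(rng.poisson(mean))
        chiasmata = np.sort(intensity.sample(n_chi, rng))
    h0, h1 = haplotypes
    cur = np.array([h0, h0, h1, h1], dtype=np.int8)
    seg_starts: list[list[float]] = [[0.0] for _ in range(4)]
    seg_labels: list[list[int]] = [[int(c)] for c in cur]
    breaks: list[list[float]] = [[] for _ in range(4)]
    for x in chiasmata:
        zeros = np.nonzero(cur == h0)[0]
        ones = np.nonzero(cur == h1)[0]
        i = int(rng.choice(zeros))
        j = int(rng.choice(ones))
        cur[i], cur[j] = cur[j], cur[i]
        for t in (i, j):
            seg_starts[t].append(float(x))
            seg_labels[t].append(int(cur[t]))
            breaks[t].append(float(x))
    return Tetrad(
        [np.array(s) for s in seg_starts],
        [np.array(l, dtype=np.int8) for l in seg_labels],
        chiasmata,
        [np.array(b) for b in breaks],
    )


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


@dataclass
class TruthBundle:
    true_maps: dict[str, GeneticMap]
    true_phases: dict[str, dict[str, PhasedLG]]
    crossover_positions: dict[str, dict[str, list[np.ndarray]]]
    centromere_truth: dict[str, float]
    tetrad_assignments: list[int] | None


@dataclass
class PopulationSim:
    config: SimConfig
    progeny: list[str]
    table: GenotypeTable
    truth: TruthBundle
    marker_meta: list[dict]  # id, lg, cm, seg, orientation bits


def _marker_panel(config: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Lay markers on each LG and assign segregation types.

    The panel targets ``marker_density`` informative markers per cM for the
    maternal parent (symmetric mixes give the paternal parent the same
    density); positions are an even grid over [0, L].
    """
    types = sorted(config.type_mix)
    probs = np.array([config.type_mix[t] for t in types])
    mat_share = sum(p for t, p in config.type_mix.items() if t != "nnxnp")
    panel: list[dict] = []
    for lg_idx, length in enumerate(config.lg_lengths):
        n = max(2, int(round(config.marker_density * length / max(mat_share, 1e-9))))
        positions = np.linspace(0.0, length, n)
        segs = rng.choice(len(types), size=n, p=probs)
        for k, (cm, si) in enumerate(zip(positions, segs)):
            seg = types[si]
            panel.append(
                {
                    "id": f"M{lg_idx + 1:02d}_{k + 1:04d}",
                    "lg": f"LG{lg_idx + 1}",
                    "lg_idx": lg_idx,
                    "cm": float(cm),
                    "seg": seg,
                    "o_m": int(rng.integers(2)),
                    "o_p": int(rng.integers(2)),
                }
            )
    return panel


_CODERS = {
    # (seg) -> call from (maternal allele idx or None, paternal allele idx or None)
    "lmxll": lambda am, ap: ("ll", "lm")[am],
    "nnxnp": lambda am, ap: ("nn", "np")[ap],
    "hkxhk": lambda am, ap: "".join(sorted("hk"[am] + "hk"[ap])),
    "efxeg": lambda am, ap: "".join(sorted("ef"[am] + "eg"[ap])),
    "abxcd": lambda am, ap: "ab"[am] + "cd"[ap],
}


class _GametePool:
    """Paternal gamete supply: unlimited meioses or a finite tetrad pool."""

    def __init__(self, config: SimConfig, profiles: list[IntensityProfile],
                 rng: np.random.Generator):
        self.config = config
        self.profiles = profiles
        self.rng = rng
        self.tetrads: list[dict] | None = None
        if config.tetrad_pool_size is not None:
            if 4 * config.tetrad_pool_size < config.n_progeny:
                raise ConfigError(
                    f"tetrad pool of {config.tetrad_pool_size} cannot supply "
                    f"{config.n_progeny} progeny"
                )
            self.tetrads = [
                {
                    "meioses": [
                        simulate_meiosis(L, prof, rng, config.paternal_rate_scale)
                        for L, prof in zip(config.lg_lengths, profiles)
                    ],
                    "remaining": [0, 1, 2, 3],
                }
                for _ in range(config.tetrad_pool_size)
            ]

    def draw(self) -> tuple[int | None, list[tuple["Tetrad", int]]]:
        """Returns (tetrad id or None, per-LG (tetrad-object, chromatid))."""
        if self.tetrads is None:
            gam = []
            for L, prof in zip(self.config.lg_lengths, self.profiles):
                t = simulate_meiosis(L, prof, self.rng, self.config.paternal_rate_scale)
                gam.append((t, int(self.rng.integers(4))))
            return None, gam
        live = [i for i, t in enumerate(self.tetrads) if t["remaining"]]
        if not live:
            raise ConfigError("tetrad pool exhausted before filling the population")
        tid = int(self.rng.choice(live))
        tet = self.tetrads[tid]
        slot = tet["remaining"].pop(int(self.rng.integers(len(tet["remaining"]))))
        return tid, [(m, slot) for m in tet["meioses"]]


def simulate_population(config: SimConfig) -> PopulationSim:
    """Simulate one full-sib population with recorded ground truth."""
    rng = np.random.default_rng(config.seed)
    panel = _marker_panel(config, rng)
    profiles = [
        make_profile(L, c, config.suppression_width, config.suppression_factor)
        for L, c in zip(config.lg_lengths, config.centromere_pos)
    ]
    pool = _GametePool(config, profiles, rng)
    n_lg = config.n_lg
    lg_names = [f"LG{i + 1}" for i in range(n_lg)]
    lg_positions = [
        np.array([m["cm"] for m in panel if m["lg_idx"] == i]) for i in range(n_lg)
    ]
    sd_by_parent = {"maternal": [], "paternal": []}
    for locus in config.sd_loci:
        sd_by_parent[locus.parent].append(locus)

    mat_phase = [[] for _ in range(n_lg)]  # per LG, list of per-progeny arrays
    pat_phase = [[] for _ in range(n_lg)]
    mat_xo: list[list[np.ndarray]] = [[] for _ in range(n_lg)]
    pat_xo: list[list[np.ndarray]] = [[] for _ in range(n_lg)]
    tetrad_ids: list[int] = []
    attempts, max_attempts = 0, max(1000, 200 * config.n_progeny)
    n_accepted = 0
    while n_accepted < config.n_progeny:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError("viability selection too strong: population unfillable")
        m_gam = []
        for L, prof in zip(config.lg_lengths, profiles):
            t = simulate_meiosis(L, prof, rng, config.maternal_rate_scale)
            m_gam.append((t, int(rng.integers(4))))
        tid, p_gam = pool.draw()

        surv = 1.0
        for parent, gam in (("maternal", m_gam), ("paternal", p_gam)):
            for locus in sd_by_parent[parent]:
                tet, slot = gam[locus.lg]
                ph = int(tet.phase_at(slot, np.array([locus.cm]))[0])
                if ph == locus.allele:
                    surv *= locus.survival
        if surv < 1.0 and rng.random() >= surv:
            continue

        n_accepted += 1
        if tid is not None:
            tetrad_ids.append(tid)
        for lg_idx in range(n_lg):
            tet, slot = m_gam[lg_idx]
            mat_phase[lg_idx].append(tet.phase_at(slot, lg_positions[lg_idx]))
            mat_xo[lg_idx].append(tet.crossovers[slot])
            tet, slot = p_gam[lg_idx]
            pat_phase[lg_idx].append(tet.phase_at(slot, lg_positions[lg_idx]))
            pat_xo[lg_idx].append(tet.crossovers[slot])

    progeny = [f"P{i + 1:04d}" for i in range(config.n_progeny)]
    mat_mats = [np.array(rows, dtype=np.int8) for rows in mat_phase]
    pat_mats = [np.array(rows, dtype=np.int8) for rows in pat_phase]

    # --- genotype coding + noise (observed table only) ---------------------
    _assign_columns(panel)
    records: list[MarkerRecord] = []
    for m in panel:
        lg_idx = m["lg_idx"]
        k = m["_col"]
        mat = mat_mats[lg_idx][:, k]
        pat = pat_mats[lg_idx][:, k]
        seg = m["seg"]
        calls = []
        for pm, pp in zip(mat, pat):
            am = int(pm) ^ m["o_m"]
            ap = int(pp) ^ m["o_p"]
            calls.append(_CODERS[seg](am, ap))
        calls = _apply_noise(calls, seg, config, rng)
        phase = _phase_token(seg, m["o_m"], m["o_p"])
        records.append(MarkerRecord(m["id"], seg, calls, phase=phase, lg=m["lg"]))

    table = GenotypeTable(progeny, records)

    # --- truth -------------------------------------------------------------
    true_maps, true_phases, crossovers = {}, {}, {}
    for parent, mats, xo in (
        ("maternal", mat_mats, mat_xo),
        ("paternal", pat_mats, pat_xo),
    ):
        informative = [
            m for m in panel
            if m["seg"] != ("nnxnp" if parent == "maternal" else "lmxll")
        ]
        rows = [(m["lg"], m["id"], m["cm"]) for m in informative]
        true_maps[parent] = GeneticMap(rows)
        phases: dict[str, PhasedLG] = {}
        for lg_idx, lg in enumerate(lg_names):
            sub = [m for m in informative if m["lg_idx"] == lg_idx]
            cols = [m["_col"] for m in sub]
            phases[lg] = PhasedLG(
                lg,
                [m["id"] for m in sub],
                np.array([m["cm"] for m in sub]),
                mats[lg_idx][:, cols],
                progeny,
            )
        true_phases[parent] = phases
        crossovers[parent] = {lg_names[i]: xo[i] for i in range(n_lg)}

    truth = TruthBundle(
        true_maps,
        true_phases,
        crossovers,
        {lg_names[i]: float(config.centromere_pos[i]) for i in range(n_lg)},
        tetrad_ids if config.tetrad_pool_size is not None else None,
    )
    return PopulationSim(config, progeny, table, truth, panel)


def _assign_columns(panel: list[dict]) -> None:
    """Cache each marker's column index within its LG."""
    counters: dict[int, int] = {}
    for m in panel:
        k = counters.get(m["lg_idx"], 0)
        m["_col"] = k
        counters[m["lg_idx"]] = k + 1


def _phase_token(seg: str, o_m: int, o_p: int) -> str:
    if seg == "lmxll":
        return f"{{{o_m}-}}"
    if seg == "nnxnp":
        return f"{{-{o_p}}}"
    return f"{{{o_m}{o_p}}}"


def _apply_noise(
    calls: list[str], seg: str, config: SimConfig, rng: np.random.Generator
) -> list[str]:
    from sibmap.codes import LEGAL_CALLS

    legal = LEGAL_CALLS[seg]
    out = []
    for call in calls:
        if config.error_rate > 0 and rng.random() < config.error_rate:
            others = [c for c in legal if c != call]
            call = others[int(rng.integers(len(others)))]
        if config.missing_rate > 0 and rng.random() < config.missing_rate:
            call = MISSING
        out.append(call)
    return out


# ---------------------------------------------------------------------------
# truth export
# ---------------------------------------------------------------------------


def write_truth(truth: TruthBundle, prefix) -> None:
    """Truth files: JSON for centromeres/tetrads, TSV for crossover positions."""
    meta = {
        "centromeres": truth.centromere_truth,
        "tetrad_assignments": truth.tetrad_assignments,
    }
    with open(f"{prefix}.truth.json", "wt", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(f"{prefix}.crossovers.tsv", "wt", encoding="utf-8") as fh:
        fh.write("parent\tlg\tprogeny\tpositions\n")
        for parent, by_lg in truth.crossover_positions.items():
            for lg, rows in by_lg.items():
                for i, xs in enumerate(rows):
                    joined = ",".join(repr(round(float(x), 6)) for x in xs)
                    fh.write(f"{parent}\t{lg}\tP{i + 1:04d}\t{joined}\n")
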