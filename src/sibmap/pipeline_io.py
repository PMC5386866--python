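"""Readers and writers for every format the pipeline touches.

Formats (all plain text, tab separated unless noted):

* CP genotype TSV — header ``marker  seg  phase  <progeny...>``; one row per
  marker with calls coded per the marker's segregation type, missing ``--``.
* map TSV — header ``lg  marker  cm  bin``; positions are decimal
  centimorgans, 0-based from the first mapped marker of each LG.
* phased-matrix TSV — progeny rows, marker columns, symbols ``A``/``B``/``-``.
* pedigree CSV — ``id,sire,dam`` with ``0`` (or blank) for unknown parents.
* VCF / HapMap-like tables — read-only convenience for biallelic SNPs.

Every writer is an inverse of the matching reader on its own output.
"""

from __future__ import annotations

import csv
import io
import logging
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field

import numpy as np

from sibmap import codes
from sibmap.codes import MISSING

log = logging.getLogger("sibmap")


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerRecord:
    """One marker: segregation type, optional phase/LG, coded progeny calls."""

    marker_id: str
    seg_code: str
    calls: list[str]
    phase: str | None = None
    lg: str | None = None

    def __post_init__(self) -> None:
        if self.seg_code not in codes.SEG_CODES:
            raise ValidationError(
                f"marker {self.marker_id}: unknown segregation code {self.seg_code!r}"
            )
        for col, call in enumerate(self.calls):
            if not codes.is_legal_call(self.seg_code, call):
                raise ParseError(
                    f"marker {self.marker_id}, progeny column {col}: "
                    f"call {call!r} illegal for {self.seg_code}"
                )

    @property
    def n_progeny(self) -> int:
        return len(self.calls)

    @property
    def n_missing(self) -> int:
        return sum(c == MISSING for c in self.calls)

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / len(self.calls) if self.calls else 0.0


class GenotypeTable(Sequence):
    """Sequence of :class:`MarkerRecord` plus the shared progeny id header."""

    def __init__(self, progeny: Sequence[str], records: Sequence[MarkerRecord]):
        if not progeny:
            raise ParseError("no progeny columns")
        self.progeny = list(progeny)
        self.records = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.marker_id in seen:
                raise ParseError(f"duplicate marker_id {rec.marker_id!r}")
            seen.add(rec.marker_id)
            if rec.n_progeny != len(self.progeny):
                raise ValidationError(
                    f"marker {rec.marker_id}: {rec.n_progeny} calls for "
                    f"{len(self.progeny)} progeny"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[MarkerRecord]:
        return iter(self.records)

    def subset(self, keep) -> "GenotypeTable":
        keep = set(keep)
        return GenotypeTable(self.progeny, [r for r in self.records if r.marker_id in keep])


def _fmt(x: float) -> str:
    """Shortest round-trip decimal for a position; stable under read/write."""
    return repr(round(float(x), 6))


class GeneticMap:
    """Ordered (lg, marker, cM, bin) rows; positions nondecreasing per LG."""

    def __init__(self, rows: Sequence[tuple], assign_bins: bool = True):
        # rows: (lg, marker, cm[, bin])
        self.rows: list[list] = []
        last: dict[str, float] = {}
        seen: set[str] = set()
        for row in rows:
            lg, marker, cm = str(row[0]), str(row[1]), float(row[2])
            bin_id = row[3] if len(row) > 3 else None
            if marker in seen:
                raise ValidationError(f"duplicate marker {marker!r} in map")
            seen.add(marker)
            if lg in last and cm < last[lg] - 1e-9:
                raise ValidationError(
                    f"positions decrease within {lg} at marker {marker} "
                    f"({cm} < {last[lg]})"
                )
            last[lg] = max(cm, last.get(lg, cm))
            self.rows.append([lg, marker, cm, bin_id])
        if assign_bins and any(r[3] is None for r in self.rows):
            self._assign_bins()

    def _assign_bins(self) -> None:
        prev_lg, prev_cm, idx = None, None, 0
        for row in self.rows:
            if row[0] != prev_lg:
                idx, prev_cm = 1, row[2]
            elif abs(row[2] - prev_cm) > 1e-9:
                idx += 1
                prev_cm = row[2]
            row[3] = f"{row[0]}.{idx}"
            prev_lg = row[0]

    # -- accessors ---------------------------------------------------------
    def lgs(self) -> list[str]:
        out: list[str] = []
        for row in self.rows:
            if row[0] not in out:
                out.append(row[0])
        return out

    def lg_rows(self, lg: str) -> list[list]:
        return [r for r in self.rows if r[0] == lg]

    def lg_markers(self, lg: str) -> list[str]:
        return [r[1] for r in self.rows if r[0] == lg]

    def lg_positions(self, lg: str) -> np.ndarray:
        return np.array([r[2] for r in self.rows if r[0] == lg], dtype=float)

    def lg_length(self, lg: str) -> float:
        pos = self.lg_positions(lg)
        return float(pos.max() - pos.min()) if len(pos) else 0.0

    @property
    def total_length(self) -> float:
        return sum(self.lg_length(lg) for lg in self.lgs())

    def position_of(self) -> dict[str, tuple[str, float]]:
        return {r[1]: (r[0], r[2]) for r in self.rows}

    def markers(self) -> list[str]:
        return [r[1] for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        if len(self.rows) != len(other.rows):
            return False
        for a, b in zip(self.rows, other.rows):
            if a[0] != b[0] or a[1] != b[1] or abs(a[2] - b[2]) > 1e-9 or a[3] != b[3]:
                return False
        return True


@dataclass
class PhasedLG:
    """Grandparental-phase grid for one parent on one LG.

    ``phases`` is progeny x markers, int8 with 0 = phase A, 1 = phase B and
    -1 = missing; ``positions`` are the mapped cM of each marker column.
    """

    lg: str
    marker_ids: list[str]
    positions: np.ndarray
    phases: np.ndarray
    progeny: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.phases = np.asarray(self.phases, dtype=np.int8)
        if self.phases.shape[1] != len(self.marker_ids):
            raise ValidationError("phase matrix does not match marker list")
        if np.any(np.diff(self.positions) < -1e-9):
            raise ValidationError(f"positions decrease within {self.lg}")
        if not self.progeny:
            self.progeny = [f"P{i + 1}" for i in range(self.phases.shape[0])]

    @property
    def n_progeny(self) -> int:
        return int(self.phases.shape[0])

    @property
    def n_markers(self) -> int:
        return int(self.phases.shape[1])

    def copy(self) -> "PhasedLG":
        return PhasedLG(
            self.lg,
            list(self.marker_ids),
            self.positions.copy(),
            self.phases.copy(),
            list(self.progeny),
        )


# ---------------------------------------------------------------------------
# CP genotype TSV
# ---------------------------------------------------------------------------


def read_genotypes(path, dialect: str = "cp-tsv", **kwargs) -> GenotypeTable:
    """Read a genotype table; codes are normalized to canonical CP tokens."""
    if dialect == "cp-tsv":
        return _read_cp_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path, **kwargs)
    if dialect == "hapmap-like":
        return _read_hapmap(path, **kwargs)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_cp_tsv(path) -> GenotypeTable:
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["marker", "seg", "phase"]:
            raise ParseError(f"{path}: bad cp-tsv header {header[:3]}")
        progeny = header[3:]
        if not progeny:
            raise ParseError("no progeny columns")
        records = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields")
            marker_id = fields[0]
            seg = fields[1].strip("<>")
            phase = fields[2] if fields[2] != "" else None
            records.append(MarkerRecord(marker_id, seg, fields[3:], phase=phase))
    return GenotypeTable(progeny, records)


def write_genotypes(table: GenotypeTable, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(["marker", "seg", "phase", *table.progeny]) + "\n")
        for rec in table:
            phase = rec.phase if rec.phase is not None else ""
            fh.write("\t".join([rec.marker_id, f"<{rec.seg_code}>", phase, *rec.calls]) + "\n")


# ---------------------------------------------------------------------------
# map TSV
# ---------------------------------------------------------------------------


def read_map(path) -> GeneticMap:
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["lg", "marker", "cm"]:
            raise ParseError(f"{path}: bad map header {header[:3]}")
        has_bin = len(header) > 3 and header[3] == "bin"
        rows = []
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: short row")
            bin_id = f[3] if has_bin and len(f) > 3 and f[3] != "" else None
            try:
                cm = float(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position {f[2]!r}") from exc
            rows.append((f[0], f[1], cm, bin_id))
    return GeneticMap(rows)


def write_map(gmap: GeneticMap, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        fh.write("lg\tmarker\tcm\tbin\n")
        for lg, marker, cm, bin_id in gmap.rows:
            fh.write(f"{lg}\t{marker}\t{_fmt(cm)}\t{bin_id or ''}\n")


# ---------------------------------------------------------------------------
# phased matrices
# ---------------------------------------------------------------------------

_PHASE_SYM = {0: "A", 1: "B", -1: "-"}
_SYM_PHASE = {"A": 0, "B": 1, "-": -1}


def write_phases(phased: PhasedLG, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        fh.write("progeny\t" + "\t".join(phased.marker_ids) + "\n")
        fh.write("cm\t" + "\t".join(_fmt(p) for p in phased.positions) + "\n")
        for i, pid in enumerate(phased.progeny):
            syms = (_PHASE_SYM[int(v)] for v in phased.phases[i])
            fh.write(pid + "\t" + "\t".join(syms) + "\n")


def read_phases(path, lg: str = "LG?") -> PhasedLG:
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "progeny":
            raise ParseError(f"{path}: bad phased-matrix header")
        marker_ids = header[1:]
        posrow = fh.readline().rstrip("\n").split("\t")
        if posrow[0] != "cm":
            raise ParseError(f"{path}: missing cm row")
        positions = np.array([float(x) for x in posrow[1:]], dtype=float)
        progeny, rows = [], []
        for line in fh:
            f = line.rstrip("\n").split("\t")
            progeny.append(f[0])
            try:
                rows.append([_SYM_PHASE[s] for s in f[1:]])
            except KeyError as exc:
                raise ParseError(f"{path}: bad phase symbol {exc}") from exc
    return PhasedLG(lg, marker_ids, positions, np.array(rows, dtype=np.int8), progeny)


# ---------------------------------------------------------------------------
# pedigree CSV
# ---------------------------------------------------------------------------


def read_pedigree(path) -> dict[str, tuple[str | None, str | None]]:
    ped: dict[str, tuple[str | None, str | None]] = {}
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:3]] != ["id", "sire", "dam"]:
            raise ParseError(f"{path}: bad pedigree header {header}")
        for row in reader:
            if not row:
                continue
            ind = row[0].strip()
            sire = row[1].strip() if len(row) > 1 else ""
            dam = row[2].strip() if len(row) > 2 else ""
            ped[ind] = (sire or None if sire != "0" else None, dam or None if dam != "0" else None)
    return ped


def write_pedigree(ped: dict[str, tuple[str | None, str | None]], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "sire", "dam"])
        for ind, (sire, dam) in ped.items():
            writer.writerow([ind, sire or "0", dam or "0"])


# ---------------------------------------------------------------------------
# VCF / HapMap-like (read-only convenience)
# ---------------------------------------------------------------------------


def _read_vcf(path, mother: str, father: str) -> GenotypeTable:
    """Biallelic sites of a plain-text VCF classified against two parents."""
    from sibmap.markerprep import classify_segregation

    with open(path, "rt", encoding="utf-8", newline="") as fh:
        samples: list[str] = []
        records: list[MarkerRecord] = []
        progeny: list[str] = []
        for line in fh:
            if line.startswith("##"):
                continue
            f = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = f[9:]
                if mother not in samples or father not in samples:
                    raise ParseError(f"{path}: parents {mother}/{father} not in VCF samples")
                progeny = [s for s in samples if s not in (mother, father)]
                continue
            if not samples:
                raise ParseError(f"{path}: missing #CHROM header")
            ref, alt = f[3], f[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                continue  # biallelic SNPs only
            alleles = (ref, alt)
            gts = {}
            for s, cell in zip(samples, f[9:]):
                gt = cell.split(":")[0].replace("|", "/")
                if "." in gt:
                    gts[s] = None
                else:
                    a, b = (alleles[int(x)] for x in gt.split("/"))
                    gts[s] = a + b
            if gts[mother] is None or gts[father] is None:
                continue
            marker_id = f[2] if f[2] not in (".", "") else f"{f[0]}_{f[1]}"
            try:
                seg, calls, _ = classify_segregation(
                    gts[mother], gts[father], [gts[p] for p in progeny]
                )
            except ValidationError:
                continue  # monomorphic in the cross
            records.append(MarkerRecord(marker_id, seg, calls))
    return GenotypeTable(progeny, records)


def _read_hapmap(path, mother: str, father: str) -> GenotypeTable:
    """Tabular SNP matrix (marker, alleles, sample columns of e.g. ``AG``/``NN``)."""
    from sibmap.markerprep import classify_segregation

    with open(path, "rt", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[2:]
        if mother not in samples or father not in samples:
            raise ParseError(f"{path}: parents not found in header")
        progeny = [s for s in samples if s not in (mother, father)]
        records = []
        for line in fh:
            f = line.rstrip("\n").split("\t")
            gts = {
                s: (None if cell.upper() in ("NN", "--", "..") else cell)
                for s, cell in zip(samples, f[2:])
            }
            if gts[mother] is None or gts[father] is None:
                continue
            try:
                seg, calls, _ = classify_segregation(
                    gts[mother], gts[father], [gts[p] for p in progeny]
                )
            except ValidationError:
                continue
            records.append(MarkerRecord(f[0], seg, calls))
    return GenotypeTable(progeny, records)


def write_vcf(table: GenotypeTable, path) -> None:
    """Export biallelic-representable markers as a minimal diploid VCF.

    Uniparental and ``hkxhk`` markers map onto two symbolic alleles; other
    biparental types are skipped (they need four alleles).
    """
    biallelic = {"lmxll", "nnxnp", "hkxhk"}
    gt_of = {
        "ll": "0/0", "lm": "0/1",
        "nn": "0/0", "np": "0/1",
        "hh": "0/0", "hk": "0/1", "kk": "1/1",
        MISSING: "./.",
    }
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.progeny) + "\n")
        pos = 0
        for rec in table:
            if rec.seg_code not in biallelic:
                continue
            pos += 1
            cells = "\t".join(gt_of[c] for c in rec.calls)
            chrom = rec.lg or "0"
            fh.write(f"{chrom}\t{pos}\t{rec.marker_id}\tA\tC\t.\t.\t.\tGT\t{cells}\n")


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------


def table_to_string(table: GenotypeTable) -> str:
    buf = io.StringIO()
    buf.write("\t".join(["marker", "seg", "phase", *table.progeny]) + "\n")
    for rec in table:
        phase = rec.phase if rec.phase is not None else ""
        buf.write("\t".join([rec.marker_id, f"<{rec.seg_code}>", phase, *rec.calls]) + "\n")
    return buf.getvalue()
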