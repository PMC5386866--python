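"""Segregation-type classification and pre-mapping marker filters.

The filter chain mirrors standard GBS post-processing: drop markers with
>20% missing calls, minor-allele frequency <10% (computed on progeny
allele counts), or extreme segregation distortion (chi-square P < 1e-5).
Boundary semantics are strict inequalities throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from sibmap import codes
from sibmap.codes import MISSING
from sibmap.pipeline_io import GenotypeTable, MarkerRecord, ValidationError


@dataclass
class FilterReport:
    """Counts surviving each sequential filter plus per-marker drop reasons."""

    n_input: int = 0
    n_after_missing: int = 0
    n_after_maf: int = 0
    n_after_sd: int = 0
    dropped: dict[str, str] = field(default_factory=dict)
    n_non_mendelian_calls: int = 0

    def counts(self) -> list[int]:
        return [self.n_input, self.n_after_missing, self.n_after_maf, self.n_after_sd]

    def to_dict(self) -> dict:
        return {
            "input": self.n_input,
            "after_missing": self.n_after_missing,
            "after_maf": self.n_after_maf,
            "after_extreme_sd": self.n_after_sd,
            "non_mendelian_calls": self.n_non_mendelian_calls,
            "dropped": dict(self.dropped),
        }

    def to_tsv(self) -> str:
        lines = ["marker\treason"]
        lines += [f"{m}\t{r}" for m, r in self.dropped.items()]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _normalize_parent(gt: str) -> tuple[str, str]:
    if len(gt) != 2:
        raise ValidationError(f"parental genotype {gt!r} is not two alleles")
    a, b = sorted(gt)
    return a, b


def classify_segregation(
    mother: str, father: str, progeny: list[str | None]
) -> tuple[str, list[str], int]:
    """Classify a raw biallelic/multiallelic marker into a CP segregation type.

    Parameters are raw two-character genotypes (e.g. ``"AG"``); progeny
    entries may be ``None``/``"--"`` for missing.  Returns the segregation
    code, the progeny calls recoded to canonical CP tokens, and the number
    of non-Mendelian progeny calls (set missing rather than dropping the
    marker).
    """
    ma, mb = _normalize_parent(mother)
    fa, fb = _normalize_parent(father)
    m_het, f_het = ma != mb, fa != fb

    if not m_het and not f_het:
        raise ValidationError("marker uninformative: both parents homozygous")

    recode: dict[str, str]
    if m_het and not f_het:
        seg = "lmxll"
        l = fa  # allele shared with the homozygous father
        m = mb if ma == l else ma
        if l not in (ma, mb):
            raise ValidationError("father's allele absent from heterozygous mother")
        recode = {"".join(sorted(l + l)): "ll", "".join(sorted(l + m)): "lm"}
    elif f_het and not m_het:
        seg = "nnxnp"
        n = ma
        p = fb if fa == n else fa
        if n not in (fa, fb):
            raise ValidationError("mother's allele absent from heterozygous father")
        recode = {"".join(sorted(n + n)): "nn", "".join(sorted(n + p)): "np"}
    else:
        shared = {ma, mb} & {fa, fb}
        if len(shared) == 2:
            seg = "hkxhk"
            h, k = sorted(shared)
            recode = {h + h: "hh", "".join(sorted(h + k)): "hk", k + k: "kk"}
        elif len(shared) == 1:
            seg = "efxeg"
            e = shared.pop()
            f = mb if ma == e else ma
            g = fb if fa == e else fa
            recode = {
                e + e: "ee",
                "".join(sorted(e + f)): "ef",
                "".join(sorted(e + g)): "eg",
                "".join(sorted(f + g)): "fg",
            }
        else:
            seg = "abxcd"
            a, b = ma, mb
            c, d = fa, fb
            recode = {
                "".join(sorted(a + c)): "ac",
                "".join(sorted(a + d)): "ad",
                "".join(sorted(b + c)): "bc",
                "".join(sorted(b + d)): "bd",
            }

    calls: list[str] = []
    n_flagged = 0
    for raw in progeny:
        if raw is None or raw == MISSING:
            calls.append(MISSING)
            continue
        key = "".join(sorted(raw))
        token = recode.get(key)
        if token is None:
            n_flagged += 1
            calls.append(MISSING)
        else:
            calls.append(token)
    return seg, calls, n_flagged


def classify_table(
    marker_ids: list[str],
    mothers: list[str],
    fathers: list[str],
    progeny_ids: list[str],
    progeny_gts: list[list[str | None]],
) -> tuple[GenotypeTable, int]:
    """Classify a whole raw genotype matrix; returns table + flagged-call count."""
    records, flagged = [], 0
    for mid, mo, fa, row in zip(marker_ids, mothers, fathers, progeny_gts):
        seg, calls, n = classify_segregation(mo, fa, row)
        flagged += n
        records.append(MarkerRecord(mid, seg, calls))
    return GenotypeTable(progeny_ids, records), flagged


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_missing(
    table: GenotypeTable, max_missing: float = 0.20, report: FilterReport | None = None
) -> GenotypeTable:
    """Drop markers with missing fraction strictly greater than *max_missing*."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError(f"max_missing {max_missing} outside [0, 1]")
    kept = []
    for rec in table:
        if rec.missing_fraction > max_missing:
            if report is not None:
                report.dropped[rec.marker_id] = (
                    f"missing {rec.missing_fraction:.3f} > {max_missing}"
                )
        else:
            kept.append(rec)
    out = GenotypeTable(table.progeny, kept)
    if report is not None:
        report.n_after_missing = len(out)
    return out


def marker_maf(rec: MarkerRecord) -> float | None:
    """Minor-allele frequency from progeny allele counts (2 per non-missing call)."""
    counts: Counter[str] = Counter()
    n = 0
    for call in rec.calls:
        if call == MISSING:
            continue
        n += 1
        counts[call[0]] += 1
        counts[call[1]] += 1
    if n == 0:
        return None
    # include alleles segregating for this code even if absent from the data
    alleles = set(a for tok in codes.LEGAL_CALLS[rec.seg_code] for a in tok)
    freqs = [counts.get(a, 0) / (2 * n) for a in sorted(alleles)]
    return min(freqs)


def filter_maf(
    table: GenotypeTable, min_maf: float = 0.10, report: FilterReport | None = None
) -> GenotypeTable:
    """Drop markers whose MAF is strictly below *min_maf* (or with no data)."""
    kept = []
    for rec in table:
        maf = marker_maf(rec)
        if maf is None:
            if report is not None:
                report.dropped[rec.marker_id] = "no data"
        elif maf < min_maf:
            if report is not None:
                report.dropped[rec.marker_id] = f"maf {maf:.4f} < {min_maf}"
        else:
            kept.append(rec)
    out = GenotypeTable(table.progeny, kept)
    if report is not None:
        report.n_after_maf = len(out)
    return out


def filter_extreme_sd(
    table: GenotypeTable, alpha: float = 1e-5, report: FilterReport | None = None
) -> GenotypeTable:
    """Drop markers with allele-segregation chi-square P strictly below *alpha*."""
    from sibmap.genomechar import sd_chi2

    kept = []
    for rec in table:
        res = sd_chi2(rec)
        if res is not None and res[1] < alpha:
            if report is not None:
                report.dropped[rec.marker_id] = f"chi2 P {res[1]:.3g} < {alpha}"
        else:
            kept.append(rec)
    out = GenotypeTable(table.progeny, kept)
    if report is not None:
        report.n_after_sd = len(out)
    return out


def apply_filters(
    table: GenotypeTable,
    max_missing: float = 0.20,
    min_maf: float = 0.10,
    sd_alpha: float = 1e-5,
) -> tuple[GenotypeTable, FilterReport]:
    """Run the three filters in sequence and report survival counts."""
    report = FilterReport(n_input=len(table))
    table = filter_missing(table, max_missing, report)
    table = filter_maf(table, min_maf, report)
    table = filter_extreme_sd(table, sd_alpha, report)
    return table, report
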