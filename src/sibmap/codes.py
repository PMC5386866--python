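"""CP segregation-code tables shared across the pipeline.

Five outcross segregation types are supported.  Uniparental markers are
heterozygous in a single parent (``lmxll`` maternal, ``nnxnp`` paternal)
and segregate 1:1 like a testcross; biparental markers are heterozygous
in both parents (``hkxhk`` shared alleles, ``efxeg`` one shared allele,
``abxcd`` four distinct alleles).
"""

from __future__ import annotations

MISSING = "--"

SEG_CODES = ("lmxll", "nnxnp", "hkxhk", "efxeg", "abxcd")

LEGAL_CALLS: dict[str, tuple[str, ...]] = {
    "lmxll": ("ll", "lm"),
    "nnxnp": ("nn", "np"),
    "hkxhk": ("hh", "hk", "kk"),
    "efxeg": ("ee", "ef", "eg", "fg"),
    "abxcd": ("ac", "ad", "bc", "bd"),
}

UNIPARENTAL = ("lmxll", "nnxnp")
BIPARENTAL = ("hkxhk", "efxeg", "abxcd")

#: maternal / paternal informativeness per segregation code
MATERNAL_INFORMATIVE = ("lmxll", "hkxhk", "efxeg", "abxcd")
PATERNAL_INFORMATIVE = ("nnxnp", "hkxhk", "efxeg", "abxcd")

# For a uniparental marker each call reveals which of the two alleles the
# focal parent transmitted: index 0 for the allele shared with the
# homozygous parent, 1 for the parent-private allele.
UNIPARENTAL_ALLELE_INDEX: dict[str, dict[str, int]] = {
    "lmxll": {"ll": 0, "lm": 1},
    "nnxnp": {"nn": 0, "np": 1},
}

# (maternal allele, paternal allele) transmitted for each call where the
# parental origin is unambiguous.  ``hkxhk`` "hk" calls are ambiguous and
# resolved by phaseimpute.resolve_hk.
TRANSMISSION: dict[str, dict[str, tuple[str, str]]] = {
    "efxeg": {"ee": ("e", "e"), "ef": ("f", "e"), "eg": ("e", "g"), "fg": ("f", "g")},
    "abxcd": {"ac": ("a", "c"), "ad": ("a", "d"), "bc": ("b", "c"), "bd": ("b", "d")},
    "hkxhk": {"hh": ("h", "h"), "kk": ("k", "k")},
}

#: per-code (maternal alleles, paternal alleles) of the parents
PARENT_ALLELES: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "lmxll": (("l", "m"), ("l", "l")),
    "nnxnp": (("n", "n"), ("n", "p")),
    "hkxhk": (("h", "k"), ("h", "k")),
    "efxeg": (("e", "f"), ("e", "g")),
    "abxcd": (("a", "b"), ("c", "d")),
}


def informative_for(seg_code: str, parent: str) -> bool:
    """True when a marker of the given segregation type tracks *parent*'s gametes."""
    if parent == "maternal":
        return seg_code in MATERNAL_INFORMATIVE
    if parent == "paternal":
        return seg_code in PATERNAL_INFORMATIVE
    raise ValueError(f"unknown parent {parent!r}")


def is_legal_call(seg_code: str, call: str) -> bool:
    return call == MISSING or call in LEGAL_CALLS[seg_code]
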