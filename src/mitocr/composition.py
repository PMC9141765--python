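"""Base composition, strand skews, codon usage and p-distance.

AT- and GC-skew measure strand-compositional asymmetry:

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed from raw base counts on the counted strand (the percentage form in
common use cancels to the same value).  Codon usage is summarized as raw
counts, codons per thousand codons (CDpT = count / total * 1000) and relative
synonymous codon usage (RSCU = count / (family total / family size)) under
the vertebrate mitochondrial genetic code.  Leucine and serine are reported
as two synonymous families each (Leu CUN / Leu UUR, Ser UCN / Ser AGY),
mirroring how codon-bias figures in mitogenome surveys present them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

__all__ = [
    "CompositionStats",
    "CodonUsage",
    "compute_composition",
    "compute_codon_usage",
    "p_distance",
    "MITO_TABLE_ID",
    "VERT_MITO",
    "codon_families",
    "translate_codon",
]

REGION_CLASSES = ("whole", "PCGs", "rRNAs", "tRNAs", "CR")

MITO_TABLE_ID = 2  # NCBI translation table: vertebrate mitochondrial
VERT_MITO = CodonTable.unambiguous_dna_by_id[MITO_TABLE_ID]
STOP_CODONS = frozenset(VERT_MITO.stop_codons)  # TAA, TAG, AGA, AGG

_BASES = "TCAG"
ALL_CODONS = tuple("".join(c) for c in product(_BASES, repeat=3))


def translate_codon(codon: str) -> str:
    """Amino acid (one letter) or '*' for a stop, vertebrate mito code."""
    if codon in STOP_CODONS:
        return "*"
    return VERT_MITO.forward_table[codon]


def _family_key(codon: str) -> str:
    aa = translate_codon(codon)
    if aa == "L":
        return "L(CUN)" if codon.startswith("CT") else "L(UUR)"
    if aa == "S":
        return "S(UCN)" if codon.startswith("TC") else "S(AGY)"
    return aa


def codon_families() -> dict[str, tuple[str, ...]]:
    """Synonymous families (stop codons excluded), Leu/Ser split by box."""
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        if codon in STOP_CODONS:
            continue
        fams.setdefault(_family_key(codon), []).append(codon)
    return {k: tuple(v) for k, v in fams.items()}


_FAMILIES = codon_families()
_CODON_FAMILY = {c: k for k, cods in _FAMILIES.items() for c in cods}


# ---------------------------------------------------------------------------
# Composition and skews
# ---------------------------------------------------------------------------

@dataclass
class CompositionStats:
    """Base counts and strand skews of one region class of a mitogenome."""

    region_class: str
    a: int
    c: int
    g: int
    t: int
    at_percent: float
    at_skew: float | None  # None when A + T == 0
    gc_skew: float | None  # None when G + C == 0


def compute_composition(seq: str, region_class: str = "whole") -> CompositionStats:
    """Count bases and compute AT%, AT-skew and GC-skew.

    ``N`` (and any other ambiguity code) is excluded from all counts.  A
    skew whose denominator is zero is reported as None rather than raised.
    """
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    total = a + c + g + t
    if total == 0:
        raise ValueError("empty effective sequence (no unambiguous bases)")
    return CompositionStats(
        region_class=region_class,
        a=a,
        c=c,
        g=g,
        t=t,
        at_percent=(a + t) / total * 100.0,
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
    )


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

@dataclass
class CodonUsage:
    """Pooled codon counts with CDpT and RSCU under the vertebrate mito code.

    ``counts`` covers all 64 codons including stops; ``total_codons`` is the
    sum of counts.  CDpT spans all codons (so it sums to 1000); RSCU is
    defined for sense codons only, within the Leu/Ser-split synonymous
    families.  ``warnings`` records internal stop codons encountered.
    """

    counts: dict[str, int]
    total_codons: int
    cdpt: dict[str, float]
    rscu: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def family(self, codon: str) -> str | None:
        return _CODON_FAMILY.get(codon)


def compute_codon_usage(cds_list: list[str]) -> CodonUsage:
    """Pool codon counts over a set of in-frame CDS sequences.

    Trailing incomplete codons (truncated stops such as T-- / TA--) are
    trimmed.  Codons containing ambiguity codes are skipped.  An internal
    stop codon yields a warning naming the CDS index and codon position, not
    an error (terminal stops are counted normally).
    """
    if not cds_list:
        raise ValueError("empty CDS list")
    counts = {c: 0 for c in ALL_CODONS}
    warn: list[str] = []
    for idx, cds in enumerate(cds_list):
        s = cds.upper()
        s = s[: len(s) - len(s) % 3]
        n_codons = len(s) // 3
        for j in range(n_codons):
            codon = s[3 * j : 3 * j + 3]
            if any(b not in "ACGT" for b in codon):
                continue
            counts[codon] += 1
            if codon in STOP_CODONS and j < n_codons - 1:
                warn.append(f"CDS {idx}: internal stop {codon} at codon {j}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no complete unambiguous codons in input")
    cdpt = {c: counts[c] / total * 1000.0 for c in ALL_CODONS}
    rscu: dict[str, float] = {}
    for fam, codons in _FAMILIES.items():
        fam_total = sum(counts[c] for c in codons)
        if fam_total == 0:
            continue
        expected = fam_total / len(codons)
        for c in codons:
            rscu[c] = counts[c] / expected
    return CodonUsage(
        counts=counts, total_codons=total, cdpt=cdpt, rscu=rscu, warnings=warn
    )


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected pairwise distance between two aligned sequences.

    Sites with a gap or ambiguity code in either sequence are excluded; the
    result is (# differing retained sites) / (# retained sites).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    retained = 0
    diff = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        retained += 1
        if x != y:
            diff += 1
    if retained == 0:
        raise ValueError("no comparable (ungapped, unambiguous) sites")
    return diff / retained
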