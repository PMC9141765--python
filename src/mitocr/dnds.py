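"""Nei-Gojobori (1986) pairwise dN/dS under the vertebrate mitochondrial code.

For each codon, every possible single-nucleotide change is classified as
synonymous or nonsynonymous; the synonymous fraction summed over positions
gives the codon's synonymous site count (changes producing a stop codon are
counted as nonsynonymous).  Pairwise expected sites S and N are the averages
of the two sequences' totals, with S + N = 3 x (codons compared) exactly.

Observed differences are counted per codon pair: codons differing at k
positions are resolved by enumerating all k! substitution orders, counting
synonymous/nonsynonymous steps along each pathway and averaging with equal
weights; pathways passing through a stop codon are excluded (if every
pathway does, all are used).  Proportions pS = Sd/S and pN = Nd/N receive
the Jukes-Cantor multiple-hit correction

    d = -3/4 ln(1 - 4p/3),

undefined for p >= 3/4.  The per-gene summary averages the pairwise dN/dS
ratios over all pairs for which the ratio is defined (dS > 0), reporting the
number of undefined pairs alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import log

from .composition import STOP_CODONS, translate_codon

__all__ = [
    "PairwiseDnDs",
    "DnDsResult",
    "ng86_pair",
    "gene_average_ratio",
    "jukes_cantor",
    "synonymous_site_fraction",
]

_BASES = "ACGT"


def jukes_cantor(p: float) -> float | None:
    """Jukes-Cantor corrected distance; None when p >= 0.75 (uncorrectable)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return -0.75 * log(1 - 4.0 * p / 3.0)


def _codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (sum of per-position fractions)."""
    aa = translate_codon(codon)
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and translate_codon(alt) == aa:
                syn += 1
    return syn / 3.0


_SITES_CACHE: dict[str, float] = {}


def synonymous_site_fraction(codon: str) -> float:
    """Cached synonymous site count for a sense codon (0..3 scale)."""
    if codon not in _SITES_CACHE:
        _SITES_CACHE[codon] = _codon_sites(codon)
    return _SITES_CACHE[codon]


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) steps over substitution pathways.

    Pathways through stop codons are excluded; when all pathways hit a stop,
    all are averaged instead so the difference count is never lost.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur = a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if translate_codon_or_stop(cur) == translate_codon_or_stop(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not blocked:
            valid.append((sd, nd))
    pool = valid if valid else all_paths
    return (
        sum(p[0] for p in pool) / len(pool),
        sum(p[1] for p in pool) / len(pool),
    )


def translate_codon_or_stop(codon: str) -> str:
    return "*" if codon in STOP_CODONS else translate_codon(codon)


@dataclass
class PairwiseDnDs:
    """NG86 quantities for one sequence pair."""

    seq_a: str
    seq_b: str
    codons_compared: int
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: float | None  # None when the JC correction is undefined
    dn: float | None
    ratio: float | None  # dN/dS; None when dS == 0 or a correction failed

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def ng86_pair(
    codon_seq_a: str,
    codon_seq_b: str,
    *,
    jc_correction: bool = True,
    name_a: str = "a",
    name_b: str = "b",
) -> PairwiseDnDs:
    """NG86 comparison of two aligned in-frame coding sequences.

    Codons containing gaps or ambiguity codes in either sequence, and codons
    that are stops in either sequence, are skipped pairwise.  With
    ``jc_correction=False`` the raw proportions pS/pN are used as dS/dN.
    """
    a = codon_seq_a.upper()
    b = codon_seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    if len(a) % 3:
        raise ValueError("aligned length must be divisible by 3")
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(x not in "ACGT" for x in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        codons += 1
        s_sites_a += synonymous_site_fraction(ca)
        s_sites_b += synonymous_site_fraction(cb)
        d_s, d_n = _pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
    if codons == 0:
        raise ValueError("no comparable codons")
    s_sites = (s_sites_a + s_sites_b) / 2.0
    n_sites = 3.0 * codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    if jc_correction:
        ds = jukes_cantor(ps)
        dn = jukes_cantor(pn)
    else:
        ds, dn = ps, pn
    ratio = None
    if ds is not None and dn is not None and ds > 0:
        ratio = dn / ds
    return PairwiseDnDs(
        seq_a=name_a,
        seq_b=name_b,
        codons_compared=codons,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ds=ds,
        dn=dn,
        ratio=ratio,
    )


@dataclass
class DnDsResult:
    """Per-gene summary: all pairwise comparisons plus the mean ratio."""

    gene: str
    pairs: list[PairwiseDnDs] = field(default_factory=list)
    mean_ratio: float | None = None
    mean_dn: float | None = None
    mean_ds: float | None = None
    n_undefined: int = 0


def gene_average_ratio(
    alignment: list[tuple[str, str]],
    gene: str = "",
    *,
    jc_correction: bool = True,
) -> DnDsResult:
    """Mean pairwise dN/dS over all unordered pairs of an alignment.

    ``alignment`` is a list of (name, aligned CDS) pairs.  The mean is the
    arithmetic mean of per-pair ratios over pairs with a defined ratio;
    pairs with undefined ratios (dS = 0 or uncorrectable proportions) are
    excluded and counted in ``n_undefined``.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    pairs: list[PairwiseDnDs] = []
    for i in range(len(alignment)):
        for j in range(i + 1, len(alignment)):
            na, sa = alignment[i]
            nb, sb = alignment[j]
            pairs.append(
                ng86_pair(sa, sb, jc_correction=jc_correction, name_a=na, name_b=nb)
            )
    defined = [p for p in pairs if p.defined]
    result = DnDsResult(
        gene=gene,
        pairs=pairs,
        n_undefined=len(pairs) - len(defined),
    )
    if defined:
        result.mean_ratio = sum(p.ratio for p in defined) / len(defined)
        result.mean_dn = sum(p.dn for p in defined) / len(defined)
        result.mean_ds = sum(p.ds for p in defined) / len(defined)
    return result
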