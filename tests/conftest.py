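"""Shared fixtures: synthetic genomes/CRs and independent brute-force oracles.

The oracle helpers here deliberately re-derive results with simple exhaustive
code paths (window scans, prefix-sum period enumeration, DFS pathway
enumeration) so the package implementations are checked against independent
logic, not against themselves.
"""

from __future__ import annotations

import math
from itertools import permutations

import pytest

from mitocr.crtypes import load_type_rules
from mitocr.synth import CR_PRESETS, SyntheticSpec, generate_cr, generate_mitogenome


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_genome():
    record, gt = generate_mitogenome(SyntheticSpec(), seed=1)
    return record, gt


@pytest.fixture(scope="session")
def eremias_cr():
    return generate_cr(CR_PRESETS["eremias_typical"], seed=1)


@pytest.fixture(scope="session")
def rules():
    return load_type_rules()


# ---------------------------------------------------------------------------
# Oracle: exhaustive fuzzy window scan
# ---------------------------------------------------------------------------

def window_scan_oracle(seq: str, ref: str, max_mm: int) -> list[tuple[int, int]]:
    """All (start, mismatches) of substitution-only matches, by direct scan."""
    out = []
    for i in range(len(seq) - len(ref) + 1):
        mm = sum(1 for a, b in zip(seq[i : i + len(ref)], ref) if a != b)
        if mm <= max_mm:
            out.append((i, mm))
    return out


# ---------------------------------------------------------------------------
# Oracle: tandem-repeat detection by exhaustive period enumeration
# ---------------------------------------------------------------------------

def tr_oracle(
    seq: str,
    min_period: int = 1,
    max_period: int = 200,
    min_copies: float = 2.0,
    min_array_length: int = 20,
    min_identity: float = 0.8,
) -> list[tuple[int, int, int]]:
    """Non-overlapping (start, end, period) triples by brute-force enumeration.

    Implements the detector's documented semantics (seed on the second copy,
    extend to the longest qualifying length, trim mismatched edges, prune
    overlaps by (length, identity, period, start)) with plain loops.
    """
    n = len(seq)
    cands: set[tuple[int, int, int, float]] = set()
    for p in range(min_period, min(max_period, n // 2) + 1):
        m = [1 if seq[k + p] == seq[k] else 0 for k in range(n - p)]
        cum = [0]
        for v in m:
            cum.append(cum[-1] + v)
        need = math.ceil(min_identity * p)
        for i in range(n - 2 * p + 1):
            if cum[i + p] - cum[i] < need:
                continue
            best = None
            for L in range(2 * p, n - i + 1):
                if cum[i + L - p] - cum[i] >= min_identity * (L - p):
                    best = L
            if best is None:
                continue
            start, end = i, i + best
            while end - start > 2 * p and m[start] == 0:
                start += 1
            while end - start > 2 * p and m[end - 1 - p] == 0:
                end -= 1
            L = end - start
            ident = (cum[end - p] - cum[start]) / (L - p)
            if (
                L >= min_array_length
                and L / p >= min_copies
                and ident >= min_identity
            ):
                cands.add((start, L, p, ident))
    ordered = sorted(cands, key=lambda c: (-c[1], -c[3], c[2], c[0]))
    kept: list[tuple[int, int, int]] = []
    occupied: list[tuple[int, int]] = []
    for i, L, p, _ in ordered:
        if any(i < e and s < i + L for s, e in occupied):
            continue
        kept.append((i, i + L, p))
        occupied.append((i, i + L))
    return sorted(kept)


# ---------------------------------------------------------------------------
# Oracle: NG86 difference counting by DFS pathway enumeration
# ---------------------------------------------------------------------------

_MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}


def _aa(codon: str) -> str:
    from Bio.Seq import Seq

    return "*" if codon in _MITO_STOPS else str(Seq(codon).translate(table=2))


def pathway_oracle(a: str, b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair by explicit pathway enumeration.

    Walks every substitution order with DFS, drops pathways through stop
    codons (falls back to all pathways when none survive) and averages.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths: list[tuple[int, int, bool]] = []  # (sd, nd, hits_stop)

    def walk(cur: str, remaining: tuple[int, ...], sd: int, nd: int, stop: bool):
        if not remaining:
            paths.append((sd, nd, stop))
            return
        for k, pos in enumerate(remaining):
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            syn = _aa(cur) == _aa(nxt)
            walk(
                nxt,
                remaining[:k] + remaining[k + 1 :],
                sd + (1 if syn else 0),
                nd + (0 if syn else 1),
                stop or nxt in _MITO_STOPS,
            )

    walk(a, tuple(diff), 0, 0, False)
    clean = [p for p in paths if not p[2]]
    pool = clean if clean else paths
    return (
        sum(p[0] for p in pool) / len(pool),
        sum(p[1] for p in pool) / len(pool),
    )


def sites_oracle(codon: str) -> float:
    """Synonymous site count of a codon by direct enumeration."""
    s = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in _MITO_STOPS and _aa(mutant) == _aa(codon):
                s += 1
    return s / 3.0
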