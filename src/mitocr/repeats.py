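"""Tandem-repeat detection in control-region sequences.

Mitochondrial CRs frequently carry arrays of a short unit repeated in tandem;
their presence and position relative to the conserved elements (TAS/CSB) is a
typing criterion, and several lacertid genera carry diagnostic repeat-unit
motifs.  The detector here is a deterministic seed-and-extend scanner:

* for each candidate period ``p`` and start ``i``, positions ``j >= p`` of a
  candidate array are compared with the base one period earlier
  (``seq[j] == seq[j - p]``);
* a seed requires the first ``p`` such comparisons (i.e. the second copy) to
  reach the identity threshold, after which the array is extended to the
  longest length whose overall adjacent-copy identity stays at or above the
  threshold;
* the extended array is then trimmed: mismatched comparisons at either edge
  are dropped, so a reported array always begins and ends on bases that
  match their periodic neighbour (this keeps boundaries exact instead of
  letting arrays absorb flanking sequence up to the identity budget);
* qualifying arrays (length, copy number) are pruned so that overlapping
  candidates keep the best (longest array, then highest identity, then
  smallest period, then leftmost start).

Adjacent-copy identity of an array ``seq[i:i+L)`` with period ``p`` is
``matches / (L - p)`` over the ``L - p`` comparable positions; the first copy
contributes no comparisons, so two random copies need genuinely high
similarity to seed.  The consensus unit is the per-column majority over the
aligned copies (ties broken alphabetically) and ``mean_identity`` is the
fraction of all array positions equal to the periodic consensus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TandemRepeatHit",
    "GenusMotifReport",
    "GENUS_DIAGNOSTIC_MOTIFS",
    "POSITION_CLASSES",
    "ANORMAL_CLASSES",
    "NORMAL_CLASSES",
    "find_tandem_repeats",
    "classify_tr_position",
    "genus_motif_report",
]

#: Repeat-unit motifs diagnostic of lacertid genera (Eremias, Takydromus x2,
#: Darevskia).
GENUS_DIAGNOSTIC_MOTIFS = ("TAGCGGCTTTTTTG", "GCGGCTT", "TTTTCC", "CAAAACTTTTAA")

#: TR position classes relative to the conserved elements; between_* classes
#: are "anormal" (inside the element scaffold), the outer two are "normal".
POSITION_CLASSES = (
    "before_TAS1",
    "between_TAS1_TAS2",
    "between_TAS2_CSB1",
    "between_CSB1_CSB2",
    "between_CSB2_CSB3",
    "after_CSB3",
    "unplaced",
)
ANORMAL_CLASSES = frozenset(
    c for c in POSITION_CLASSES if c.startswith("between_")
)
NORMAL_CLASSES = frozenset(("before_TAS1", "after_CSB3"))


@dataclass
class TandemRepeatHit:
    """A tandem-repeat array located in a CR sequence."""

    start: int
    end: int
    period: int
    copy_number: float
    consensus: str
    mean_identity: float
    position_class: str | None = None

    @property
    def array_length(self) -> int:
        return self.end - self.start


def _consensus(seq: str, start: int, length: int, period: int) -> str:
    cols: list[Counter] = [Counter() for _ in range(period)]
    for j in range(length):
        cols[j % period][seq[start + j]] += 1
    out = []
    for counter in cols:
        best = max(counter.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        # ties broken alphabetically
        top = best[1]
        out.append(min(b for b, c in counter.items() if c == top))
    return "".join(out)


def find_tandem_repeats(
    seq: str,
    min_period: int = 1,
    max_period: int = 200,
    min_copies: float = 2.0,
    min_array_length: int = 20,
    min_identity: float = 0.8,
) -> list[TandemRepeatHit]:
    """Detect tandem-repeat arrays by seed-and-extend (see module docstring).

    Returns non-overlapping hits sorted by start position.  Defaults follow
    the copy-number-filtered settings used for CR repeat surveys:
    ``min_copies=2``, ``min_array_length=20``, ``min_identity=0.8``,
    ``max_period=200``.
    """
    s = seq.upper()
    n = len(s)
    if n == 0:
        return []
    if not (1 <= min_period <= max_period):
        raise ValueError("need 1 <= min_period <= max_period")
    if max_period > n // 2:
        max_period = n // 2
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    candidates: list[tuple[int, int, int, float]] = []  # (start, L, period, identity)
    for p in range(min_period, max_period + 1):
        m = (arr[p:] == arr[:-p]).astype(np.int32)  # m[k] = seq[k+p]==seq[k]
        if m.size < p:
            continue
        cum = np.concatenate(([0], np.cumsum(m)))
        # seed: second copy (p comparisons from i) meets the threshold
        need = int(np.ceil(min_identity * p))
        window = cum[p:] - cum[:-p]  # window[i] = matches in comparisons i..i+p-1
        seed_starts = np.nonzero(window >= need)[0]
        seen: set[tuple[int, int, int]] = set()
        for i in seed_starts:
            i = int(i)
            if i + 2 * p > n:
                continue
            # identity for array length L: (cum[i+L-p]-cum[i]) / (L-p), L in [2p, n-i]
            max_L = n - i
            Ls = np.arange(2 * p, max_L + 1)
            matches = cum[i + Ls - p] - cum[i]
            ok = matches >= min_identity * (Ls - p)
            if not ok.any():
                continue
            last = int(np.nonzero(ok)[0][-1])
            start, end = i, i + int(Ls[last])
            # trim mismatched comparisons off both edges
            while end - start > 2 * p and m[start] == 0:
                start += 1
            while end - start > 2 * p and m[end - 1 - p] == 0:
                end -= 1
            L = end - start
            comps = L - p
            ident = float((cum[end - p] - cum[start]) / comps)
            if (
                L >= min_array_length
                and L / p >= min_copies
                and ident >= min_identity
                and (start, end, p) not in seen
            ):
                seen.add((start, end, p))
                candidates.append((start, L, p, ident))
    # prune overlaps: keep best by (array length, identity, small period, start)
    candidates.sort(key=lambda c: (-c[1], -c[3], c[2], c[0]))
    kept: list[tuple[int, int, int, float]] = []
    occupied: list[tuple[int, int]] = []
    for i, L, p, ident in candidates:
        if any(i < e and s0 < i + L for s0, e in occupied):
            continue
        kept.append((i, L, p, ident))
        occupied.append((i, i + L))
    hits = []
    for i, L, p, _ in sorted(kept):
        cons = _consensus(s, i, L, p)
        mean_ident = sum(
            1 for j in range(L) if s[i + j] == cons[j % p]
        ) / L
        hits.append(
            TandemRepeatHit(
                start=i,
                end=i + L,
                period=p,
                copy_number=round(L / p, 3),
                consensus=cons,
                mean_identity=mean_ident,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Position classification relative to conserved elements
# ---------------------------------------------------------------------------

_BOUNDARY_PAIRS = (
    (None, "TAS1", "before_TAS1"),
    ("TAS1", "TAS2", "between_TAS1_TAS2"),
    ("TAS2", "CSB1", "between_TAS2_CSB1"),
    ("CSB1", "CSB2", "between_CSB1_CSB2"),
    ("CSB2", "CSB3", "between_CSB2_CSB3"),
    ("CSB3", None, "after_CSB3"),
)


def classify_tr_position(hit: TandemRepeatHit, elements) -> str:
    """Position class of a TR relative to the annotated conserved elements.

    ``elements`` is a mapping element name -> ElementHit (or any object with
    ``start``/``end``) or an iterable of ElementHits.  A TR strictly before
    TAS1, strictly after CSB3, or strictly between two canonically adjacent
    annotated elements gets the corresponding class; anything else (no
    elements annotated, TR straddling an element, flanking element missing)
    is "unplaced".
    """
    if not isinstance(elements, dict):
        elements = {e.element: e for e in elements}
    if not elements:
        return "unplaced"
    if any(e.start < hit.end and hit.start < e.end for e in elements.values()):
        return "unplaced"  # TR straddles an annotated element
    left = max(
        (e for e in elements.values() if e.end <= hit.start),
        key=lambda e: e.end,
        default=None,
    )
    right = min(
        (e for e in elements.values() if e.start >= hit.end),
        key=lambda e: e.start,
        default=None,
    )
    for lname, rname, cls in _BOUNDARY_PAIRS:
        if lname == (left.element if left else None) and rname == (
            right.element if right else None
        ):
            return cls
    return "unplaced"


def is_anormal(position_class: str) -> bool:
    return position_class in ANORMAL_CLASSES


# ---------------------------------------------------------------------------
# Genus-diagnostic motifs
# ---------------------------------------------------------------------------

@dataclass
class GenusMotifReport:
    """Presence of each genus-diagnostic motif among the detected arrays."""

    present: dict[str, bool]

    def __getitem__(self, motif: str) -> bool:
        return self.present[motif]


def genus_motif_report(
    hits: list[TandemRepeatHit], cr_seq: str
) -> GenusMotifReport:
    """Test each diagnostic motif against the detected repeat arrays.

    A motif counts as present when it occurs as a substring of a hit's raw
    array sequence or of any rotation of its consensus unit (repeat phase is
    arbitrary, so the consensus is matched rotationally; the doubled
    consensus covers motifs spanning the unit boundary when the motif is no
    longer than the unit).
    """
    s = cr_seq.upper()
    present = {}
    for motif in GENUS_DIAGNOSTIC_MOTIFS:
        found = False
        for h in hits:
            array = s[h.start : h.end]
            if motif in array or motif in (h.consensus + h.consensus):
                found = True
                break
        present[motif] = found
    return GenusMotifReport(present=present)
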