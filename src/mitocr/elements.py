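"""Conserved control-region elements: TAS/CSB motif search and variant typing.

The vertebrate control region carries short conserved motifs — termination-
associated sequences (TAS1, TAS2) near its 5' end and conserved sequence
blocks (CSB1, CSB2, CSB3) near the heavy-strand replication origin at its 3'
end.  Lacertid CRs are annotated by fuzzy (substitution-only) matching of
each element against the *Lacerta dugesii* reference motif; observed variants
are rendered in dot notation (a middle dot marks identity with the reference)
and classified against shipped survey tables of known per-element variant
types.

Substitution-only matching is deliberate: every tabulated variant is
length-preserving, so windows of exactly the reference length are scored by
Hamming distance.  The default mismatch budget per element is 25% of the
motif length, rounded down (TAS1 6, TAS2 2, CSB1 9, CSB2 4, CSB3 5); the
most degenerate published CSB3 variant carries 8 mismatches and is flagged
"novel" under the default budget unless the caller raises it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "REFERENCE_MOTIFS",
    "TAS2_UPDATED",
    "TAS2_UPDATED_ABSTRACT",
    "DEFAULT_MAX_MISMATCHES",
    "ELEMENT_ORDER",
    "DOT",
    "ElementHit",
    "VariantTable",
    "fuzzy_find",
    "render_dots",
    "expand_dots",
    "parse_variant_table",
    "load_variant_table",
    "assign_variant_type",
    "tabulate_variant_counts",
    "annotate_elements",
]

#: Reference motifs of the standard lacertid reference sequence (*L. dugesii*).
REFERENCE_MOTIFS: dict[str, str] = {
    "TAS1": "ACTATTATGTATATAGTGCATTAA",
    "TAS2": "CATACATTAA",
    "CSB1": "CTATATGGTATTATTGTCTTAATGCTTGGTAGACATAT",
    "CSB2": "CAAACCCCCCTACCCCCC",
    "CSB3": "TCGCCAAACCCCTAAAACGA",
}

#: Proposed updated TAS2 anchor (majority first base T across the family).
TAS2_UPDATED = "TATGCATTAA"
#: A second, conflicting spelling of the updated TAS2 printed elsewhere in
#: the source survey; shipped verbatim, not corrected.
TAS2_UPDATED_ABSTRACT = "TATACATTAT"

ELEMENT_ORDER = ("TAS1", "TAS2", "CSB1", "CSB2", "CSB3")

#: 25% of motif length, rounded down.
DEFAULT_MAX_MISMATCHES = {e: len(m) // 4 for e, m in REFERENCE_MOTIFS.items()}

DOT = "·"  # middle dot used in dot-notation variant rows


@dataclass
class ElementHit:
    """A substitution-only alignment of a reference motif inside a CR."""

    element: str
    start: int
    end: int
    matched_sequence: str
    mismatch_count: int
    mismatch_positions: list[tuple[int, str, str]]  # (pos, ref base, observed)
    variant_type: int | str | None = None  # table type id, "novel", or None
    best: bool = False

    @property
    def dot_pattern(self) -> str:
        return render_dots(self.matched_sequence, REFERENCE_MOTIFS[self.element])


@dataclass
class VariantTable:
    """A per-element table of known variant types in dot notation."""

    element: str
    reference: str
    rows: list[tuple[int, str, tuple[str, ...]]] = field(default_factory=list)
    # rows: (type_id, expanded motif, species tuple)

    def expanded(self) -> dict[int, str]:
        return {tid: motif for tid, motif, _ in self.rows}


# ---------------------------------------------------------------------------
# Fuzzy search
# ---------------------------------------------------------------------------

def fuzzy_find(
    cr_seq: str,
    element: str,
    max_mismatches: int | None = None,
    *,
    reference: str | None = None,
    search_from: int = 0,
) -> list[ElementHit]:
    """All substitution-only matches of an element motif in a CR sequence.

    Every window of reference length starting at or after ``search_from``
    with Hamming distance <= ``max_mismatches`` is returned, sorted by
    (mismatch_count, start); the first hit is flagged ``best``.  ``reference``
    overrides the shipped motif (used for the updated TAS2 anchor).
    """
    ref = reference if reference is not None else REFERENCE_MOTIFS[element]
    if max_mismatches is None:
        max_mismatches = DEFAULT_MAX_MISMATCHES[element]
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    seq = cr_seq.upper()
    L = len(ref)
    hits: list[ElementHit] = []
    for i in range(max(0, search_from), len(seq) - L + 1):
        window = seq[i : i + L]
        mism = [
            (j, ref[j], window[j]) for j in range(L) if window[j] != ref[j]
        ]
        if len(mism) <= max_mismatches:
            hits.append(
                ElementHit(
                    element=element,
                    start=i,
                    end=i + L,
                    matched_sequence=window,
                    mismatch_count=len(mism),
                    mismatch_positions=mism,
                )
            )
    hits.sort(key=lambda h: (h.mismatch_count, h.start))
    if hits:
        hits[0].best = True
    return hits


def annotate_elements(
    cr_seq: str,
    max_mismatches: dict[str, int] | None = None,
    *,
    ordered: bool = True,
) -> dict[str, ElementHit]:
    """Best hit per element, searched in canonical TAS1->CSB3 order.

    With ``ordered=True`` (default) each element is searched only downstream
    of the previous best hit, enforcing the canonical layout; with
    ``ordered=False`` every element is searched over the whole CR (needed to
    recognize rearranged, non-canonical layouts).
    """
    overrides = max_mismatches or {}
    best: dict[str, ElementHit] = {}
    cursor = 0
    for element in ELEMENT_ORDER:
        hits = fuzzy_find(
            cr_seq,
            element,
            overrides.get(element, DEFAULT_MAX_MISMATCHES[element]),
            search_from=cursor if ordered else 0,
        )
        if hits:
            best[element] = hits[0]
            if ordered:
                cursor = hits[0].end
    return best


# ---------------------------------------------------------------------------
# Dot notation
# ---------------------------------------------------------------------------

def render_dots(observed: str, reference: str) -> str:
    """Dot-notation rendering: middle dot where observed equals reference."""
    if len(observed) != len(reference):
        raise ValueError(
            f"length mismatch: observed {len(observed)} vs reference {len(reference)}"
        )
    return "".join(DOT if o == r else o for o, r in zip(observed, reference))


def expand_dots(pattern: str, reference: str) -> str:
    """Inverse of :func:`render_dots` ('.' is accepted as a dot too)."""
    if len(pattern) != len(reference):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs reference {len(reference)}"
        )
    return "".join(
        r if p in (DOT, ".") else p for p, r in zip(pattern, reference)
    )


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def parse_variant_table(path: str | Path) -> VariantTable:
    """Parse a variant-table fixture TSV.

    Format: comment lines ``# element=TAS2`` and ``# reference=CATACATTAA``,
    then a header row and rows ``type_id<TAB>dot_pattern<TAB>species`` where
    species is a semicolon-separated list.  Dot rows must have exactly the
    reference length.
    """
    element = reference = None
    rows: list[tuple[int, str, tuple[str, ...]]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for raw in reader:
            if not raw or not raw[0].strip():
                continue
            first = raw[0].strip()
            if first.startswith("#"):
                stripped = first.lstrip("#").strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    if key.strip() == "element":
                        element = val.strip()
                    elif key.strip() == "reference":
                        reference = val.strip()
                continue
            if first == "type_id":
                continue
            if element is None or reference is None:
                raise ValueError(f"{path}: missing element/reference header")
            type_id = int(first)
            pattern = raw[1].strip()
            if len(pattern) != len(reference):
                raise ValueError(
                    f"{path}: row {type_id} pattern width {len(pattern)} != "
                    f"reference width {len(reference)}"
                )
            species = tuple(
                s.strip() for s in (raw[2] if len(raw) > 2 else "").split(";") if s.strip()
            )
            rows.append((type_id, expand_dots(pattern, reference), species))
    if element is None or reference is None:
        raise ValueError(f"{path}: missing element/reference header")
    return VariantTable(element=element, reference=reference, rows=rows)


_TABLE_FILES = {
    "TAS1": "lacertidae_tas1_variants.tsv",
    "TAS2": "lacertidae_tas2_variants.tsv",
    "CSB1": "lacertidae_csb1_variants.tsv",
    "CSB2": "lacertidae_csb2_variants.tsv",
    "CSB3": "lacertidae_csb3_variants.tsv",
}


def load_variant_table(element: str) -> VariantTable:
    """Load the shipped lacertid variant survey table for one element."""
    fname = _TABLE_FILES[element]
    with resources.as_file(resources.files("mitocr.data").joinpath(fname)) as p:
        table = parse_variant_table(p)
    if table.element != element or table.reference != REFERENCE_MOTIFS[element]:
        raise ValueError(f"shipped table {fname} inconsistent with references")
    return table


def assign_variant_type(hit: ElementHit, table: VariantTable) -> int | str:
    """Exact-match the observed motif against a variant table.

    Returns the matching row's type id, or "novel" when no row matches.
    """
    if hit.element != table.element:
        raise ValueError(
            f"hit element {hit.element} does not match table {table.element}"
        )
    for type_id, motif, _ in table.rows:
        if hit.matched_sequence == motif:
            hit.variant_type = type_id
            return type_id
    hit.variant_type = "novel"
    return "novel"


def tabulate_variant_counts(table: VariantTable, predicate) -> int:
    """Number of taxa whose expanded motif satisfies ``predicate``.

    Counts species-list sizes, i.e. the survey's per-type taxon counts.
    """
    return sum(
        len(species) for _, motif, species in table.rows if predicate(motif)
    )
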