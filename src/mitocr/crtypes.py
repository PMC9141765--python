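"""Control-region typing: layout profiles and the rule-driven classifier.

A CR layout is summarized as a :class:`CRProfile`: which of the five
conserved elements (TAS1, TAS2, CSB1, CSB2, CSB3) are present, whether they
appear in canonical order, and where tandem-repeat arrays sit relative to
them.  TRs between two conserved elements are "anormal"; TRs outside the
element scaffold (before TAS1 or after CSB3) are "normal".

Profiles are classified against an editable rule table into five general
types and twenty-one subtypes.  The shipped table (data/cr_type_rules.yaml)
encodes the scheme used for lacertids:

* Types I-IV: all five elements present, in order, distinguished by the
  anormal-TR placement (I: none; II: between CSB1 and CSB2; III: between
  TAS2 and CSB1; IV: between CSB2 and CSB3), with the subtype determined by
  the normal-TR placement pattern;
* Type V: element scaffold defective (elements missing, or present but out
  of canonical order), with subtypes V-1..V-11 keyed to the defect.

The published scheme defines subtypes only schematically, so the shipped
table is an explicit, overridable reconstruction; "unclassified" is a
first-class outcome for layouts no rule covers, never forced into Type V.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .elements import ELEMENT_ORDER, ElementHit, annotate_elements
from .repeats import (
    ANORMAL_CLASSES,
    NORMAL_CLASSES,
    TandemRepeatHit,
    classify_tr_position,
    find_tandem_repeats,
)

__all__ = [
    "CRProfile",
    "TypeRule",
    "CRTypeAssignment",
    "annotate_cr_sequence",
    "build_profile",
    "classify_cr",
    "load_type_rules",
    "load_layout_profiles",
    "type_map_table",
    "AmbiguousRuleError",
]

GENERAL_TYPES = ("I", "II", "III", "IV", "V")


@dataclass
class CRProfile:
    """Presence/order/TR-placement summary of one control region."""

    record_id: str
    element_presence: dict[str, bool]  # keyed by ELEMENT_ORDER
    element_order_ok: bool
    anormal_tr_classes: frozenset[str]
    normal_tr_classes: frozenset[str]
    cr_length: int = 0

    def present_elements(self) -> tuple[str, ...]:
        return tuple(e for e in ELEMENT_ORDER if self.element_presence[e])


@dataclass
class TypeRule:
    """One row of the typing rule table.

    ``presence`` is the exact set of elements that must be present (all
    others absent); ``order_ok``, ``anormal`` and ``normal`` constrain the
    corresponding profile fields exactly when given and are ignored when
    None.  Higher ``priority`` wins among satisfied rules.
    """

    label: str
    general_type: str
    presence: frozenset[str]
    order_ok: bool | None
    anormal: frozenset[str] | None
    normal: frozenset[str] | None
    priority: int

    def matches(self, profile: CRProfile) -> bool:
        if frozenset(profile.present_elements()) != self.presence:
            return False
        if self.order_ok is not None and profile.element_order_ok != self.order_ok:
            return False
        if self.anormal is not None and profile.anormal_tr_classes != self.anormal:
            return False
        if self.normal is not None and profile.normal_tr_classes != self.normal:
            return False
        return True


@dataclass
class CRTypeAssignment:
    record_id: str
    general_type: str  # "I".."V" or "unclassified"
    subtype: str  # e.g. "I-4" or "unclassified"
    matched_rule: str | None


class AmbiguousRuleError(ValueError):
    """Two satisfied rules share the top priority."""


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def annotate_cr_sequence(
    cr_seq: str,
    record_id: str = "",
    *,
    ordered: bool = True,
    max_mismatches: dict[str, int] | None = None,
    tr_params: dict | None = None,
) -> tuple[dict[str, ElementHit], list[TandemRepeatHit], CRProfile]:
    """Full CR annotation: element hits, positioned TR hits, layout profile.

    ``ordered=False`` searches every element over the whole CR (needed to
    recognize rearranged layouts); ``tr_params`` are forwarded to
    :func:`find_tandem_repeats`.
    """
    hits = annotate_elements(cr_seq, max_mismatches, ordered=ordered)
    trs = find_tandem_repeats(cr_seq, **(tr_params or {}))
    for tr in trs:
        tr.position_class = classify_tr_position(tr, hits)
    profile = build_profile(hits, trs, len(cr_seq), record_id)
    return hits, trs, profile

def build_profile(
    elements: list[ElementHit] | dict[str, ElementHit],
    trs: list[TandemRepeatHit],
    cr_length: int,
    record_id: str = "",
) -> CRProfile:
    """Derive a :class:`CRProfile` from element hits and TR hits of one CR.

    Duplicate hits for an element keep the fewest-mismatch one (with a
    warning).  Element order is checked against the canonical
    TAS1→TAS2→CSB1→CSB2→CSB3 order over the elements actually present.  TR
    position classes are recomputed against the retained element hits;
    unplaced TRs contribute to neither class set.
    """
    if isinstance(elements, dict):
        best = dict(elements)
    else:
        best = {}
        for hit in elements:
            prev = best.get(hit.element)
            if prev is None:
                best[hit.element] = hit
            else:
                warnings.warn(
                    f"{record_id}: duplicate {hit.element} hits; keeping the "
                    "fewest-mismatch one",
                    stacklevel=2,
                )
                if hit.mismatch_count < prev.mismatch_count:
                    best[hit.element] = hit
    presence = {e: e in best for e in ELEMENT_ORDER}
    present = [best[e] for e in ELEMENT_ORDER if e in best]
    starts = [h.start for h in sorted(present, key=lambda h: ELEMENT_ORDER.index(h.element))]
    order_ok = all(a < b for a, b in zip(starts, starts[1:]))
    anormal: set[str] = set()
    normal: set[str] = set()
    for tr in trs:
        cls = tr.position_class or classify_tr_position(tr, best)
        if cls in ANORMAL_CLASSES:
            anormal.add(cls)
        elif cls in NORMAL_CLASSES:
            normal.add(cls)
    return CRProfile(
        record_id=record_id,
        element_presence=presence,
        element_order_ok=order_ok,
        anormal_tr_classes=frozenset(anormal),
        normal_tr_classes=frozenset(normal),
        cr_length=cr_length,
    )


# ---------------------------------------------------------------------------
# Rule table
# ---------------------------------------------------------------------------

def _as_rule(entry: dict) -> TypeRule:
    def fset(key):
        val = entry.get(key)
        return None if val is None else frozenset(val)

    presence = entry.get("presence")
    if presence is None:
        raise ValueError(f"rule {entry.get('label')}: presence is required")
    rule = TypeRule(
        label=str(entry["label"]),
        general_type=str(entry["general_type"]),
        presence=frozenset(presence),
        order_ok=entry.get("order_ok"),
        anormal=fset("anormal"),
        normal=fset("normal"),
        priority=int(entry.get("priority", 0)),
    )
    if rule.general_type not in GENERAL_TYPES:
        raise ValueError(f"rule {rule.label}: unknown general type {rule.general_type}")
    bad = rule.presence - set(ELEMENT_ORDER)
    if bad:
        raise ValueError(f"rule {rule.label}: unknown elements {sorted(bad)}")
    return rule


def load_type_rules(path: str | Path | None = None) -> list[TypeRule]:
    """Load a typing rule table (the shipped lacertid table by default).

    Validates label uniqueness and that every subtype maps to exactly one
    general type.
    """
    if path is None:
        src = resources.files("mitocr.data").joinpath("cr_type_rules.yaml")
        with src.open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    rules = [_as_rule(e) for e in raw["rules"]]
    labels = [r.label for r in rules]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate subtype labels in rule table")
    for r in rules:
        if not r.label.startswith(r.general_type + "-"):
            raise ValueError(
                f"rule {r.label}: label does not belong to general type {r.general_type}"
            )
    return rules


def classify_cr(profile: CRProfile, rules: list[TypeRule]) -> CRTypeAssignment:
    """Classify a profile: the highest-priority satisfied rule wins.

    No satisfied rule yields "unclassified"; two satisfied rules sharing the
    top priority raise :class:`AmbiguousRuleError`.
    """
    satisfied = [r for r in rules if r.matches(profile)]
    if not satisfied:
        return CRTypeAssignment(
            record_id=profile.record_id,
            general_type="unclassified",
            subtype="unclassified",
            matched_rule=None,
        )
    top = max(r.priority for r in satisfied)
    winners = [r for r in satisfied if r.priority == top]
    if len(winners) > 1:
        raise AmbiguousRuleError(
            "ambiguous classification; equal-priority rules: "
            + ", ".join(r.label for r in winners)
        )
    rule = winners[0]
    return CRTypeAssignment(
        record_id=profile.record_id,
        general_type=rule.general_type,
        subtype=rule.label,
        matched_rule=rule.label,
    )


# ---------------------------------------------------------------------------
# Layout-profile fixture and the type map
# ---------------------------------------------------------------------------

def load_layout_profiles(path: str | Path | None = None) -> list[dict]:
    """Load the shipped CR layout-profile fixture.

    Each row carries a profile id, the layout fields (presence, order flag,
    TR class sets), the subtype the layout is meant to represent and the
    species reported with that subtype; returns a list of dicts with a
    ``profile`` (CRProfile) plus ``expected_subtype`` / ``species`` metadata.
    """
    if path is None:
        ctx = resources.as_file(
            resources.files("mitocr.data").joinpath("lacertidae_cr_layout_profiles.tsv")
        )
        with ctx as p:
            return load_layout_profiles(p)
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        ):
            present = frozenset(
                e.strip() for e in row["present"].split(",") if e.strip()
            )
            profile = CRProfile(
                record_id=row["profile_id"],
                element_presence={e: e in present for e in ELEMENT_ORDER},
                element_order_ok=row["order_ok"].strip().lower() == "true",
                anormal_tr_classes=frozenset(
                    c.strip() for c in row["anormal"].split(",") if c.strip()
                ),
                normal_tr_classes=frozenset(
                    c.strip() for c in row["normal"].split(",") if c.strip()
                ),
                cr_length=int(row.get("cr_length") or 0),
            )
            out.append(
                {
                    "profile": profile,
                    "expected_subtype": row["subtype"],
                    "species": tuple(
                        s.strip() for s in row["species"].split(";") if s.strip()
                    ),
                }
            )
    return out


def type_map_table(
    assignments: list[CRTypeAssignment],
    taxon_list: list[tuple[str, str]] | None = None,
):
    """Per-taxon type map as a pandas DataFrame.

    ``taxon_list`` pairs (taxon, record_id); taxa whose record has no
    assignment (e.g. incomplete CR) are flagged "N.A.".  Without a taxon
    list, one row per assignment keyed by record id.
    """
    import pandas as pd

    by_id = {a.record_id: a for a in assignments}
    rows = []
    if taxon_list is None:
        taxon_list = [(a.record_id, a.record_id) for a in assignments]
    for taxon, rid in taxon_list:
        a = by_id.get(rid)
        if a is None:
            rows.append({"taxon": taxon, "general_type": "N.A.", "subtype": "N.A."})
        else:
            rows.append(
                {"taxon": taxon, "general_type": a.general_type, "subtype": a.subtype}
            )
    return pd.DataFrame(rows, columns=["taxon", "general_type", "subtype"])
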