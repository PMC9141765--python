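"""Seeded generators for synthetic mitogenomes, control regions and codon
alignments with machine-checkable ground truth.

Every generator is deterministic given (spec, seed): one integer seed drives
one pseudo-random stream per artifact, and fields are always drawn in a fixed
order so extending a spec does not shift earlier draws.

The CR generator places conserved elements (optionally with prescribed
dot-pattern variants), inter-element spacers and tandem-repeat arrays per a
:class:`CRSpec`, and returns the exact layout as ground truth.  Spacers are
composition-controlled random sequence, rejection-sampled to be free of
tandem repeats and of accidental element matches, and the bases flanking
each repeat array are constrained to break the array's periodicity so that a
detector with edge trimming recovers the array interval exactly.

The mitogenome generator lays out the canonical 37-gene vertebrate order
with configurable gene overlaps (the ATP8/ATP6 junction instantiates the
conserved ATGGNNNTAA overlap motif), an OL motif, valid start/stop codons,
stop-free PCG interiors and a CR built by the CR generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .composition import STOP_CODONS, translate_codon
from .elements import (
    DEFAULT_MAX_MISMATCHES,
    ELEMENT_ORDER,
    REFERENCE_MOTIFS,
    expand_dots,
    fuzzy_find,
)
from .model import (
    CANONICAL_GENE_ORDER,
    OL_MOTIF_26,
    PCG_NAMES,
    GeneFeature,
    MitogenomeRecord,
    revcomp,
)
from .repeats import find_tandem_repeats

__all__ = [
    "TRArraySpec",
    "CRSpec",
    "CRGroundTruth",
    "SyntheticSpec",
    "MitogenomeGroundTruth",
    "CR_PRESETS",
    "generate_cr",
    "generate_mitogenome",
    "simulate_codon_alignment",
    "cr_spec_for_subtype",
    "write_ground_truth",
]

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TRArraySpec:
    """A tandem-repeat array to embed, keyed by its position class."""

    position_class: str
    unit: str
    copies: int = 3
    error_rate: float = 0.0


@dataclass(frozen=True)
class CRSpec:
    """Layout of a synthetic control region.

    ``elements`` lists (element, dot_pattern) in placement order; a None
    pattern embeds the reference motif.  ``gaps`` overrides the spacer length
    of a specific inter-element zone by its position class (e.g.
    ``between_CSB2_CSB3: 35``).  TR arrays are attached to their position
    class; the zone is then rendered spacer + array + spacer.
    """

    elements: tuple[tuple[str, str | None], ...] = tuple(
        (e, None) for e in ELEMENT_ORDER
    )
    trs: tuple[TRArraySpec, ...] = ()
    gaps: tuple[tuple[str, int], ...] = ()
    default_gap: int = 45
    lead: int = 50
    tail: int = 60
    at_percent: float = 65.0

    def gap_for(self, zone: str) -> int:
        return dict(self.gaps).get(zone, self.default_gap)


@dataclass
class CRGroundTruth:
    """Exact layout of a generated CR."""

    length: int = 0
    elements: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    trs: list[dict] = field(default_factory=list)
    at_percent: float = 0.0


#: Preset CR layouts modelled on lacertid genera.  Eremias: normal TRs
#: before TAS1 and after CSB3 (unit TAGCGGCTTTTTTG), 35 nt CSB2-CSB3 gap.
#: Darevskia: genus-specific TAS2/CSB1 variants, anormal TR between CSB1 and
#: CSB2 (unit CAAAACTTTTAA), 35 nt CSB2-CSB3 gap.  Takydromus: normal TR
#: before TAS1 (unit GCGGCTT) plus an anormal TTTTCC array between TAS2 and
#: CSB1.  minimal_V: a defective scaffold retaining only CSB2+CSB3.
CR_PRESETS: dict[str, CRSpec] = {
    "eremias_typical": CRSpec(
        trs=(
            TRArraySpec("before_TAS1", "TAGCGGCTTTTTTG", 3),
            TRArraySpec("after_CSB3", "TAGCGGCTTTTTTG", 3),
        ),
        gaps=(("between_CSB2_CSB3", 35),),
    ),
    "darevskia_typical": CRSpec(
        elements=(
            ("TAS1", None),
            ("TAS2", "T··G······"),
            ("CSB1", "···············C·T····················"),
            ("CSB2", None),
            ("CSB3", None),
        ),
        trs=(TRArraySpec("between_CSB1_CSB2", "CAAAACTTTTAA", 3),),
        gaps=(("between_CSB2_CSB3", 35),),
    ),
    "takydromus_typical": CRSpec(
        trs=(
            TRArraySpec("before_TAS1", "GCGGCTT", 4),
            TRArraySpec("between_TAS2_CSB1", "TTTTCC", 4),
        ),
    ),
    "minimal_V": CRSpec(
        elements=(("CSB2", None), ("CSB3", None)),
        gaps=(("between_CSB2_CSB3", 35),),
    ),
}


# ---------------------------------------------------------------------------
# Random sequence helpers
# ---------------------------------------------------------------------------

def _base_probs(at_percent: float) -> np.ndarray:
    at = at_percent / 100.0
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])


def _random_seq(rng: np.random.Generator, length: int, at_percent: float) -> str:
    if length <= 0:
        return ""
    idx = rng.choice(4, size=length, p=_base_probs(at_percent))
    return "".join(_BASES[i] for i in idx)


def _spacer_is_clean(seq: str) -> bool:
    if len(seq) >= 20 and find_tandem_repeats(seq):
        return False
    for element, ref in REFERENCE_MOTIFS.items():
        if len(seq) >= len(ref) and fuzzy_find(
            seq, element, DEFAULT_MAX_MISMATCHES[element]
        ):
            return False
    return True


def _blocked_periods(unit_len: int, array_len: int) -> list[int]:
    """Periods whose flanking continuation must be broken around an array."""
    out = []
    k = 1
    while array_len / (k * unit_len) >= 1.5 and k * unit_len <= array_len // 2:
        out.append(k * unit_len)
        k += 1
    return out or [unit_len]


def _gen_spacer(
    rng: np.random.Generator,
    length: int,
    at_percent: float,
    built: str,
    left_block: list[int] | None = None,
    right_block: tuple[list[int], str] | None = None,
) -> str:
    """A clean spacer with periodicity-breaking constraints at TR boundaries.

    ``left_block`` lists periods of an array immediately to the left: the
    leading spacer bases are forced to differ from the base one such period
    back in the already-built sequence.  ``right_block`` = (periods, array)
    for an array immediately to the right: trailing spacer bases are forced
    to differ from the base one period ahead inside that array.
    """
    if length < 0:
        raise ValueError("negative spacer length (layout not realizable)")
    if length == 0:
        return ""
    probs = _base_probs(at_percent)
    for _ in range(200):
        cand = list(_random_seq(rng, length, at_percent))
        if left_block:
            horizon = min(length, max(left_block))
            for j in range(horizon):
                targets = set()
                for p in left_block:
                    pos = len(built) + j - p
                    if 0 <= pos < len(built):
                        targets.add(built[pos])
                    elif pos >= len(built):  # inside this spacer
                        targets.add(cand[pos - len(built)])
                cand[j] = _draw_avoiding(rng, probs, targets, cand[j])
        if right_block:
            periods, array = right_block
            horizon = min(length, max(periods))
            for j in range(length - horizon, length):
                targets = set()
                for p in periods:
                    off = j + p - length
                    if 0 <= off < len(array):
                        targets.add(array[off])
                cand[j] = _draw_avoiding(rng, probs, targets, cand[j])
        seq = "".join(cand)
        if _spacer_is_clean(seq):
            return seq
    raise RuntimeError("could not generate a clean spacer (layout too constrained)")


def _draw_avoiding(
    rng: np.random.Generator, probs: np.ndarray, targets: set, current: str
) -> str:
    allowed = [i for i, b in enumerate(_BASES) if b not in targets]
    if not allowed:  # all four bases constrained: keep the least-blocked draw
        return current
    w = probs[allowed]
    return _BASES[allowed[int(rng.choice(len(allowed), p=w / w.sum()))]]


def _materialize_tr(rng: np.random.Generator, spec: TRArraySpec) -> str:
    if spec.copies < 2:
        raise ValueError("a tandem-repeat array needs at least 2 copies")
    unit = spec.unit.upper()
    reps = math.ceil(spec.copies)
    seq = list((unit * reps)[: round(spec.copies * len(unit))])
    if spec.error_rate > 0:
        for i in range(len(unit), len(seq)):  # first copy kept intact
            if rng.random() < spec.error_rate:
                seq[i] = rng.choice([b for b in _BASES if b != seq[i]])
    return "".join(seq)


# ---------------------------------------------------------------------------
# Control-region generation
# ---------------------------------------------------------------------------

def _zone_name(left: str | None, right: str | None) -> str:
    if left is None:
        return "before_TAS1" if right == "TAS1" else f"before_{right}"
    if right is None:
        return "after_CSB3" if left == "CSB3" else f"after_{left}"
    return f"between_{left}_{right}"


def generate_cr(
    spec: CRSpec, seed: int, extra_tail: int = 0
) -> tuple[str, CRGroundTruth]:
    """Generate a CR sequence and its exact ground-truth annotation.

    Elements are placed in the order given by ``spec.elements``, separated by
    the configured spacer lengths; each TR array is rendered inside its
    position-class zone flanked by constrained spacers.  Raises when a TR's
    position class matches no zone of the layout.
    """
    rng = np.random.default_rng([int(seed), 0x_C0])
    names = [e for e, _ in spec.elements]
    if len(set(names)) != len(names):
        raise ValueError("duplicate element in CRSpec")
    zones: list[str] = []
    zones.append(_zone_name(None, names[0] if names else None))
    for a, b in zip(names, names[1:]):
        zones.append(_zone_name(a, b))
    if names:
        zones.append(_zone_name(names[-1], None))
    trs_by_zone: dict[str, list[TRArraySpec]] = {}
    for tr in spec.trs:
        if tr.position_class not in zones:
            raise ValueError(
                f"TR position class {tr.position_class!r} matches no zone of "
                f"this layout ({zones})"
            )
        trs_by_zone.setdefault(tr.position_class, []).append(tr)

    gt = CRGroundTruth(at_percent=spec.at_percent)
    parts: list[str] = []
    pos = 0

    def emit(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    def emit_zone(zone: str, base_gap: int, tail_pad: int = 0) -> None:
        arrays = trs_by_zone.get(zone, [])
        built = "".join(parts)
        if not arrays:
            emit(_gen_spacer(rng, base_gap + tail_pad, spec.at_percent, built))
            return
        g = max(12, base_gap // 2)
        prev_block: list[int] | None = None
        for tr in arrays:
            array = _materialize_tr(rng, tr)
            blocks = _blocked_periods(len(tr.unit), len(array))
            built = "".join(parts)
            emit(
                _gen_spacer(
                    rng, g, spec.at_percent, built,
                    left_block=prev_block, right_block=(blocks, array),
                )
            )
            gt.trs.append(
                {
                    "position_class": zone,
                    "start": pos,
                    "end": pos + len(array),
                    "period": len(tr.unit),
                    "copies": tr.copies,
                    "unit": tr.unit,
                }
            )
            emit(array)
            prev_block = blocks
        built = "".join(parts)
        emit(
            _gen_spacer(
                rng, g + tail_pad, spec.at_percent, built, left_block=prev_block
            )
        )

    # leading zone
    emit_zone(zones[0], spec.gap_for(zones[0]) if zones[0] in dict(spec.gaps) else spec.lead)
    for i, (name, pattern) in enumerate(spec.elements):
        ref = REFERENCE_MOTIFS[name]
        motif = expand_dots(pattern, ref) if pattern else ref
        gt.elements[name] = (pos, pos + len(motif), motif)
        emit(motif)
        zone = zones[i + 1]
        is_last = i == len(spec.elements) - 1
        base_gap = spec.tail if is_last and zone not in dict(spec.gaps) else spec.gap_for(zone)
        emit_zone(zone, base_gap, tail_pad=extra_tail if is_last else 0)
    seq = "".join(parts)
    gt.length = len(seq)
    return seq, gt


# ---------------------------------------------------------------------------
# Mitogenome generation
# ---------------------------------------------------------------------------

#: Default gene lengths (nt); PCG lengths are multiples of 3.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "rrnS": 951, "rrnL": 1540, "OL": 30,
    "ND1": 966, "ND2": 1035, "COI": 1551, "COII": 684, "ATP8": 165,
    "ATP6": 684, "COIII": 786, "ND3": 348, "ND4L": 294, "ND4": 1374,
    "ND5": 1824, "ND6": 516, "CYTB": 1140,
    "trnS1": 66,
}
_DEFAULT_TRNA_LEN = 68

#: Default gene overlaps (gene_a, gene_b) -> length; the ATP8/ATP6 junction
#: additionally instantiates the conserved overlap motif.
DEFAULT_OVERLAPS: dict[tuple[str, str], int] = {
    ("ATP8", "ATP6"): 10,
    ("ATP6", "COIII"): 1,
    ("ND4L", "ND4"): 7,
    ("ND5", "ND6"): 5,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic mitogenome."""

    record_id: str = "SYN1"
    taxon: str = "synthetic lacertid"
    cr_preset: str = "eremias_typical"
    cr_spec: CRSpec | None = None  # overrides cr_preset when given
    overlaps: tuple[tuple[tuple[str, str], int], ...] = tuple(
        DEFAULT_OVERLAPS.items()
    )
    gene_lengths: tuple[tuple[str, int], ...] = ()
    include_ol_motif: bool = True
    ol_pattern: str = OL_MOTIF_26
    genome_length: int | None = None  # pad the CR tail up to this total
    at_percent: float = 60.0

    def resolved_cr_spec(self) -> CRSpec:
        return self.cr_spec if self.cr_spec is not None else CR_PRESETS[self.cr_preset]


@dataclass
class MitogenomeGroundTruth:
    """Exact layout of a generated mitogenome."""

    features: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    overlaps: dict[str, int] = field(default_factory=dict)  # "A|B" -> length
    ol_motif: str = ""
    ol_motif_start: int = -1
    cr: CRGroundTruth | None = None
    cr_interval: tuple[int, int] = (0, 0)
    genome_length: int = 0


def _random_sense_codons(rng: np.random.Generator, n: int) -> str:
    sense = [c for c in _all_codons() if c not in STOP_CODONS]
    return "".join(sense[int(i)] for i in rng.integers(0, len(sense), size=n))


def _all_codons() -> list[str]:
    return [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def generate_mitogenome(
    spec: SyntheticSpec, seed: int
) -> tuple[MitogenomeRecord, MitogenomeGroundTruth]:
    """Generate a circular annotated mitogenome with ground truth.

    The 37 genes follow the canonical vertebrate order starting at tRNA-Phe;
    configured overlaps shift the downstream gene's start back over its
    neighbour, PCG interiors are stop-free in-frame codons, start/stop codons
    and the ATP8/ATP6 overlap motif are stamped explicitly, the OL motif (N
    positions instantiated) is embedded in the OL locus and the CR is built
    by :func:`generate_cr` between tRNA-Pro and the origin.
    """
    rng = np.random.default_rng([int(seed), 0x_9E])
    overlaps = dict(spec.overlaps)
    lengths = dict(DEFAULT_GENE_LENGTHS)
    lengths.update(dict(spec.gene_lengths))

    order = [(g, s) for g, s in CANONICAL_GENE_ORDER if g != "CR"]
    features: list[GeneFeature] = []
    cursor = 0
    prev_name: str | None = None
    for name, strand in order:
        glen = lengths.get(name, _DEFAULT_TRNA_LEN)
        start = cursor
        if prev_name is not None and (prev_name, name) in overlaps:
            start = cursor - overlaps[(prev_name, name)]
            if start < 0:
                raise ValueError(f"overlap before origin at {prev_name}/{name}")
        features.append(GeneFeature(name=name, strand=strand, start=start, end=start + glen))
        cursor = start + glen
        prev_name = name

    # CR occupies [cursor, genome end); tRNA-Phe restarts at 0 on the circle.
    cr_spec = spec.resolved_cr_spec()
    extra = 0
    if spec.genome_length is not None:
        probe, _ = generate_cr(cr_spec, seed)
        extra = spec.genome_length - cursor - len(probe)
        if extra < 0:
            raise ValueError(
                f"genome_length {spec.genome_length} below minimal layout "
                f"({cursor + len(probe)})"
            )
    cr_seq, cr_gt = generate_cr(cr_spec, seed, extra_tail=extra)
    total = cursor + len(cr_seq)
    features.append(GeneFeature(name="CR", strand="H", start=cursor, end=total))

    genome = list(_random_seq(rng, total, spec.at_percent))

    def stamp(s: int, text: str) -> None:
        genome[s : s + len(text)] = list(text)

    by_name = {f.name: f for f in features}
    pcgs = [f for f in features if f.name in PCG_NAMES]
    # stop-free in-frame interiors
    for f in pcgs:
        codons = _random_sense_codons(rng, f.length() // 3)
        stamp(f.start, codons if f.strand == "H" else revcomp(codons))
    # start / stop codons
    for f in pcgs:
        if f.strand == "H":
            stamp(f.start, "GTG" if f.name == "COI" else "ATG")
            stamp(f.end - 3, "TAA")
        else:  # ND6: AGG stop dovetails with the ND5 TAA stop
            stamp(f.end - 3, revcomp("ATG"))
            stamp(f.start, revcomp("AGG"))
    if ("ND5", "ND6") in overlaps:
        stamp(by_name["ND5"].end - 3, "TAA")
    # ATP8/ATP6 junction motif with instantiated wildcards
    gt = MitogenomeGroundTruth()
    if ("ATP8", "ATP6") in overlaps and overlaps[("ATP8", "ATP6")] == 10:
        inner = _random_seq(rng, 3, 50.0)
        stamp(by_name["ATP6"].start, "ATGG" + inner + "TAA")
    # OL motif
    if spec.include_ol_motif:
        motif = "".join(
            b if b != "N" else _BASES[int(rng.integers(0, 4))]
            for b in spec.ol_pattern
        )
        ol = by_name["OL"]
        off = (ol.length() - len(motif)) // 2
        stamp(ol.start + off, motif)
        gt.ol_motif = motif
        gt.ol_motif_start = ol.start + off
    # control region content
    stamp(cursor, cr_seq)

    record = MitogenomeRecord(
        record_id=spec.record_id,
        sequence="".join(genome),
        circular=True,
        features=features,
        taxon=spec.taxon,
    )
    gt.features = {f.name: (f.start, f.end, f.strand) for f in features}
    gt.overlaps = {f"{a}|{b}": n for (a, b), n in overlaps.items()}
    gt.cr = cr_gt
    gt.cr_interval = (cursor, total)
    gt.genome_length = total
    return record, gt


# ---------------------------------------------------------------------------
# Codon-alignment simulation
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    n_taxa: int,
    n_codons: int,
    syn_rate: float,
    nonsyn_rate: float,
    seed: int,
) -> tuple[list[tuple[str, str]], dict]:
    """Star-tree codon alignment simulation under the vertebrate mito code.

    From a random stop-free ancestral CDS, each taxon independently receives
    mutations: at every codon position a uniformly random alternative base is
    proposed and accepted with probability ``syn_rate`` if the change is
    synonymous or ``nonsyn_rate`` if nonsynonymous (rates are per-position
    acceptance probabilities in [0, 1]; proposals creating stop codons are
    rejected).  Returns the alignment and ground-truth counts of applied
    synonymous / nonsynonymous changes.
    """
    if n_codons < 1 or n_taxa < 1:
        raise ValueError("need n_taxa >= 1 and n_codons >= 1")
    if not (0 <= syn_rate <= 1 and 0 <= nonsyn_rate <= 1):
        raise ValueError("rates are acceptance probabilities in [0, 1]")
    rng = np.random.default_rng([int(seed), 0x_A1])
    ancestral = _random_sense_codons(rng, n_codons)
    taxa: list[tuple[str, str]] = []
    syn_applied = nonsyn_applied = 0
    for t in range(n_taxa):
        seq = list(ancestral)
        for ci in range(n_codons):
            for pos in range(3):
                u = rng.random()
                prop = _BASES[int(rng.integers(0, 4))]
                idx = 3 * ci + pos
                if prop == seq[idx]:
                    continue
                codon = "".join(seq[3 * ci : 3 * ci + 3])
                new = codon[:pos] + prop + codon[pos + 1 :]
                if new in STOP_CODONS:
                    continue
                syn = translate_codon(new) == translate_codon(codon)
                accept = u < (syn_rate if syn else nonsyn_rate)
                if accept:
                    seq[idx] = prop
                    if syn:
                        syn_applied += 1
                    else:
                        nonsyn_applied += 1
        taxa.append((f"taxon{t + 1}", "".join(seq)))
    truth = {
        "ancestral": ancestral,
        "syn_applied": syn_applied,
        "nonsyn_applied": nonsyn_applied,
    }
    return taxa, truth


# ---------------------------------------------------------------------------
# Subtype round-trip support and ground-truth sidecars
# ---------------------------------------------------------------------------

_NORMAL_UNIT = "TAGCGGCTTTTTTG"
_ANORMAL_UNITS = {
    "between_TAS1_TAS2": "CAAAACTTTTAA",
    "between_TAS2_CSB1": "TTTTCC",
    "between_CSB1_CSB2": "CAAAACTTTTAA",
    "between_CSB2_CSB3": "CAAAACTTTTAA",
}


def cr_spec_for_subtype(rule) -> CRSpec:
    """Build a CRSpec whose annotation classifies back to ``rule``.

    Presence comes from the rule's element set; a False ``order_ok`` swaps
    the first two elements; anormal/normal TR classes get default diagnostic
    units (four copies for the short TTTTCC unit, three otherwise).
    """
    present = [e for e in ELEMENT_ORDER if e in rule.presence]
    if rule.order_ok is False:
        if len(present) < 2:
            raise ValueError("cannot scramble order with fewer than 2 elements")
        present[0], present[1] = present[1], present[0]
    trs: list[TRArraySpec] = []
    for cls in sorted(rule.normal or ()):
        trs.append(TRArraySpec(cls, _NORMAL_UNIT, 3))
    for cls in sorted(rule.anormal or ()):
        unit = _ANORMAL_UNITS[cls]
        trs.append(TRArraySpec(cls, unit, 4 if len(unit) < 10 else 3))
    return CRSpec(
        elements=tuple((e, None) for e in present),
        trs=tuple(trs),
        gaps=(("between_CSB2_CSB3", 35),) if rule.order_ok is not False else (),
    )


def write_ground_truth(gt, path: str | Path) -> None:
    """Write a generator ground-truth object as a JSON sidecar."""
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (set, frozenset, tuple)):
            return list(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(gt, fh, indent=1, default=default, sort_keys=True)
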