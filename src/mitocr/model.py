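"""Data model and I/O for annotated vertebrate mitochondrial genomes.

The vertebrate mitogenome is a circular molecule of roughly 17-21 kb carrying
a canonical set of 37 genes (13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus
two non-coding loci: the light-strand replication origin (OL) and the long
control region (CR) between tRNA-Pro and tRNA-Phe.  This module defines the
in-memory representation (:class:`MitogenomeRecord`, :class:`GeneFeature`),
GenBank/FASTA I/O through Biopython, control-region extraction, gene-overlap
scanning and OL-motif scanning.

Coordinates are 0-based half-open on the heavy (H) strand throughout; GenBank
1-based inclusive coordinates are converted at the I/O boundary.  A feature
spanning the origin of the circular molecule is represented with
``wraps_origin=True`` and ``end`` < ``start`` interpreted modulo the genome
length (never by doubling the sequence).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "MitogenomeRecord",
    "ControlRegion",
    "OverlapRecord",
    "OLHit",
    "GenBankParseError",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "CANONICAL_GENE_ORDER",
    "LIGHT_STRAND_GENES",
    "OL_MOTIF_26",
    "OL_MOTIF_25",
    "OVERLAP_MOTIFS",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "extract_control_region",
    "scan_gene_overlaps",
    "scan_ol_motif",
    "levenshtein",
]


# ---------------------------------------------------------------------------
# Controlled vocabulary and canonical gene order
# ---------------------------------------------------------------------------

PCG_NAMES = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "ATP6", "ATP8", "COI", "COII", "COIII", "CYTB",
)

#: tRNA names; Ser1 = AGN family (next to tRNA-His), Ser2 = UCN family (after
#: COI); Leu1 = CUN family, Leu2 = UUR family (after the 16S rRNA).
TRNA_NAMES = (
    "trnF", "trnV", "trnL2", "trnI", "trnQ", "trnM", "trnW", "trnA",
    "trnN", "trnC", "trnY", "trnS2", "trnD", "trnK", "trnG", "trnR",
    "trnH", "trnS1", "trnL1", "trnE", "trnT", "trnP",
)

RRNA_NAMES = ("rrnS", "rrnL")

GENE_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES
ALL_FEATURE_NAMES = GENE_NAMES + ("OL", "CR")

#: Canonical vertebrate mitochondrial gene order starting at tRNA-Phe, with
#: the strand each gene is encoded on.  ND6 and eight tRNAs sit on the light
#: (L) strand; everything else on the heavy (H) strand.
CANONICAL_GENE_ORDER: tuple[tuple[str, str], ...] = (
    ("trnF", "H"), ("rrnS", "H"), ("trnV", "H"), ("rrnL", "H"),
    ("trnL2", "H"), ("ND1", "H"), ("trnI", "H"), ("trnQ", "L"),
    ("trnM", "H"), ("ND2", "H"), ("trnW", "H"), ("trnA", "L"),
    ("trnN", "L"), ("OL", "H"), ("trnC", "L"), ("trnY", "L"),
    ("COI", "H"), ("trnS2", "L"), ("trnD", "H"), ("COII", "H"),
    ("trnK", "H"), ("ATP8", "H"), ("ATP6", "H"), ("COIII", "H"),
    ("trnG", "H"), ("ND3", "H"), ("trnR", "H"), ("ND4L", "H"),
    ("ND4", "H"), ("trnH", "H"), ("trnS1", "H"), ("trnL1", "H"),
    ("ND5", "H"), ("ND6", "L"), ("trnE", "L"), ("CYTB", "H"),
    ("trnT", "H"), ("trnP", "L"), ("CR", "H"),
)

LIGHT_STRAND_GENES = frozenset(
    name for name, strand in CANONICAL_GENE_ORDER if strand == "L"
)

#: The two OL motif variants observed among the racerunner mitogenomes: a
#: 26 nt pattern with five wildcard positions and a 25 nt pattern with four.
OL_MOTIF_26 = "TTCCCCCGTTANNNNNAAAACGGGGG"
OL_MOTIF_25 = "TTCCCCCGTTANNNNAAAACGGGGG"

#: Conserved ATP8/ATP6 overlap motifs (N = any base).
OVERLAP_MOTIFS = ("ATGGNNNTAA", "ATGANTAA")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def levenshtein(a: str, b: str) -> int:
    """Plain edit distance (substitutions, insertions, deletions)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class GenBankParseError(ValueError):
    """Raised when a GenBank record cannot be interpreted."""


@dataclass
class GeneFeature:
    """A located gene (or OL/CR) on the H-strand coordinate system.

    ``start``/``end`` are 0-based half-open.  For a feature spanning the
    origin of the circular genome, ``wraps_origin`` is True and ``end`` is
    the post-wrap coordinate (``end`` <= ``start``).
    """

    name: str
    strand: str  # "H" or "L"
    start: int
    end: int
    wraps_origin: bool = False
    known: bool = True  # False for names outside the controlled vocabulary

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if not self.wraps_origin and self.end <= self.start:
            raise ValueError(
                f"{self.name}: end ({self.end}) must exceed start ({self.start}) "
                "unless wraps_origin"
            )

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start
        if genome_length is None:
            raise ValueError("genome_length required for a wrapping feature")
        return genome_length - self.start + self.end

    def extract(self, sequence: str) -> str:
        """H-strand sequence of the feature (wrap-aware)."""
        if self.wraps_origin:
            return sequence[self.start:] + sequence[: self.end]
        return sequence[self.start : self.end]


@dataclass
class MitogenomeRecord:
    """A (typically circular) mitochondrial genome with its feature table."""

    record_id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        seen: set[str] = set()
        for f in self.features:
            if not (0 <= f.start < n) or not (0 < f.end <= n):
                raise ValueError(
                    f"{f.name}: interval [{f.start}, {f.end}) outside genome of {n} nt"
                )
            if f.wraps_origin and not self.circular:
                raise ValueError(f"{f.name}: wrapping feature on a linear record")
            if f.known and f.name in ALL_FEATURE_NAMES:
                if f.name in seen:
                    raise ValueError(f"duplicate canonical feature {f.name}")
                seen.add(f.name)

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def feature_seq(self, name: str) -> str:
        f = self.feature(name)
        if f is None:
            raise KeyError(name)
        s = f.extract(self.sequence)
        return revcomp(s) if f.strand == "L" else s


@dataclass
class ControlRegion:
    """The control region located between tRNA-Pro and tRNA-Phe."""

    record_id: str
    start: int
    end: int
    length: int
    wraps_origin: bool
    sequence: str


@dataclass
class OverlapRecord:
    """An intersection between two gene intervals."""

    gene_a: str
    gene_b: str
    overlap_length: int
    overlap_sequence: str
    motif_class: str  # "ATGGNNNTAA", "ATGANTAA" or "none"

    def __post_init__(self) -> None:
        if self.overlap_length < 1:
            raise ValueError("overlap_length must be >= 1")
        if len(self.overlap_sequence) != self.overlap_length:
            raise ValueError("overlap_sequence length must equal overlap_length")


@dataclass
class OLHit:
    """A match of one of the OL motif patterns on the H-strand."""

    start: int
    end: int
    matched_motif: str
    pattern_length: int


# ---------------------------------------------------------------------------
# Name normalization and the synonym table
# ---------------------------------------------------------------------------

def _normalize(label: str) -> str:
    return re.sub(r"[^A-Z0-9]", "", label.upper())


def _load_synonyms() -> dict[str, str]:
    with resources.files("mitocr.data").joinpath("gene_synonyms.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    table: dict[str, str] = {}
    for canonical, aliases in raw.items():
        table[_normalize(canonical)] = canonical
        for alias in aliases or []:
            table[_normalize(str(alias))] = canonical
    return table


_SYNONYMS: dict[str, str] | None = None


def resolve_gene_name(label: str) -> str | None:
    """Map a GenBank gene/product label to the controlled vocabulary.

    Returns None when the label is not recognized (the caller keeps the
    feature with ``known=False`` rather than dropping it).
    """
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    return _SYNONYMS.get(_normalize(label))


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "D-loop", "rep_origin", "misc_feature", "gene"}


def _feature_label(feat: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    if feat.type == "D-loop":
        return "D-loop"
    if feat.type == "rep_origin":
        return "OL"
    return None


def _location_to_interval(loc, genome_length: int) -> tuple[int, int, bool]:
    """Convert a Biopython location to (start, end, wraps_origin)."""
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if (
            len(parts) == 2
            and int(parts[1].end) == genome_length
            and int(parts[0].start) == 0
        ):
            return int(parts[1].start), int(parts[0].end), True
        return int(parts[0].start), int(parts[-1].end), False
    return int(loc.start), int(loc.end), False


def read_genbank(path: str | Path) -> list[MitogenomeRecord]:
    """Read one or more annotated mitogenomes from a GenBank flat file.

    Feature labels are mapped onto the controlled vocabulary through the
    shipped synonym table (e.g. "COX1" -> COI, "D-loop" -> CR); unrecognized
    features are retained with ``known=False`` and a warning.  Raises
    :class:`GenBankParseError` for records without sequence (missing ORIGIN)
    or with unparseable feature coordinates.
    """
    records: list[MitogenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        try:
            seq = str(rec.seq)
        except UndefinedSequenceError as exc:
            raise GenBankParseError(f"{rec.id}: missing ORIGIN sequence") from exc
        if not seq:
            raise GenBankParseError(f"{rec.id}: missing ORIGIN sequence")
        n = len(seq)
        circular = rec.annotations.get("topology", "circular") == "circular"
        features: list[GeneFeature] = []
        seen_intervals: set[tuple[str, int, int]] = set()
        for feat in rec.features:
            if feat.type not in _FEATURE_TYPES or feat.type == "gene":
                # "gene" features duplicate CDS/tRNA/rRNA spans
                continue
            label = _feature_label(feat)
            if label is None:
                continue
            try:
                start, end, wraps = _location_to_interval(feat.location, n)
            except Exception as exc:
                raise GenBankParseError(
                    f"{rec.id}: malformed location for {label!r}"
                ) from exc
            canonical = resolve_gene_name(label)
            strand = "L" if feat.location.strand == -1 else "H"
            name = canonical if canonical is not None else label
            if canonical is None:
                warnings.warn(
                    f"{rec.id}: unknown feature label {label!r} retained as-is",
                    stacklevel=2,
                )
            key = (name, start, end)
            if key in seen_intervals:
                continue
            seen_intervals.add(key)
            features.append(
                GeneFeature(
                    name=name,
                    strand=strand,
                    start=start,
                    end=end,
                    wraps_origin=wraps,
                    known=canonical is not None,
                )
            )
        features.sort(key=lambda f: f.start)
        records.append(
            MitogenomeRecord(
                record_id=rec.id or rec.name,
                sequence=seq,
                circular=circular,
                features=features,
                taxon=rec.annotations.get("organism"),
            )
        )
    if not records:
        raise GenBankParseError(f"no GenBank records parsed from {path}")
    return records


_GB_TYPE = {"OL": "rep_origin", "CR": "D-loop"}


def _gb_feature_type(name: str) -> str:
    if name in PCG_NAMES:
        return "CDS"
    if name in TRNA_NAMES:
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    return _GB_TYPE.get(name, "misc_feature")


def write_genbank(records: Iterable[MitogenomeRecord], path: str | Path) -> None:
    """Write records as a GenBank flat file (round-trips with read_genbank)."""
    out: list[SeqRecord] = []
    for rec in records:
        n = len(rec.sequence)
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.record_id,
            name=re.sub(r"[^A-Za-z0-9_]", "_", rec.record_id)[:16],
            description=rec.taxon or "synthetic mitochondrial genome",
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if rec.circular else "linear",
                "organism": rec.taxon or "synthetic construct",
            },
        )
        for f in rec.features:
            strand = -1 if f.strand == "L" else 1
            if f.wraps_origin:
                loc = CompoundLocation(
                    [
                        SimpleLocation(f.start, n, strand=strand),
                        SimpleLocation(0, f.end, strand=strand),
                    ]
                )
            else:
                loc = SimpleLocation(f.start, f.end, strand=strand)
            sr.features.append(
                SeqFeature(loc, type=_gb_feature_type(f.name), qualifiers={"gene": [f.name]})
            )
        out.append(sr)
    SeqIO.write(out, str(path), "genbank")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as (id, uppercase sequence) pairs."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in entries),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Control-region extraction
# ---------------------------------------------------------------------------

def extract_control_region(record: MitogenomeRecord) -> ControlRegion:
    """Extract the CR as the H-strand interval from the end of tRNA-Pro to
    the start of tRNA-Phe, wrapping the origin when needed.
    """
    trnP = record.feature("trnP")
    trnF = record.feature("trnF")
    if trnP is None:
        raise ValueError(f"{record.record_id}: missing tRNA-Pro (trnP) feature")
    if trnF is None:
        raise ValueError(f"{record.record_id}: missing tRNA-Phe (trnF) feature")
    n = len(record.sequence)
    start = trnP.end % n
    end = trnF.start if trnF.start != 0 else n  # abutting the origin: no wrap
    if start == end:
        raise ValueError(f"{record.record_id}: zero-length control region")
    if start < end:
        wraps = False
        seq = record.sequence[start:end]
    else:
        if not record.circular:
            raise ValueError(
                f"{record.record_id}: CR would wrap the origin of a linear record"
            )
        wraps = True
        seq = record.sequence[start:] + record.sequence[:end]
    return ControlRegion(
        record_id=record.record_id,
        start=start,
        end=end,
        length=len(seq),
        wraps_origin=wraps,
        sequence=seq,
    )


# ---------------------------------------------------------------------------
# Gene-overlap scanning
# ---------------------------------------------------------------------------

def _match_with_N(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        p == "N" or p == s for s, p in zip(seq, pattern)
    )


def classify_overlap_motif(seq: str) -> str:
    for motif in OVERLAP_MOTIFS:
        if _match_with_N(seq, motif):
            return motif
    return "none"


def _unrolled(f: GeneFeature, n: int) -> tuple[int, int]:
    """Feature interval on [0, 2n) so wrap-around intersections are linear."""
    if f.wraps_origin:
        return f.start, f.end + n
    return f.start, f.end


def scan_gene_overlaps(record: MitogenomeRecord) -> list[OverlapRecord]:
    """Report every pairwise intersection between gene feature intervals.

    Works for same- or opposite-strand pairs; the overlap sequence is
    reported on the H-strand.  OL and CR are skipped (they are loci, not
    genes, and the CR by definition abuts its neighbours).
    """
    n = len(record.sequence)
    genes = [f for f in record.features if f.known and f.name in GENE_NAMES]
    genes = sorted(genes, key=lambda f: f.start)
    doubled = record.sequence + record.sequence
    out: list[OverlapRecord] = []
    for i, a in enumerate(genes):
        a0, a1 = _unrolled(a, n)
        for b in genes[i + 1 :]:
            b0, b1 = _unrolled(b, n)
            # compare on the unrolled circle, considering the wrap copies
            best = 0
            best_lo = 0
            for shift in (0, n, -n):
                lo = max(a0, b0 + shift)
                hi = min(a1, b1 + shift)
                if hi - lo > best:
                    best, best_lo = hi - lo, lo
            if best > 0:
                seq = doubled[best_lo % n : best_lo % n + best]
                out.append(
                    OverlapRecord(
                        gene_a=a.name,
                        gene_b=b.name,
                        overlap_length=best,
                        overlap_sequence=seq,
                        motif_class=classify_overlap_motif(seq),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# OL motif scanning
# ---------------------------------------------------------------------------

def scan_ol_motif(record: MitogenomeRecord | str) -> list[OLHit]:
    """Search the H-strand for both printed OL motif patterns.

    N positions match any base.  On circular records the search window
    extends across the origin (sequence plus a prefix of pattern length - 1,
    transiently).  Coordinates are H-strand positions of the match start.
    """
    if isinstance(record, MitogenomeRecord):
        seq, circular = record.sequence, record.circular
    else:
        seq, circular = record.upper(), False
    hits: list[OLHit] = []
    for pattern in (OL_MOTIF_26, OL_MOTIF_25):
        hay = seq + (seq[: len(pattern) - 1] if circular else "")
        rx = re.compile(pattern.replace("N", "[ACGT]"))
        for m in rx.finditer(hay):
            if m.start() >= len(seq):
                continue
            hits.append(
                OLHit(
                    start=m.start(),
                    end=m.start() + len(pattern),
                    matched_motif=pattern,
                    pattern_length=len(pattern),
                )
            )
    hits.sort(key=lambda h: (h.start, -h.pattern_length))
    return hits
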