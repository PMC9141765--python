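# Methods

This note documents the models and procedures implemented in `mitocr`, the
defaults they ship with, and what the synthetic-data tests do and do not
establish about real data.

## Coordinates and the genome model

All coordinates are 0-based, half-open, on the heavy (H) strand; GenBank's
1-based inclusive convention is converted at the I/O boundary (via
Biopython).  A feature spanning the origin of a circular molecule carries a
`wraps_origin` flag rather than a doubled sequence; motif scanners append a
transient prefix of (pattern length − 1) to search across the origin.  The
controlled vocabulary covers the 37 canonical genes (with Ser1/Ser2 = AGN /
UCN and Leu1/Leu2 = CUN / UUR disambiguation), OL and CR; GenBank labels are
mapped through an editable synonym table
(`src/mitocr/data/gene_synonyms.yaml`) and unknown labels are retained with
a flag, never dropped, since GenBank dialects vary widely.

The control region is defined as the H-strand interval from the end of
tRNA-Pro to the start of tRNA-Phe (the canonical vertebrate order), wrapping
the origin when necessary.

## Conserved-element annotation

TAS1, TAS2, CSB1, CSB2 and CSB3 are located by substitution-only fuzzy
matching against the *L. dugesii* reference motifs (24, 10, 38, 18 and 20 nt
respectively).  Substitution-only matching is a deliberate model choice:
every published variant of these elements in the lacertid survey encoded
here is length-preserving, so windows of exactly the reference length are
scored by Hamming distance.  Defaults:

* per-element mismatch budget: 25% of motif length, rounded down —
  TAS1 6, TAS2 2, CSB1 9, CSB2 4, CSB3 5.  The most degenerate published
  CSB3 variant (Type 8, 6 substitutions) deliberately exceeds the default
  budget and is reported "novel" unless the caller raises the budget;
* ties among equal-mismatch windows break to the smallest start (5'-most);
* elements are searched in canonical order with each search restricted
  downstream of the previous best hit; this enforces the canonical layout
  and is toggleable (`ordered=False`) for recognizing rearranged CRs.

Two "updated" TAS2 anchors are shipped verbatim alongside the classic
reference because the source survey prints two conflicting spellings of its
proposed update (`TATGCATTAA` in the body, `TATACATTAT` in the abstract);
mismatches are always reported against the classic reference, which is what
the variant tables use.

### Variant tables

The per-element survey tables (types in dot notation with their species
lists) ship as TSV fixtures under `src/mitocr/data/`.  Three TAS2 rows (20,
23, 26) are flagged reconstructions: as printed, they carry letters
identical to the reference base, which would collapse them onto other types
and contradict the survey's own statement that exactly one species carries
the reference TAS2; each such letter was moved by the smallest positional
shift that yields a real, globally unique substitution.  Two other printed
redundancies (TAS1 row 7, CSB3 row 8) do not affect any motif and were
canonicalized to dots.  Classification of an observed motif is an exact
string match over expanded rows; where two rows share a motif the smaller
type id wins.

## Tandem-repeat detection

The detector is a deterministic seed-and-extend scanner (it replaces an
external web service, whose scoring is not reproduced bit-for-bit).  For
period `p`, position `j` of a candidate array is compared with the base one
period earlier; identity of an array is the matching fraction over its
`L − p` comparable positions, so the first copy earns nothing and random
sequence rarely seeds.  A seed requires the second copy to reach the
identity threshold; the array is extended to the longest qualifying length,
then **edge-trimmed**: comparisons that mismatch at either boundary are
dropped, so reported arrays begin and end on period-consistent bases.
Without trimming, a threshold detector absorbs flanking sequence up to its
identity budget and array boundaries become fuzzy.  Overlapping candidates
are pruned keeping the longest array (then highest identity, smallest
period, leftmost start).  The consensus unit is the per-column majority with
alphabetical tie-break.

Defaults: `min_copies=2`, `min_array_length=20 nt`, `min_identity=0.8`,
`max_period=200`.  The copy-number threshold of 2 is a documented choice
(the survey filtered "according to the copy number" without stating the
cutoff).  TR position classes are relative to the annotated elements: a TR
strictly between two canonically adjacent elements is *anormal*
(`between_*`); before TAS1 or after CSB3 is *normal*; anything else —
straddling an element, missing flank, no elements — is `unplaced`.

## CR typing

A CR layout profile records element presence, canonical-order consistency,
and the sets of anormal/normal TR classes.  Classification is rule-driven
from an editable YAML table (`src/mitocr/data/cr_type_rules.yaml`) rather
than hard-coded, because the published typology defines its 21 subtypes
only schematically.  The shipped reconstruction: Types I–IV require the full
ordered scaffold and are distinguished by anormal-TR placement (I none, II
between CSB1/CSB2, III between TAS2/CSB1, IV between CSB2/CSB3), with
subtypes keyed to the normal-TR pattern; Type V covers defective scaffolds,
its eleven subtypes keyed to which elements are missing (or, V-10, present
but out of order).  The highest-priority satisfied rule wins; profiles no
rule covers are reported "unclassified" — never forced into Type V — and
equal-priority ambiguity is an error, not a silent pick.  The shipped
21-profile fixture pairs each subtype with the species reported under it
(one species is reported under two subtypes in the source; the contradiction
is preserved in the annotations).

## Composition, codon usage, distances

Skews are computed from raw counts (the percentage form cancels);
ambiguity codes are excluded, and a skew with zero denominator is flagged
rather than raised.  Codon usage pools in-frame codons across CDSs under
the vertebrate mitochondrial code after trimming incomplete terminal codons
(truncated stops T–– / TA––); internal stops warn with their location.
CDpT spans all codons including terminal stops (so ΣCDpT = 1000); RSCU is
defined within synonymous families with leucine and serine split by codon
box (CUN/UUR, UCN/AGY), matching how mitogenome codon-bias figures are
presented; family means are 1 for observed families.  p-distance excludes
sites with gaps or ambiguity in either sequence.

## dN/dS (Nei–Gojobori 1986)

Site counting: each codon position contributes the fraction of its three
possible changes that are synonymous; changes producing stop codons count
as nonsynonymous; pairwise expected sites are the average over the two
sequences, with S + N = 3 × codons exactly.  Difference counting: codons
differing at k positions average synonymous/nonsynonymous steps over all k!
substitution orders with equal weights; pathways through stop codons are
excluded (all pathways are used if none survive).  Codons with gaps,
ambiguity, or a stop in either sequence are dropped pairwise.  Proportions
receive the Jukes–Cantor correction (undefined at p ≥ 0.75, flagged); raw
proportions are available (`jc_correction=False`) since survey software does
not always state which was used.  The per-gene summary is the arithmetic
mean of pairwise ratios over defined pairs (not a ratio of means), with
undefined pairs counted.  This implementation reproduces an independent
NG86 implementation (Biopython's) to ≤ 1e-9 on simulated pairs, which the
test suite checks.

## Synthetic data

The generators define the test conditions.  `generate_cr` renders a CR as
lead spacer / elements with optional prescribed variant patterns / gap
spacers / TR arrays / tail spacer, with defaults of 45 nt inter-element
gaps, 65% AT spacers (CRs in the family run 58–77% AT), and a 35 nt
CSB2–CSB3 gap in the Eremias/Darevskia/minimal presets (the conserved
spacing in those genera).  Spacers are rejection-sampled to contain no
tandem repeats and no accidental element matches, and the bases flanking
each TR array are constrained to break the array's periodicity (for the
unit period and its relevant multiples), so the edge-trimming detector
recovers embedded arrays exactly.  `generate_mitogenome` lays out the
canonical gene order with realistic default lengths, configured overlaps
(ATP8/ATP6 10 bp via an instantiated ATGGNNNTAA, ND4L/ND4 7 bp, ND5/ND6
5 bp, ATP6/COIII 1 bp), stop-free in-frame PCG interiors, ATG starts (GTG
for COI), TAA stops (AGG for ND6, dovetailing the ND5 stop), an instantiated
OL motif and a CR from `generate_cr`; an optional total-length target pads
the CR tail.  `simulate_codon_alignment` is a star-tree simulation: per
position a uniform alternative base is proposed and accepted with
probability `syn_rate` or `nonsyn_rate` (stop-creating proposals rejected).

What passing these tests shows: the annotators recover exactly what the
generators embed under realistic composition, spacing and repeat structure.
What they do not show: robustness to indels inside conserved elements, to
heteroplasmic length variation in repeat arrays, to sequencing error, or to
taxa whose true element motifs fall outside the encoded variant tables —
real CRs can and do present all of these.  The star-tree simulation has no
phylogenetic covariance, so dN/dS averages over simulated alignments test
the estimator, not tree-aware inference.

## Numerical and degenerate-input conventions

Deterministic tie-breaks throughout (smallest start for element hits;
length/identity/period/start for TR pruning; alphabetical consensus ties;
smallest type id for duplicate variant motifs).  Zero-denominator statistics
are flagged (`None`) rather than raised where a value can be legitimately
undefined (skews of AT- or GC-free sequence, dN/dS with dS = 0, Jukes–Cantor
at saturation); empty effective input is an error.  All generators take a
single integer seed and draw fields in a fixed order, so outputs are
byte-identical across runs and platforms for a given (spec, seed).

## Problem sizes

The shipped tests and the acceptance script run on synthetic genomes of
~15.8 kb, CRs of 0.2–1 kb, oracle sweeps over strings ≤ 1 kb (elements) and
≤ 200 nt with periods ≤ 10 (repeats), 300–400 sampled codon pairs for the
pathway oracle, and simulated alignments of 2–5 taxa × 200–2000 codons —
sizes at which every brute-force oracle is exact and the full suite runs in
a few seconds.
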