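# mitocr

Annotation and typing of the vertebrate mitochondrial **control region**
(CR), built for comparative mitogenomics of lacertid lizards and usable for
any taxon with the canonical 37-gene vertebrate gene order.

The CR — the long non-coding segment between *tRNA-Pro* and *tRNA-Phe* — is
the fastest-evolving part of the mitogenome, yet it carries short conserved
signals: two termination-associated sequences (TAS1, TAS2) near its 5' end
and three conserved sequence blocks (CSB1-CSB3) near the heavy-strand
replication origin, often interleaved with tandem-repeat (TR) arrays.
`mitocr` locates these elements by fuzzy matching against the *Lacerta
dugesii* reference motifs, renders variants in dot notation (· = identity
with the reference), types each variant against encoded survey tables,
detects TR arrays, and classifies whole CR layouts into five general types
and twenty-one subtypes with an editable rule table.  Around that core it
provides the accessory statistics of a mitogenome survey, where

* AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C),
* RSCU(codon) = count / (family total / family size) under the vertebrate
  mitochondrial code, CDpT = count / total × 1000,
* p-distance = differing sites / compared sites,
* dN/dS by Nei–Gojobori (1986) counting with equal pathway weighting and the
  Jukes–Cantor correction d = −(3/4) ln(1 − 4p/3),

plus gene-overlap scanning (including the conserved `ATGGNNNTAA` /
`ATGANTAA` ATP8/ATP6 junction motifs), light-strand origin (O_L) motif
search, and seeded synthetic-data generators that emit mitogenomes and CRs
with exact ground truth, so every stage is testable offline.

## Worked example

Generate a synthetic mitogenome (Eremias-like CR layout), annotate it, and
type its control region:

```bash
mitocr simulate -o demo --seed 1          # writes demo/synthetic.gb + ground truth
mitocr annotate -i demo/synthetic.gb -o demo
mitocr typify   -i demo/synthetic.gb -o demo
```

`demo/elements.tsv` then contains one row per conserved element:

```text
record_id  element  start  end  motif                     mismatches  variant_type  dot_pattern
SYN1       TAS1     92     116  ACTATTATGTATATAGTGCATTAA  0           1             ························
SYN1       TAS2     161    171  CATACATTAA                0           1             ··········
SYN1       CSB1     216    254  CTATATGGTATTATT...CATAT   0           1             ··········...
SYN1       CSB2     299    317  CAAACCCCCCTACCCCCC        0           1             ··················
SYN1       CSB3     352    372  TCGCCAAACCCCTAAAACGA      0           1             ····················
```

All five elements match their reference motifs exactly (0 mismatches,
variant type 1 in each survey table), and CSB3 starts 35 nt after CSB2 ends
(352 − 317), the spacing conserved in *Eremias* and *Darevskia*.
`demo/repeats.tsv` reports the two TR arrays (unit `TAGCGGCTTTTTTG`, period
14, 3.0 copies) placed before TAS1 and after CSB3 — the "normal" positions —
so `demo/types.tsv` classifies the CR as general type **I**, subtype
**I-4**, the layout shared by most *Eremias* species.  `demo/overlaps.tsv`
shows the ATP8/ATP6 overlap of 10 bp matching `ATGGNNNTAA` (here
`ATGGTGATAA`), plus the 7/5/1 bp ND4L/ND4, ND5/ND6 and ATP6/COIII overlaps.

The same functionality is available as a library:

```python
from mitocr import CR_PRESETS, generate_cr, annotate_cr_sequence

seq, truth = generate_cr(CR_PRESETS["darevskia_typical"], seed=1)
hits, repeats, profile = annotate_cr_sequence(seq)
print(hits["TAS2"].dot_pattern)   # 'T··G······' — the Darevskia-specific TAS2
```

## Layout

| Module | Contents |
| --- | --- |
| `mitocr.model` | mitogenome data model, GenBank/FASTA I/O, CR extraction, overlap + O_L scanning |
| `mitocr.composition` | base composition, skews, codon usage (CDpT/RSCU), p-distance |
| `mitocr.elements` | TAS/CSB fuzzy search, dot notation, variant tables |
| `mitocr.repeats` | tandem-repeat detector, TR position classes, genus-diagnostic motifs |
| `mitocr.crtypes` | CR layout profiles and the rule-driven 5-type / 21-subtype classifier |
| `mitocr.dnds` | Nei–Gojobori dN/dS with Jukes–Cantor correction |
| `mitocr.synth` | seeded generators: mitogenomes, CRs, codon alignments (+ ground truth) |
| `mitocr.cli` | `mitocr annotate / typify / stats / simulate` |

See `docs/methods.md` for the underlying models, parameter defaults and
known limitations.
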