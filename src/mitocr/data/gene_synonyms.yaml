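# Canonical feature name -> accepted GenBank spellings.
# Lookup is case/punctuation-insensitive (labels are normalized to A-Z0-9
# before matching), so "tRNA-Phe", "trna_phe" and "TRNA PHE" all resolve.
ND1: [NAD1, NADH1, NADH dehydrogenase subunit 1, MT-ND1]
ND2: [NAD2, NADH2, NADH dehydrogenase subunit 2, MT-ND2]
ND3: [NAD3, NADH3, NADH dehydrogenase subunit 3, MT-ND3]
ND4: [NAD4, NADH4, NADH dehydrogenase subunit 4, MT-ND4]
ND4L: [NAD4L, NADH4L, NADH dehydrogenase subunit 4L, MT-ND4L]
ND5: [NAD5, NADH5, NADH dehydrogenase subunit 5, MT-ND5]
ND6: [NAD6, NADH6, NADH dehydrogenase subunit 6, MT-ND6]
ATP6: [ATPASE6, ATPASE 6, ATP synthase F0 subunit 6, MT-ATP6]
ATP8: [ATPASE8, ATPASE 8, ATP synthase F0 subunit 8, MT-ATP8]
COI: [COX1, CO1, COXI, cytochrome c oxidase subunit I, cytochrome c oxidase subunit 1, MT-CO1]
COII: [COX2, CO2, COXII, cytochrome c oxidase subunit II, cytochrome c oxidase subunit 2, MT-CO2]
COIII: [COX3, CO3, COXIII, cytochrome c oxidase subunit III, cytochrome c oxidase subunit 3, MT-CO3]
CYTB: [COB, CYB, cytochrome b, MT-CYB]
rrnS: [12S rRNA, 12S ribosomal RNA, s-rRNA, small subunit ribosomal RNA, SSU, MT-RNR1, rrn12]
rrnL: [16S rRNA, 16S ribosomal RNA, l-rRNA, large subunit ribosomal RNA, LSU, MT-RNR2, rrn16]
CR: [D-loop, control region, D loop, putative control region, CTRL]
OL: [O_L, OriL, origin of L-strand replication, L-strand origin, rep_origin]
trnF: [tRNA-Phe, trnF-gaa]
trnV: [tRNA-Val, trnV-tac]
trnL2: [tRNA-Leu2, tRNA-Leu(UUR), trnL-taa, trnL(UUR), Leu2]
trnL1: [tRNA-Leu1, tRNA-Leu(CUN), trnL-tag, trnL(CUN), Leu1]
trnI: [tRNA-Ile, trnI-gat]
trnQ: [tRNA-Gln, trnQ-ttg]
trnM: [tRNA-Met, trnM-cat]
trnW: [tRNA-Trp, trnW-tca]
trnA: [tRNA-Ala, trnA-tgc]
trnN: [tRNA-Asn, trnN-gtt]
trnC: [tRNA-Cys, trnC-gca]
trnY: [tRNA-Tyr, trnY-gta]
trnS2: [tRNA-Ser2, tRNA-Ser(UCN), trnS-tga, trnS(UCN), Ser2]
trnS1: [tRNA-Ser1, tRNA-Ser(AGN), tRNA-Ser(AGY), trnS-gct, trnS(AGN), Ser1]
trnD: [tRNA-Asp, trnD-gtc]
trnK: [tRNA-Lys, trnK-ttt]
trnG: [tRNA-Gly, trnG-tcc]
trnR: [tRNA-Arg, trnR-tcg]
trnH: [tRNA-His, trnH-gtg]
trnE: [tRNA-Glu, trnE-ttc]
trnT: [tRNA-Thr, trnT-tgt]
trnP: [tRNA-Pro, trnP-tgg]
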