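# element=CSB1
# reference=CTATATGGTATTATTGTCTTAATGCTTGGTAGACATAT
type_id	dot_pattern	species
1	······································	L. agilis; L. bilineata; L. viridis viridis; Ph. kulzeri; Po. muralis; Ps. algirus; T. kuehnei; T. amurensis; T. septentrionalis; T. sylvaticus; T. wolteri; Z. vivipara
2	···············C·T····················	D. armeniaca; D. caucasica; D. chlorogaster; D. daghestanica; D. dahli; D. derjugini; D. mixta; D. parvula; D. portschinskii; D. raddei; D. rudis; D. unisexualis; D. valentini
3	···············TC··G··················	Mer. squamulosus; Pe. laticeps
4	···············TC·····················	Po. siculus
5	···············TCT·G········C·········	Mes. olivieri
6	····T········C·TCA····················	E. stummeri
7	············G··C·T····················	D. praticola
8	·········G······C··G··················	E. vermiculata
9	················GA····················	Ac. aureus; Ac. boskianus
10	············G·························	D. brauneri; D. saxicola
11	···················G··················	E. scripta; E. nikolskii
12	····T··············G··················	E. dzungarica; E. przewalskii; E. yarkandensis
13	·········G······A··G··················	E. argus
14	········GGC·······G···················	E. brenchleyi
15	····T····G·········G··················	E. multiocellata
16	····T··········TA··G··················	E. szczerbaki
17	·····A·······························A	Ac. guineensis
18	·················A··········A·········	Ac. schmidti
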