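# element=CSB3
# reference=TCGCCAAACCCCTAAAACGA
type_id	dot_pattern	species
1	····················	Au. australis; D. brauneri; D. chlorogaster; D. clarkorum; D. daghestanica; D. dahli; D. derjugini; D. mixta; D. parvula; D. portschinskii; D. praticola; D. raddei; D. rudis; D. saxicola; D. unisexualis; D. valentini; E. dzungarica; E. scripta KZL15; E. scripta KZL44; E. multiocellata; E. przewalskii; E. stummeri; E. szczerbaki; E. yarkandensis; L. agilis; L. bilineata; L. viridis viridis; Ph. kulzeri; Po. muralis; Po. siculus; T. amurensis; T. kuehnei; T. septentrionalis; T. sylvaticus; T. wolteri; Z. vivipara
2	············A·······	Ac. aureus; Ac. boskianus; Ac. schmidti; Mer. squamulosus; Pe. laticeps
3	···T······A·········	D. armeniaca
4	········T···········	E. nikolskii
5	C·······TT··CG····C·	E. argus
6	··········T·G·····A·	E. brenchleyi
7	········T·····G···AG	E. vermiculata
8	AG·····TT······T·T··	Ps. algirus
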