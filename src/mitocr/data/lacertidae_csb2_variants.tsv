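# element=CSB2
# reference=CAAACCCCCCTACCCCCC
type_id	dot_pattern	species
1	··················	Ac. aureus; Ac. boskianus; Ac. schmidti; Au. australis; D. armeniaca; D. brauneri; D. chlorogaster; D. daghestanica; D. dahli; D. derjugini; D. mixta; D. parvula; D. portschinskii; D. praticola; D. raddei; D. saxicola; D. unisexualis; D. valentini; E. dzungarica; E. scripta; E. multiocellata; E. przewalskii; E. stummeri; E. szczerbaki; E. yarkandensis; L. agilis; L. bilineata; L. viridis viridis; Mer. squamulosus; Mes. olivieri; Pe. laticeps; Ph. kulzeri; Po. muralis; Po. siculus; Ps. algirus; T. kuehnei; T. amurensis; T. septentrionalis; T. sylvaticus; T. wolteri; Z. vivipara
2	····T·············	E. nikolskii
3	··············T···	D. rudis
4	T····T··T········T	Ac. erythrurus
5	····T·T·T·····T···	E. argus
6	·····T·····G·····T	E. brenchleyi
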