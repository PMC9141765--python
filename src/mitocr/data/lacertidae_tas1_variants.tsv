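# element=TAS1
# reference=ACTATTATGTATATAGTGCATTAA
type_id	dot_pattern	species
1	························	Al. nigropunctatus; D. armeniaca; D. brauneri; D. chlorogaster; D. daghestanica; D. dahli; D. derjugini; D. mixta; D. parvula; D. portschinskii; D. raddei; D. rudis; D. saxicola; D. unisexualis; D. valentini; E. nikolskii; E. przewalskii; L. agilis; L. bilineata; L. viridis viridis; Ph. kulzeri; Po. muralis; Po. siculus; T. kuehnei; T. septentrionalis; T. sylvaticus; T. wolteri
2	·················A······	Ac. aureus; Ac. boskianus; Ac. erythrurus; Ac. guineensis; Ac. schmidti; Au. australis; E. scripta; E. multiocellata; E. stummeri; E. vermiculata; E. yarkandensis
3	·······C·G······C······C	E. argus
4	··············T··A······	E. brenchleyi
5	··············C··A······	E. szczerbaki
6	··AT·········AT··A······	Mes. olivieri
7	··A············T······C·	Pe. laticeps
8	··AT···················G	Ps. algirus
9	····C···················	Z. vivipara
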