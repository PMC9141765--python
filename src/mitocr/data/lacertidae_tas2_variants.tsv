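# element=TAS2
# reference=CATACATTAA
# note: rows 20, 23 and 26 are reconstructions — the source survey
# prints letters identical to the reference base in these rows,
# which would collapse them onto other types; each such letter was
# moved by the smallest shift giving a real, unique substitution.
type_id	dot_pattern	species
1	··········	L. viridis viridis
2	T··G······	D. armeniaca; D. brauneri; D. daghestanica; D. dahli; D. mixta; D. parvula; D. portschinskii; D. rudis; D. saxicola; D. valentini; E. przewalskii; L. agilis; Po. siculus
3	T·········	D. derjugini; D. raddei; E. yarkandensis; Ph. kulzeri; L. bilineata
4	T········T	Ac. schmidti; E. dzungarica; E. nikolskii; E. szczerbaki; Po. muralis
5	T···T·····	D. chlorogaster; D. clarkorum
6	T···A·····	T. amurensis
7	T········C	D. unisexualis
8	T······A·T	Ac. erythrurus
9	T··C······	D. caucasica
10	A········T	Ac. boskianus; E. multiocellata; E. stummeri
11	AG········	Ac. guineensis
12	A·········	E. vermiculata
13	·········T	Ac. aureus
14	···G······	Au. australis; Pe. laticeps
15	···GT·····	Mes. olivieri
16	·G········	Z. vivipara
17	····T···T·	Al. nigropunctatus
18	····T·····	T. septentrionalis; T. wolteri
19	·····T····	T. sexlineatus
20	····TT····	T. sylvaticus
21	····AC··G·	D. praticola
22	···C·GA···	E. argus
23	··A··T····	E. brenchleyi
24	·······A·T	E. scripta
25	········C·	Ps. algirus
26	····A·····	T. kuehnei
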