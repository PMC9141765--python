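# Control-region layout profiles for the 21 lacertid subtypes.
# One representative profile per subtype; layouts are a reconstruction of the
# published schematic typology (the source defines subtypes graphically), and
# the species column carries the taxa reported under each subtype.  Note
# D. chlorogaster is reported under both I-2 and IV-2 in the source; that
# contradiction is preserved verbatim in the species annotations.
profile_id	subtype	present	order_ok	anormal	normal	cr_length	species
P01	I-1	TAS1,TAS2,CSB1,CSB2,CSB3	true			950	Ac. aureus; Ac. schmidti; D. valentini; Mes. olivieri
P02	I-2	TAS1,TAS2,CSB1,CSB2,CSB3	true		after_CSB3	1400	Ph. kulzeri; Po. siculus; Z. vivipara; D. chlorogaster
P03	I-3	TAS1,TAS2,CSB1,CSB2,CSB3	true		before_TAS1	1300	Pe. laticeps
P04	I-4	TAS1,TAS2,CSB1,CSB2,CSB3	true		before_TAS1,after_CSB3	2100	E. multiocellata; E. stummeri; E. przewalskii; E. yarkandensis; E. szczerbaki; E. dzungarica; E. nikolskii; E. argus
P05	II-1	TAS1,TAS2,CSB1,CSB2,CSB3	true	between_CSB1_CSB2		1500	D. dahli; D. parvula; D. portschinskii; D. rudis; D. saxicola; L. bilineata; Ac. boskianus; Ps. algirus
P06	II-2	TAS1,TAS2,CSB1,CSB2,CSB3	true	between_CSB1_CSB2	before_TAS1	1800	D. armeniaca; D. brauneri; D. daghestanica; D. mixta; D. unisexualis; L. agilis; L. viridis; Po. muralis
P07	II-3	TAS1,TAS2,CSB1,CSB2,CSB3	true	between_CSB1_CSB2	before_TAS1,after_CSB3	2400	E. scripta
P08	III-1	TAS1,TAS2,CSB1,CSB2,CSB3	true	between_TAS2_CSB1	before_TAS1	1700	T. septentrionalis; T. wolteri; D. derjugini; T. kuehnei; T. sylvaticus; D. raddei
P09	IV-1	TAS1,TAS2,CSB1,CSB2,CSB3	true	between_CSB2_CSB3		1600	E. brenchleyi
P10	IV-2	TAS1,TAS2,CSB1,CSB2,CSB3	true	between_CSB2_CSB3	after_CSB3	1900	D. chlorogaster
P11	V-1	CSB2,CSB3	true			146	Al. nigropunctatus
P12	V-2	TAS2,CSB1,CSB2,CSB3	true			900	Ac. guineensis
P13	V-3	TAS1,CSB1,CSB2,CSB3	true			1100	E. vermiculata
P14	V-4	TAS1,TAS2,CSB2,CSB3	true			850	Ac. erythrurus
P15	V-5	TAS1,TAS2,CSB1,CSB3	true			1000	Au. australis
P16	V-6	TAS1,TAS2,CSB1,CSB2	true			950	D. praticola
P17	V-7	CSB1,CSB2,CSB3	true			700	T. sexlineatus
P18	V-8	TAS1,TAS2,CSB1	true			800	T. amurensis
P19	V-9	TAS1,TAS2,CSB3	true			750	D. caucasica
P20	V-10	TAS1,TAS2,CSB1,CSB2,CSB3	false			1200	D. clarkorum
P21	V-11	CSB3	true			400	Mer. squamulosus
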