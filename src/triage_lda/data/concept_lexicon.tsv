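# Toy concept lexicon: term TAB concept_id TAB semtype.
# Synonymous terms share one concept id; sports terms share semtype dora.
painkiller	C0002771	phsu
painkillers	C0002771	phsu
analgesic	C0002771	phsu
analgesics	C0002771	phsu
oedema	C0013604	patf
edema	C0013604	patf
swelling	C0013604	patf
tear	C3203359	inpo
rupture	C3203359	inpo
ligament tear	C0262595	inpo
ligament rupture	C0262595	inpo
meniscus tear	C0240063	inpo
meniscal tear	C0240063	inpo
tear of meniscus	C0240063	inpo
total knee replacement	C0086511	topp
knee arthroplasty	C0086511	topp
knee prosthesis	C0086511	topp
knee replacement	C0086511	topp
mcmurray test	C3669149	diap
mcmurray testing	C3669149	diap
bilateral knee pain	C2220048	sosy
pain in both knees	C2220048	sosy
medial joint line tenderness	C0576135	sosy
tender medial joint line	C0576135	sosy
knee pain	C0231749	sosy
hip pain	C0019559	sosy
physiotherapy	C0949766	topp
physical therapy	C0949766	topp
osteoarthritis	C0029408	dsyn
arthrosis	C0029408	dsyn
baker cyst	C0010710	dsyn
popliteal cyst	C0010710	dsyn
hoffa fat pad	C2835657	blor
anterior cruciate ligament	C0001074	blor
acl	C0001074	blor
patella	C0030647	blor
kneecap	C0030647	blor
x ray	C0043299	diap
radiograph	C0043299	diap
magnetic resonance imaging	C0024485	diap
mri scan	C0024485	diap
injection	C0021485	topp
steroid injection	C0149783	topp
effusion	C0013687	sosy
joint effusion	C0240158	sosy
crepitus	C0277964	sosy
instability	C0231686	sosy
locking	C0576093	sosy
ibuprofen	C0020740	phsu
paracetamol	C0000970	phsu
rugby	C800000	dora
skiing	C800001	dora
football	C800002	dora
badminton	C800003	dora
sport	C800004	dora
ice hockey	C800005	dora
basketball	C800006	dora
netball	C800007	dora
golf	C800008	dora
tennis	C800009	dora
running	C800010	dora
cycling	C800011	dora
swimming	C800012	dora
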