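# Abbreviation / variant expansion table: surface TAB canonical.
tkr	total knee replacement
thr	total hip replacement
physio	physiotherapy
oa	osteoarthritis
acl	anterior cruciate ligament
mcl	medial collateral ligament
rom	range of movement
mri	magnetic resonance imaging
nsaids	anti inflammatory drugs
gp	general practitioner
o/e	on examination
pt	physiotherapy
wb	weight bearing
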