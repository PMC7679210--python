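# Honorific triggers for personal-name masking, one per line.
# A trailing '.' in the letter text is tolerated for every entry.
Dr
Mr
Mrs
Ms
Miss
Prof
Professor
Sister
Mister
Madam
Rev
Nurse
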