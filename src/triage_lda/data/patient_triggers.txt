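# Phrases that are followed by a patient name (capitalized sequence)
# rather than an honorific, one per line, matched case-insensitively.
thank you for seeing
thank you for reviewing
thank you for referring
grateful if you could see
re:
regarding
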