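# Enclitic / contraction expansion table: surface TAB expansion.
# Applied after lowercasing, at word boundaries.
won't	will not
can't	cannot
shan't	shall not
n't	 not
i'm	i am
let's	let us
're	 are
've	 have
'll	 will
'd	 would
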