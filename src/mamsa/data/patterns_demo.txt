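# Demo motif patterns in PROSITE pattern syntax.
# N-glycosylation sequon
PS00001	N-{P}-[ST]-{P}
# Protein kinase C phosphorylation site
PS00005	[ST]-x-[RK]
# Tyrosine kinase phosphorylation site
PS00007	[RK]-x(2,3)-[DE]-x(2,3)-Y
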