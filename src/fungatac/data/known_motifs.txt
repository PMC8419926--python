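# Known Aspergillus TF binding-site consensus motifs (IUPAC).
# amyR and prtT spellings are reported for A. niger; the remaining
# entries are the field's standard consensus strings and are meant as a
# documented extension point -- replace or extend with your own
# id<TAB>consensus lines as needed.
amyR	CGG-N8-MGG
prtT	CCGHCGG
creA	SYGGRG
pacC	GCCARG
ebox	CACGTG
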