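drug,gene
codeine,CYP2D6
tramadol,CYP2D6
abacavir,HLA-B
capecitabine,DPYD
fluorouracil,DPYD
gentamicin,MT-RNR1
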