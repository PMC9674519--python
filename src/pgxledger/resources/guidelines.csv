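drug,gene,phenotype,recommendation
codeine,CYP2D6,poor,AVOID
codeine,CYP2D6,ultra_rapid,AVOID
codeine,CYP2D6,normal,STANDARD
tramadol,CYP2D6,poor,AVOID
tramadol,CYP2D6,ultra_rapid,AVOID
tramadol,CYP2D6,normal,STANDARD
abacavir,HLA-B,positive,AVOID
abacavir,HLA-B,negative,STANDARD
capecitabine,DPYD,poor,AVOID
capecitabine,DPYD,intermediate,REDUCE_DOSE
capecitabine,DPYD,normal,STANDARD
fluorouracil,DPYD,poor,AVOID
fluorouracil,DPYD,intermediate,REDUCE_DOSE
fluorouracil,DPYD,normal,STANDARD
gentamicin,MT-RNR1,positive,AVOID
gentamicin,MT-RNR1,negative,STANDARD
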