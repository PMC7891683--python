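clade,cervical_min,cervical_max,dorsal_min,dorsal_max,sacral_min,sacral_max,note
Crocodylia (crown),9,9,15,15,2,2,conserved formula enabling position-specific prediction
Paralligatoridae,8,9,14,16,2,2,
Bernissartiidae,8,9,14,16,2,2,
Goniopholididae,9,9,12,17,2,2,Goniopholis aff. G. lucasii with 12 dorsals deviates
Susisuchidae,8,9,14,16,2,2,
Tethysuchia,7,9,13,17,2,3,
Atoposauridae,6,9,13,17,2,2,Atoposaurus jourdani possibly 6 cervicals
Notosuchia,7,10,13,19,2,3,Notosuchus terrestris 10 cervicals 19 dorsals; some taxa short-tailed
Protosuchia,7,9,13,17,2,3,
Thalattosuchia,6,9,15,19,2,3,aquatic; deviates slightly from the crocodyliform formula
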