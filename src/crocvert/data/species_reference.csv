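species,specimen_id,smallest_mature_svl_m,smallest_mature_tl_m,male_mature_tl_m,male_source,female_mature_tl_m,max_tl_m
Alligator mississippiensis,UF 67824,1.31,2.53,1.83,literature,1.83,4.50
Caiman crocodilus,USNM 313860,0.75,1.43,1.43,literature,1.30,2.70
Caiman yacare,UF 121245,0.91,1.71,1.56,literature,1.30,2.50
Melanosuchus niger,UF 72914,1.29,2.59,2.38,estimated,2.05,4.20
Paleosuchus trigonatus,USNM 213705,0.66,1.15,1.31,literature,1.10,2.30
Crocodylus acutus,UF 63930,1.40,2.66,2.82,literature,2.20,6.25
Crocodylus johnstoni,NTM JA076,0.82,1.58,1.68,literature,1.40,3.20
Crocodylus moreletii,UF 54813,1.18,2.27,1.50,literature,1.50,4.16
Crocodylus porosus,FMNH 22026,1.82,3.51,3.35,literature,2.30,6.30
Crocodylus rhombifer,AMNH 57773,1.07,2.06,1.97,literature,1.91,3.50
Osteolaemus tetraspis,UF 33749,0.72,1.38,1.02,estimated,0.88,1.90
Gavialis gangeticus,AMNH 110145,1.64,3.16,3.00,literature,2.60,5.48
Tomistoma schlegelii,UF 84888,1.56,3.00,2.90,estimated,2.50,5.07
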