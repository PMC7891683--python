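taxon,specimen_id,anteriormost_closed,open_positions,predictor_id,tl_m,published_max_tl_m
Toyotamaphimeia machikanensis,MOU F00001,C2,,C2-D15sum,6.32,13.50
Penghusuchus pani,NMNS 005645,C2,,C2-D15sum,4.49,9.00
Gavialinae indet.,MZKB F1280,D6,,D3-10ave,7.01,14.02
Crocodylus affinis,YPM 258,Ca1,C2;C5;D1;D5;D10;D15;S1;S2,C2-D15sum,3.87,7.54
Crocodylus grinnelli,YPM 1344,D5,,C2-D15sum,2.09,3.63
Boverisuchus vorax,USNM 12957,C8,,C2-D15sum,2.21,3.88
Boverisuchus vorax,AMNH 29993,C3,,C2-D15sum,2.15,3.77
Borealosuchus wilsoni,USNM 12990,S1,D5;D10,C2-D15sum,3.19,5.99
Deinosuchus riograndensis,AMNH 3073,,D3,D3-10ave,7.73,
Pachycheilosuchus trinquei,USNM 427794,S1,,S1-2ave,1.15,1.69
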