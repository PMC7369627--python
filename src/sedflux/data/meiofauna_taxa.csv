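taxon,control,low,medium,high
Cladocera,33,27,90,57
Copepoda,16,17,16,21
Halacaridae,0,4,3,4
Kinorhyncha,0,0,40,146
Nematoda,78,142,662,1793
Ostracoda,0,0,16,9
Total,128,191,827,2030
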