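name,abbr,area,population,area_km2,density,ops_total,ops_with,ops_without
Alsterdorf,Als,West,152952,41.88,3652.06,2168,1752,416
Altona,Alo,West,70791,11.42,6199.41,3877,3322,555
Barmbek,Bar,East,170752,25.265,6761.12,4749,3927,822
Bergedorf,Beg,East,114212,129.25,883.68,3426,2699,727
Berliner Tor,Bet,East,78123,13.37,5841.85,2823,2369,454
Billstedt,Bil,East,56125,57.38,978.19,1973,1519,454
Finkenwerder,Fin,South,12846,56.18,228.64,383,314,69
Harburg,Har,South,109213,47.08,2319.73,2431,2076,355
Innenstadt,Inn,West,21607,6.87,3145.58,2541,2205,336
Osdorf,Osd,West,204793,57.69,3550.01,2982,2557,425
Rotherbaum,Rot,West,109294,11.01,9928.60,2086,1784,302
Sasel,Sas,East,169192,86.42,1957.72,4842,4203,639
Stellingen,Ste,West,272006,49.08,5542.67,4494,3674,820
Süderelbe,Sue,South,58611,59.26,989.07,1959,1669,290
Veddel,Ved,South,22271,24.72,901.11,1063,910,153
Wandsbek,Wan,East,123594,45.39,2722.76,4883,3967,916
Wilhelmsburg,Wil,South,51689,26.60,1942.90,1355,1140,215
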