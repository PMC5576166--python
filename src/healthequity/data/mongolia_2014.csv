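region,population,area_km2,physicians,nurses,hospital_beds
Ulaanbaatar,1362974,4704,5779,5575,10577
Orkhon,94421,840,260,342,592
Darkhan-Uul,99947,3280,253,375,660
Gobisumber,16058,5540,60,68,89
Selenge,106212,41200,192,286,630
Uvurkhangai,112992,62900,229,329,720
Bayan-Ulgii,95151,45700,158,287,671
Arkhangai,93086,55300,167,281,532
Tuv,90107,74000,188,302,533
Khovd,81479,76900,181,280,574
Bulgan,60494,48700,111,217,349
Khuvsgul,126043,100600,223,359,691
Uvs,75792,69600,145,274,521
Khentii,71212,80300,155,242,416
Zavkhan,69732,82500,159,270,592
Dornogobi,63808,109500,198,200,401
Dundgobi,44351,74700,121,164,247
Sukhbaatar,57423,82300,126,211,379
Bayankhongor,83044,116000,169,306,480
Dornod,75194,123600,174,274,438
Gobi-Altai,56735,141400,166,251,386
Umnugobi,59694,165400,150,160,412
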