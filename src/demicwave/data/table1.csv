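site,code,mean_cal_bp,dist_km_BK,dist_km_GEISSE,dist_km_KRE-H
Buran Kaya,BK,38528,,,
Geissenklosterle,GEISSE,37569,3701,,
Krems-Hundssteig,KRE-H,37124,3062,614,
Ranis 4 Ilsenhohle,RANIS,35655,3327,,506
Dolni Vestonice IIa,DVI,35550,2946,751,130
Fumane,FUMAN,35479,3200,790,1111
Henrykow 15,HENRY,35477,2833,784,437
Trencianske Bohuslavice-Pod Tureckom,TRENC,34058,,880,
EL Castillo,CASTI,33887,5613,1994,2530
Le Sire,SIRE,33465,4533,876,
"Maisieres Canal, champ de fouille",MAISI,33261,4122,,
Lapa do Picareiro,LP,33230,6543,2927,3459
Komarowa Cave,KC,32526,2705,,
Vale Boi,VB,32372,6537,2922,3450
Les Garennes,GAREN,32324,4793,1136,1668
Solutre-J-10,SOLUT,32319,4357,700,1231
Tarte,TARTE,32308,5013,1397,1930
Arbreda,ARBRE,32227,,1345,1878
Paglicci,PAGLI,32157,,1472,
Palomar,PALOM,31983,5744,2129,2662
Antonilako Koba,AK,31348,5457,1839,2374
Mira,MIRA,31315,736,2888,2559
Grotta Arene Candide,ARENE,31263,3554,,
Piana Ciresului,POIAN,31236,1577,1774,1169
Sirgenstein,SIRG,31184,,,617
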