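cas,name,target_species,ec50_low_mg_ml,ec50_high_mg_ml,qualifier,note
23135-22-0,Oxamyl,Meloidogyne enterolobii,0.028,0.028,eq,
23135-22-0,Oxamyl,Meloidogyne incognita,0.004,0.004,eq,
23135-22-0,Oxamyl,Pratylenchus penetrans,,,eq,66 +/- 2 % mean corrected mortality at 2 mg/mL; no EC50 reported
137-42-8,Metam sodium,Meloidogyne incognita,0.008,0.008,eq,values refer to the decomposition volatile metabolite methyl isothiocyanate
1254304-22-7,Fluazaindolizine,Meloidogyne enterolobii,0.200,0.200,gt,
1254304-22-7,Fluazaindolizine,Meloidogyne incognita,0.030,0.030,eq,
318290-98-1,Fluensulfone,Meloidogyne enterolobii,0.026,0.026,eq,
318290-98-1,Fluensulfone,Meloidogyne incognita,0.001,0.001,eq,
658066-35-4,Fluopyram,Meloidogyne enterolobii,0.0004,0.0004,eq,
658066-35-4,Fluopyram,Meloidogyne incognita,0.0001,0.0001,eq,
693-54-9,2-Decanone,Meloidogyne incognita,0.056,0.056,eq,
693-54-9,2-Decanone,Meloidogyne javanica,0.056,0.056,eq,
6175-49-1,1-Dodecanol,Bursaphelenchus xylophilus,0.009,0.009,eq,
589-98-0,3-Octanol,Pratylenchus penetrans,0.680,0.680,eq,
112-14-1,Octyl acetate,Meloidogyne incognita,0.037,0.037,eq,
112-14-1,Octyl acetate,Meloidogyne javanica,0.061,0.061,eq,
112-12-9,2-Undecanone,Meloidogyne incognita,0.021,0.021,eq,
112-12-9,2-Undecanone,Meloidogyne javanica,0.023,0.023,eq,
539-86-6,Allicin,Meloidogyne incognita,0.018,0.018,eq,
2179-57-9,Diallyl disulphide,Bursaphelenchus xylophilus,0.043,0.047,eq,
2050-87-5,Diallyl trisulphide,Bursaphelenchus xylophilus,0.003,0.004,eq,
6028-61-1,Dipropyl trisulphide,Bursaphelenchus xylophilus,0.004,0.005,eq,
17619-36-2,Methyl propyl trisulphide,Bursaphelenchus xylophilus,0.017,0.023,eq,
4180-23-8,trans-Anethole,Meloidogyne incognita,0.170,0.170,eq,
4180-23-8,trans-Anethole,Pratylenchus penetrans,1.780,1.780,eq,
100-52-7,Benzaldehyde,Meloidogyne incognita,0.009,0.009,eq,
100-52-7,Benzaldehyde,Pratylenchus penetrans,0.450,0.450,eq,
104-55-2,trans-Cinnamaldehyde,Bursaphelenchus xylophilus,0.057,0.057,eq,
104-55-2,trans-Cinnamaldehyde,Meloidogyne incognita,0.064,0.064,eq,
140-67-0,Estragole,Meloidogyne incognita,0.230,0.230,eq,
97-53-0,Eugenol,Meloidogyne incognita,0.256,0.256,eq,
97-53-0,Eugenol,Pratylenchus penetrans,1.720,1.720,eq,
512-85-6,cis-Ascaridole,Meloidogyne incognita,0.033,0.033,eq,
499-75-2,Carvacrol,Bursaphelenchus xylophilus,0.097,0.125,eq,
499-75-2,Carvacrol,Meloidogyne incognita,0.112,0.112,eq,
499-75-2,Carvacrol,Pratylenchus penetrans,0.480,0.480,eq,
99-49-0,Carvone,Meloidogyne incognita,0.115,0.115,eq,
89-83-8,Thymol,Bursaphelenchus xylophilus,0.110,0.119,eq,
89-83-8,Thymol,Meloidogyne javanica,0.140,0.140,eq,
89-83-8,Thymol,Pratylenchus penetrans,0.500,0.500,eq,
106-24-1,Geraniol,Bursaphelenchus xylophilus,0.415,0.540,eq,
106-24-1,Geraniol,Meloidogyne incognita,0.158,0.158,eq,
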