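cas,name,oral_ld50,oral_model,oral_predicted,dermal_ld50,dermal_model,dermal_predicted
23135-22-0,Oxamyl,3,rat,0,5000,rat,0
137-42-8,Metam sodium,896,rat,0,2000,rat,0
1254304-22-7,Fluazaindolizine,940,rat,0,2000,rat,0
318290-98-1,Fluensulfone,671,rat,0,>2000,rat,0
658066-35-4,Fluopyram,>2000,rat,0,2000,rat,0
693-54-9,2-Decanone,7936,rat,0,,,0
6175-49-1,1-Dodecanol,>12800,rat,0,>8000,rabbit,0
589-98-0,3-Octanol,>5000,rat,0,>5000,rabbit,0
112-14-1,Octyl acetate,3000,rat,0,>5000,rabbit,0
112-12-9,2-Undecanone,5000,rat,0,>5000,rabbit,0
539-86-6,Allicin,1121,rat,1,,,0
2179-57-9,Diallyl disulphide,260,rat,0,3600,rabbit,0
2050-87-5,Diallyl trisulphide,100,rat,0,,,0
6028-61-1,Dipropyl trisulphide,800,rat,0,,,0
17619-36-2,Methyl propyl trisulphide,496,rat,1,,,0
4180-23-8,trans-Anethole,3050,rat,0,>5000,rabbit,0
100-52-7,Benzaldehyde,1300,rat,0,>2000,rabbit,0
104-55-2,trans-Cinnamaldehyde,2225,rat,0,12000,rat,0
140-67-0,Estragole,1230,rat,0,5000,rabbit,0
97-53-0,Eugenol,3000,rat,0,2000,rat,0
512-85-6,cis-Ascaridole,4042,rat,1,,,0
499-75-2,Carvacrol,810,rat,0,2700,rabbit,0
99-49-0,Carvone,3710,rat,0,4000,rabbit,0
89-83-8,Thymol,980,rat,0,>2000,rat,0
106-24-1,Geraniol,>4000,rat,0,>5000,rabbit,0
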