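cas,name,aerosols,air,biota,sediment,soil,suspended_particles,water
23135-22-0,Oxamyl,0.0,0.0,0.0,0.0,0.0,0.0,99.9
137-42-8,Metam sodium,0.0,0.0,0.0,0.0,0.0,0.0,99.9
1254304-22-7,Fluazaindolizine,0.0,0.9,0.0,0.0,0.0,0.0,99.0
318290-98-1,Fluensulfone,0.0,0.3,0.0,0.1,6.4,0.0,93.1
658066-35-4,Fluopyram,0.0,0.0,0.0,1.3,59.3,0.0,39.3
693-54-9,2-Decanone,0.0,73.5,0.0,0.5,20.6,0.0,5.4
6175-49-1,1-Dodecanol,0.0,1.0,0.0,2.1,95.9,0.0,0.9
589-98-0,3-Octanol,0.0,31.5,0.0,0.4,19.3,0.0,48.7
112-14-1,Octyl acetate,0.0,77.9,0.0,0.3,14.3,0.0,7.5
112-12-9,2-Undecanone,0.0,32.4,0.0,1.2,52.2,0.0,14.1
539-86-6,Allicin,0.0,0.2,0.0,0.0,1.5,0.0,98.2
2179-57-9,Diallyl disulphide,0.0,98.0,0.0,0.0,0.2,0.0,1.8
2050-87-5,Diallyl trisulphide,0.0,88.3,0.0,0.0,2.7,0.0,8.9
6028-61-1,Dipropyl trisulphide,0.0,39.8,0.0,1.1,49.6,0.0,9.5
17619-36-2,Methyl propyl trisulphide,0.0,70.1,0.0,0.0,3.2,0.0,26.6
4180-23-8,trans-Anethole,0.0,40.4,0.0,0.8,36.3,0.0,22.5
100-52-7,Benzaldehyde,0.0,28.6,0.0,0.0,1.6,0.0,69.8
104-55-2,trans-Cinnamaldehyde,0.0,3.2,0.0,0.2,8.6,0.0,88.0
140-67-0,Estragole,0.0,25.4,0.0,1.1,50.7,0.0,22.7
97-53-0,Eugenol,0.0,3.1,0.0,0.4,18.3,0.0,78.2
512-85-6,cis-Ascaridole,0.0,93.0,0.0,0.0,0.9,0.0,6.1
499-75-2,Carvacrol,0.0,2.7,0.0,1.3,59.2,0.0,36.7
99-49-0,Carvone,0.0,64.1,0.0,0.1,5.7,0.0,30.1
89-83-8,Thymol,0.0,2.5,0.0,1.3,57.8,0.0,38.3
106-24-1,Geraniol,0.0,43.5,0.0,0.5,21.0,0.0,35.0
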