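cas,name,fish_lc50,fish_species,fish_predicted,algae_ec50,algae_species,algae_predicted,invertebrate_ec50,invertebrate_species,invertebrate_predicted
23135-22-0,Oxamyl,3.1,Oncorhynchus mykiss,0,0.9,Raphidocelis subcapitata,0,0.3,Daphnia magna,0
137-42-8,Metam sodium,>0.2,Lepomis macrochirus,0,1.1,Raphidocelis subcapitata,0,1.0,Daphnia magna,0
1254304-22-7,Fluazaindolizine,>30.0,Cyprinodon variegatus,0,46.0,Raphidocelis subcapitata,0,>120,Daphnia magna,0
318290-98-1,Fluensulfone,38.0,Oncorhynchus mykiss,0,0.02,Raphidocelis subcapitata,0,0.8,Daphnia magna,0
658066-35-4,Fluopyram,>1.0,Pimephales promelas,0,>1.1,Skeletonema costatum,0,55.5,Daphnia magna,0
693-54-9,2-Decanone,5.0,Pimephales promelas,1,,,0,4.6,Daphnia magna,1
6175-49-1,1-Dodecanol,1.0,Pimephales promelas,0,,,0,0.8,Daphnia magna,0
589-98-0,3-Octanol,23.2,Pimephales promelas,1,114.4,Raphidocelis subcapitata,0,184.5,Daphnia magna,0
112-14-1,Octyl acetate,8.2,Pimephales promelas,1,,,0,6.4,Daphnia magna,1
112-12-9,2-Undecanone,3.0,Oncorhynchus mykiss,0,>0.2,Raphidocelis subcapitata,0,0.2,Daphnia magna,0
539-86-6,Allicin,23.9,Pimephales promelas,1,,,0,38.7,Daphnia magna,1
2179-57-9,Diallyl disulphide,5.0,Pimephales promelas,1,,,0,2.3,Daphnia magna,1
2050-87-5,Diallyl trisulphide,1.9,Pimephales promelas,1,,,0,0.4,Daphnia magna,1
6028-61-1,Dipropyl trisulphide,1.8,Pimephales promelas,1,,,0,0.2,Daphnia magna,1
17619-36-2,Methyl propyl trisulphide,6.8,Pimephales promelas,1,,,0,1.0,Daphnia magna,1
4180-23-8,trans-Anethole,7.0,Danio rerio,0,9.6,not reported,0,4.2,Daphnia magna,0
100-52-7,Benzaldehyde,1.1,Lepomis macrochirus,0,33.1,Raphidocelis subcapitata,0,19.7,Daphnia magna,0
104-55-2,trans-Cinnamaldehyde,>20.0,Lepomis macrochirus,0,16.1,Chlorella vulgaris,0,11.5,Daphnia magna,0
140-67-0,Estragole,5.3,Pimephales promelas,1,,,0,3.8,Daphnia magna,1
97-53-0,Eugenol,>10.0,Oncorhynchus mykiss,0,15.4,Raphidocelis subcapitata,0,1.1,Daphnia magna,0
512-85-6,cis-Ascaridole,10.9,Pimephales promelas,1,,,0,40.3,Daphnia magna,1
499-75-2,Carvacrol,6.2,Danio rerio (not confirmed),0,4.1,Raphidocelis subcapitata,0,6.1,Daphnia magna,0
99-49-0,Carvone,50.0,Danio rerio,0,154.7,Raphidocelis subcapitata,0,249.5,Daphnia magna,0
89-83-8,Thymol,3.0,Oncorhynchus mykiss,0,11.7,Raphidocelis subcapitata,0,4.9,Daphnia magna,0
106-24-1,Geraniol,11.6,Oncorhynchus mykiss,0,48.0,Raphidocelis subcapitata,0,16.1,Daphnia magna,0
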