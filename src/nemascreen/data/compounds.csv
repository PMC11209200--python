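name,cas,class_group,molar_mass_g_mol,melting_point_c,vapour_pressure_pa,solubility_mg_l,henry_pa_m3_mol,log_kow,koc,provenance
Oxamyl,23135-22-0,pesticide,219.26,98.5,1.8e-05,148100,2.66e-08,-0.44,0.3,
Metam sodium,137-42-8,pesticide,129.19,88.5,0.06,578290,1.3e-05,-2.91,0.0004,
Fluazaindolizine,1254304-22-7,pesticide,468.20,218.5,0.21,2148,0.046,-0.16,0.2,
Fluensulfone,318290-98-1,pesticide,291.70,34.4,0.03,545,0.016,1.96,2,
Fluopyram,658066-35-4,pesticide,396.76,117.5,1.2e-06,16,2.98e-05,3.30,698,
2-Decanone,693-54-9,beta_keto_fatty_acid,156.26,14.0,0.33,77,0.672,3.70,1750,
1-Dodecanol,6175-49-1,beta_keto_fatty_acid,184.32,21.0,0.11,4,5.207,5.13,47200,
3-Octanol,589-98-0,beta_keto_fatty_acid,130.23,-45.0,0.34,1380,3.209,2.72,184,
Octyl acetate,112-14-1,beta_keto_fatty_acid,172.26,-38.5,0.53,179,0.513,3.40,879,
2-Undecanone,112-12-9,beta_keto_fatty_acid,170.29,15.0,5.34,80,0.114,3.69,1710,
Allicin,539-86-6,organosulfur,162.30,25.0,1.80,24000,0.012,1.30,7,
Diallyl disulphide,2179-57-9,organosulfur,146.30,-24.4,0.01,71,0.027,2.20,56,
Diallyl trisulphide,2050-87-5,organosulfur,178.30,8.4,0.14,51,0.499,2.60,139,
Dipropyl trisulphide,6028-61-1,organosulfur,182.40,11.0,3.20,28,0.209,3.84,2420,
Methyl propyl trisulphide,17619-36-2,organosulfur,154.32,-11.0,0.22,265,0.130,2.20,56,
trans-Anethole,4180-23-8,phenylpropanoid,148.20,21.0,6.67,111,8.905,3.33,748,
Benzaldehyde,100-52-7,phenylpropanoid,106.12,-57.1,0.01,6950,2.031,1.48,106,
trans-Cinnamaldehyde,104-55-2,phenylpropanoid,132.16,-18.0,3.90,2865,0.180,2.11,45,
Estragole,140-67-0,phenylpropanoid,148.20,-1.2,6.67,178,5.553,3.47,1030,
Eugenol,97-53-0,phenylpropanoid,164.20,-9.2,2.95,2460,0.196,2.49,108,
cis-Ascaridole,512-85-6,terpene,168.23,3.3,0.02,530,0.760,2.30,698,
Carvacrol,499-75-2,terpene,150.22,1.0,3.09,1250,0.370,3.33,748,
Carvone,99-49-0,terpene,150.21,-43.0,1.90,27,0.105,2.40,88,
Thymol,89-83-8,terpene,150.22,49.6,2.10,980,0.322,3.30,698,
Geraniol,106-24-1,terpene,154.25,-15.0,4.00,100,6.170,2.90,278,
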