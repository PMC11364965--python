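compound_name,smiles,rt_predicted,rt_observed,delta_rt
Histidine,NC(Cc1c[nH]cn1)C(=O)O,2.45,1.23,1.22
Norepinepherine,NCC(O)c1ccc(O)c(O)c1,3.57,1.35,2.22
Ascorbic Acid,OCC(O)C1OC(=O)C(O)=C1O,2.74,1.85,0.89
5-Hydroxytryptophan,NC(Cc1c[nH]c2ccc(O)cc12)C(=O)O,3.24,2.47,0.77
Zeatin,OC/C(C)=C\CNc1ncnc2[nH]cnc12,3.31,2.47,0.84
Phenylalanine,NC(Cc1ccccc1)C(=O)O,3.25,2.786,0.464
Indole,c1ccc2[nH]ccc2c1,4.44,3.34,1.1
Caffeine,Cn1cnc2c1c(=O)n(C)c(=O)n2C,3.97,3.41,0.56
N-acetyl serotonin,CC(=O)NCCc1c[nH]c2ccc(O)cc12,5,3.704,1.296
4-chlorophenylalanine,NC(Cc1ccc(Cl)cc1)C(=O)O,3.99,3.81,0.18
Isopentenyl adenine,CC(C)=CCNc1ncnc2[nH]cnc12,3.93,3.94,-0.01
Indole-3-acetic acid,OC(=O)Cc1c[nH]c2ccccc12,4.2,3.94,0.26
6-Benzylaminopurine,C(Nc1ncnc2[nH]cnc12)c1ccccc1,4.53,4.07,0.46
Lidocaine,CCN(CC)CC(=O)Nc1c(C)cccc1C,5.25,4.4,0.85
Coumaric acid,OC(=O)/C=C/c1ccc(O)cc1,4.59,4.44,0.15
Gibberellin A3,CC12C3C4CCC5(CC4(CC5=C)C(=O)O)C1(O)C=CC(O)C2OC3=O,5.63,4.492,1.138
Serotonin,NCCc1c[nH]c2ccc(O)cc12,4.52,4.51,0.01
5-chlorotryptamine,NCCc1c[nH]c2ccc(Cl)cc12,4.87,4.55,0.32
Vanillin,COc1cc(C=O)ccc1O,4.63,4.57,0.06
Strictosamide,CC1OC(OC2C=COC3CC(=O)NC(c4[nH]c5ccccc5c4C3)C2)C(O)C(O)C1O,4.85,4.621,0.229
Ferulic Acid,COc1cc(/C=C/C(=O)O)ccc1O,4.89,4.621,0.269
Anthranilic acid,Nc1ccccc1C(=O)O,4.58,4.69,-0.11
Melatonin,COc1ccc2[nH]cc(CCNC(C)=O)c2c1,4.97,4.86,0.11
Kinetin,C(Nc1ncnc2[nH]cnc12)c1ccco1,5.32,5.061,0.259
N-Feruloyl serotonin,COc1cc(/C=C/C(=O)NCCc2c[nH]c3ccc(O)cc23)ccc1O,4.67,5.079,-0.409
3-hydroxy tryptamine,NCCc1c[nH]c2cccc(O)c12,5.64,5.281,0.359
Quercetin,O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12,4.92,5.3,-0.38
7-hydroxy mitragynine,CCC1CN2CCC3(O)c4cc(OC)ccc4NC3C2CC1/C(=C\OC)C(=O)OC,5.41,5.648,-0.238
Mitragynine,CCC1CN2CCc3c([nH]c4cc(OC)ccc34)C2CC1/C(=C\OC)C(=O)OC,5.73,5.65,0.08
Pipernal,O=Cc1ccc2OCOc2c1,6.04,5.85,0.19
Strychnine,O=C1CC2OCC=C3CN4CCC56C4CC3C2C6N1c1ccccc15,4.67,5.9,-1.23
Reserpine,COC(=O)C1C(OC(=O)c2cc(OC)c(OC)c(OC)c2)C(OC)C(OC)CC1CN1CCc2c([nH]c3cc(OC)ccc23)C1,6,5.94,0.06
Indole-3-butyric acid,OC(=O)CCCc1c[nH]c2ccccc12,6.05,6.363,-0.313
Jasmonic acid,CC/C=C\CC1C(CC(=O)O)CCC1=O,5.97,6.418,-0.448
1-Naphthaleneacetic acid,OC(=O)Cc1cccc2ccccc12,6.48,6.45,0.03
2-Naphthoxyacetic acid,OC(=O)COc1ccc2ccccc2c1,6.43,6.8,-0.37
Ramelton,CCC(=O)NCCC1CCc2ccc3c(c21)CCO3,6.31,6.86,-0.55
Luzindole,CC(=O)NCCc1c(Cc2ccccc2)[nH]c2ccccc12,6.87,6.86,0.01
Methyl Salicylate,COC(=O)c1ccccc1O,6.9,7.17,-0.27
Melamine,Nc1nc(N)nc(N)n1,6.49,7.68,-1.19
Brassinolide,CC(C)C(C)C(O)C(O)C(C)C1CCC2C1(C)CCC1C2CC(O)C2CC(O)C(O)CC12C,5.91,7.76,-1.85
Paclobutrazol,CC(C)(C)C(O)C(Cc1ccc(Cl)cc1)n1cncn1,7.16,7.89,-0.73
cis-4-Phenyl-2-propionamidotetralin (4-P-PDOT),CCC(=O)NC1Cc2ccccc2C(c2ccccc2)C1,7.27,8.03,-0.76
Corticosterone,CC12CCC(=O)C=C1CCC1C2C(O)CC2(C)C1CCC2C(=O)CO,7.97,8.252,-0.282
Progesterone,CC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C,6.95,8.33,-1.38
Nicotine,CN1CCCC1c1cccnc1,7.95,10.09,-2.14
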