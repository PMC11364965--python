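name,class,formula,monoisotopic_mass,smiles,predicted_rt
Abscisic acid,abscisic acid,C15H20O4,264.136159,CC1=CC(=O)CC(C)(C)C1(O)/C=C/C(C)=C\C(=O)O,5.56
7-hydroxy-ABA,abscisic acid,C15H20O5,280.131074,,5.58
9-hydroxy-ABA,abscisic acid,C15H20O5,280.131074,,5.49
Neophaseic acid,abscisic acid,C15H20O5,280.131074,,6.01
Melatonin,indolamine,C13H16N2O2,232.121178,COc1ccc2[nH]cc(CCNC(C)=O)c2c1,4.88
2-hydroxymelatonin,indolamine,C13H16N2O3,248.116092,,5.07
4-hydroxymelatonin,indolamine,C13H16N2O3,248.116092,,4.97
6-hydroxymelatonin,indolamine,C13H16N2O3,248.116092,,5.02
N-sinapoyl Melatonin,melatonin conjugate,C24H26N2O6,438.179087,,3.54
Feruloyl serotonin,melatonin conjugate,C20H20N2O4,352.142307,COc1cc(/C=C/C(=O)NCCc2c[nH]c3ccc(O)cc23)ccc1O,3.83
N-Acetylserotonin,indolamine,C12H14N2O2,218.105528,CC(=O)NCCc1c[nH]c2ccc(O)cc12,4.63
Serotonin,indolamine,C10H12N2O,176.094963,NCCc1c[nH]c2ccc(O)cc12,4.52
Tryptophan,tryptophan metabolism,C11H12N2O2,204.089878,NC(Cc1c[nH]c2ccccc12)C(=O)O,
"2,3-dihydroxyindole",tryptophan metabolism,C8H7NO2,149.047678,Oc1[nH]c2ccccc2c1O,4.98
2-formylamino-benzaldehyde,tryptophan metabolism,C8H7NO2,149.047678,O=Cc1ccccc1NC=O,5.23
6-hydroxy-kynurenate,tryptophan metabolism,C10H7NO4,205.037508,O=C(O)c1cc(=O)c2cc(O)ccc2[nH]1,3.95
"7,8-dihydroxykynurenate",tryptophan metabolism,C10H7NO5,221.032422,,
"4,6-dihydroxyquinoline",tryptophan metabolism,C9H7NO2,161.047678,Oc1ccnc2ccc(O)cc12,
"5-(3'-carboxy-3'-oxopropyl)-4,6-dihydroxypicolinate",tryptophan metabolism,C10H9NO7,255.037902,,
Glucobrassicin,glucosinolate,C16H20N2O9S2,448.061022,OCC1OC(SC(=NOS(=O)(=O)O)Cc2c[nH]c3ccccc23)C(O)C(O)C1O,
IAA aspartate,auxin,C14H14N2O5,290.090272,OC(=O)CC(NC(=O)Cc1c[nH]c2ccccc12)C(=O)O,
IAA glutamate,auxin,C15H16N2O5,304.105922,OC(=O)CCC(NC(=O)Cc1c[nH]c2ccccc12)C(=O)O,
Indole-3-acetic acid,auxin,C10H9NO2,175.063329,OC(=O)Cc1c[nH]c2ccccc12,4.2
Zeatin,cytokinin,C10H13N5O,219.112010,OC/C(C)=C\CNc1ncnc2[nH]cnc12,3.31
Zeatin riboside-O-glucoside,cytokinin,C21H31N5O10,513.207092,,4.05
2-methylthio-cis-zeatin,cytokinin,C11H15N5OS,265.099731,CSc1nc(NC/C=C(C)\CO)c2nc[nH]c2n1,4.52
2-methylthio-cis-zeatin riboside,cytokinin,C16H23N5O5S,397.141990,,4.13
Isopentenyl adenine,cytokinin,C10H13N5,203.117095,CC(C)=CCNc1ncnc2[nH]cnc12,3.93
Kinetin,cytokinin,C10H9N5O,215.080710,C(Nc1ncnc2[nH]cnc12)c1ccco1,5.32
Jasmonic acid,jasmonate,C12H18O3,210.125594,CC/C=C\CC1C(CC(=O)O)CCC1=O,5.97
Gibberellin A3,gibberellin,C19H22O6,346.141638,CC12C3C4CCC5(CC4(CC5=C)C(=O)O)C1(O)C=CC(O)C2OC3=O,5.63
Methyl Salicylate,salicylate,C8H8O3,152.047344,COC(=O)c1ccccc1O,6.9
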