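id,smiles,label,barrier,source
pos1,COc1c(N(C)C)ccc(/C=N/N=C/c2ccccc2O)c1O,ESIPT,,synthetic
pos2,Oc1ccccc1/C=N/N=C/c1ccccc1O,ESIPT,,synthetic
pos3,Oc1ccccc1-c1nc2ccc(Br)cc2s1,ESIPT,,synthetic
pos4,Oc1ccccc1/C=N/N=C/c1ccccc1O,ESIPT,,synthetic
pos5,N#Cc1cc(O)c(-c2nc3ccc(Cl)cc3o2)c(F)c1,ESIPT,,synthetic
pos6,CN(C)c1ccc(O)c(-c2nc3ccccc3o2)c1,ESIPT,,synthetic
pos7,C/C(=N\N=C\c1ccccc1O)c1ccccc1O,ESIPT,,synthetic
pos8,COc1c(C#N)ccc2nc(-c3ccccc3O)[nH]c12,ESIPT,,synthetic
pos9,Cc1ccc(-c2nc3cccc(Br)c3[nH]2)c(O)c1,ESIPT,,synthetic
pos10,Oc1ccccc1/C=N/N=C/c1ccccc1O,ESIPT,,synthetic
pos11,Cc1ccc(/C=N/N=C/c2ccccc2O)c(O)c1F,ESIPT,,synthetic
pos12,N#Cc1cccc2nc(-c3c(O)cccc3[N+](=O)[O-])sc12,ESIPT,,synthetic
pos13,C/C(=N\N=C(/Br)c1ccccc1O)c1ccccc1O,ESIPT,,synthetic
pos14,Oc1ccccc1-c1nc2ccccc2o1,ESIPT,,synthetic
pos15,Oc1ccccc1/C=N/N=C/c1ccccc1O,ESIPT,,synthetic
pos16,Oc1ccccc1-c1nc2ccccc2s1,ESIPT,,synthetic
pos17,CN(C)/C(=N\N=C\c1ccccc1O)c1cc([N+](=O)[O-])ccc1O,ESIPT,,synthetic
pos18,Oc1ccccc1-c1nc2ccccc2o1,ESIPT,,synthetic
pos19,COc1cc(N(C)C[N+](=O)[O-])cc(O)c1-c1nc2ccccc2[nH]1,ESIPT,,synthetic
pos20,CN(C)c1cc([N+](=O)[O-])cc2sc(-c3ccccc3O)nc12,ESIPT,,synthetic
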