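# Drug-like single-fragment SMILES pool for the synthetic-data generator.
# Columns: id  smiles       (lines starting with # are comments)
aspirin         CC(=O)Oc1ccccc1C(=O)O
paracetamol     CC(=O)Nc1ccc(O)cc1
ibuprofen       CC(C)Cc1ccc(C(C)C(=O)O)cc1
caffeine        Cn1cnc2c1c(=O)n(C)c(=O)n2C
naproxen        COc1ccc2cc(C(C)C(=O)O)ccc2c1
ketoprofen      CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1
diclofenac      O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl
nicotine        CN1CCCC1c1cccnc1
benzocaine      CCOC(=O)c1ccc(N)cc1
lidocaine       CCN(CC)CC(=O)Nc1c(C)cccc1C
procaine        CCN(CC)CCOC(=O)c1ccc(N)cc1
atenolol        CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
propranolol     CC(C)NCC(O)COc1cccc2ccccc12
metoprolol      COCCc1ccc(OCC(O)CNC(C)C)cc1
salbutamol      CC(C)(C)NCC(O)c1ccc(O)c(CO)c1
warfarin        CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
coumarin        O=c1ccc2ccccc2o1
quinine         COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1
theophylline    Cn1c(=O)c2[nH]cnc2n(C)c1=O
tolbutamide     CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1
chlorzoxazone   Oc1nc2cc(Cl)ccc2o1
carbamazepine   NC(=O)N1c2ccccc2C=Cc2ccccc21
phenytoin       O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1
primidone       CCC1(c2ccccc2)C(=O)NCNC1=O
amantadine      NC12CC3CC(CC(C3)C1)C2
memantine       CC12CC3CC(C)(C1)CC(N)(C3)C2
tacrine         Nc1c2c(nc3ccccc13)CCCC2
fluoxetine      CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1
sertraline      CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21
bupropion       CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1
venlafaxine     COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1
tramadol        COc1cccc(C2(O)CCCCC2CN(C)C)c1
codeine         COc1ccc2CC3C4C=CC(O)C5Oc1c2C45CCN3C
atropine        CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2
scopolamine     CN1C2CC(OC(=O)C(CO)c3ccccc3)CC1C1OC21
pilocarpine     CCC1C(Cc2cncn2C)COC1=O
physostigmine   CNC(=O)Oc1ccc2c(c1)C1(C)CCN(C)C1N2C
neostigmine     CN(C)C(=O)Oc1cccc([N+](C)(C)C)c1
edrophonium     CC[N+](C)(C)c1cccc(O)c1
pyridostigmine  CN(C)C(=O)Oc1ccc[n+](C)c1
galanthaminone  COc1ccc2c3c1OC1CC(=O)C=CC31CCN(C)C2
imipramine      CN(C)CCCN1c2ccccc2CCc2ccccc21
amitriptyline   CN(C)CCC=C1c2ccccc2CCc2ccccc21
nortriptyline   CNCCC=C1c2ccccc2CCc2ccccc21
clomipramine    CN(C)CCCN1c2ccccc2CCc2ccc(Cl)cc21
haloperidol     O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1
risperidone     Cc1nc2CCCCn2c(=O)c1CCN1CCC(c2noc3cc(F)ccc23)CC1
olanzapine      Cc1cc2c(s1)Nc1ccccc1N=C2N1CCN(C)CC1
quetiapine      OCCOCCN1CCN(C2=Nc3ccccc3Sc3ccccc32)CC1
clozapine       CN1CCN(C2=Nc3cc(Cl)ccc3Nc3ccccc32)CC1
aripiprazole    O=c1ccc2cc(OCCCCN3CCN(c4cccc(Cl)c4Cl)CC3)ccc2[nH]1
buspirone       O=C1CC2(CCCC2)CC(=O)N1CCCCN1CCN(c2ncccn2)CC1
trazodone       O=c1n(CCCN2CCN(c3cccc(Cl)c3)CC2)nc2ccccn12
ondansetron     Cc1nccn1CC1CCc2c(C1=O)c1ccccc1n2C
granisetron     CN1C2CCCC1CC(NC(=O)c1nn(C)c3ccccc13)C2
metoclopramide  CCN(CC)CCNC(=O)c1cc(Cl)c(N)cc1OC
domperidone     O=c1[nH]c2ccccc2n1CCCN1CCC(n2c(=O)[nH]c3cc(Cl)ccc32)CC1
cimetidine      CC(=NC#N)NCCSCc1nc[nH]c1C
ranitidine      CNC(=CN(=O)=O)NCCSCc1ccc(CN(C)C)o1
omeprazole      COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1
famotidine      NC(N)=Nc1nc(CSCCC(N)=NS(N)(=O)=O)cs1
sildenafil      CCCc1nn(C)c2c1nc([nH]c2=O)-c1cc(S(=O)(=O)N2CCN(C)CC2)ccc1OCC
celecoxib       Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1
rofecoxib       O=C1OCC(=C1c1ccccc1)c1ccc(S(C)(=O)=O)cc1
indomethacin    COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1
piroxicam       CN1C(C(=O)Nc2ccccn2)=C(O)c2ccccc2S1(=O)=O
meloxicam       CN1C(C(=O)Nc2nc(C)cs2)=C(O)c2ccccc2S1(=O)=O
nabumetone      COc1ccc2cc(CCC(C)=O)ccc2c1
sulindac        CC1=C(CC(=O)O)c2cc(F)ccc2C1=Cc1ccc(S(C)=O)cc1
zolpidem        Cc1ccc2nc(-c3ccc(C)cc3)c(CC(=O)N(C)C)n2c1
chlorpromazine  CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21
melatonin       COc1ccc2[nH]cc(CCNC(C)=O)c2c1
serotonin       NCCc1c[nH]c2ccc(O)cc12
dopamine        NCCc1ccc(O)c(O)c1
levodopa        NC(Cc1ccc(O)c(O)c1)C(=O)O
methyldopa      CC(N)(Cc1ccc(O)c(O)c1)C(=O)O
baclofen        NCC(CC(=O)O)c1ccc(Cl)cc1
gabapentin      NCC1(CC(=O)O)CCCCC1
pregabalin      CC(C)CC(CN)CC(=O)O
vigabatrin      C=CC(N)CCC(=O)O
tizanidine      Clc1ccc2nsnc2c1NC1=NCCN1
riluzole        Nc1nc2ccc(OC(F)(F)F)cc2s1
donepezil_des   O=C1c2cc(O)c(O)cc2CC1CC1CCNCC1
rivastig_frag   CCN(C)C(=O)Oc1cccc(C(C)N)c1
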