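name,smarts
at_C_sp3,[CX4]
at_C_sp2,[CX3]
at_C_sp,[CX2]
at_c_arom,[c]
at_CH3,[CX4H3]
at_CH2,[CX4H2]
at_CH1,[CX4H1]
at_C_quart,[CX4H0]
at_N_any,[#7]
at_n_arom,[n]
at_N_amine_prim,[NX3H2]
at_N_amine_sec,[NX3H1][#6]
at_N_amine_tert,[NX3H0]([#6])([#6])[#6]
at_N_plus,[#7+]
at_O_any,[#8]
at_o_arom,[o]
at_OH,[OX2H]
at_O_ether,[OX2H0]([#6])[#6]
at_O_carbonyl,[OX1]=[#6]
at_S_any,[#16]
at_s_arom,[s]
at_F,[F]
at_Cl,[Cl]
at_Br,[Br]
at_I,[I]
at_halogen,"[F,Cl,Br,I]"
at_P,[#15]
at_B,[#5]
grp_carboxylic,[CX3](=O)[OX2H1]
grp_ester,[CX3](=O)[OX2H0][#6]
grp_amide,[CX3](=O)[NX3]
grp_ketone,[#6][CX3](=O)[#6]
grp_aldehyde,[CX3H1]=O
grp_nitrile,[CX2]#[NX1]
grp_nitro,[NX3](=O)=O
grp_sulfonamide,[SX4](=O)(=O)[NX3]
grp_sulfone,[SX4](=O)(=O)([#6])[#6]
grp_sulfoxide,[SX3](=O)([#6])[#6]
grp_thioether,[SX2]([#6])[#6]
grp_urea,[NX3][CX3](=O)[NX3]
grp_carbamate,[NX3][CX3](=O)[OX2]
grp_guanidine,[NX3][CX3](=[NX2])[NX3]
grp_hydroxyl_arom,[c][OX2H]
grp_aniline,[c][NX3H2]
grp_methoxy,[OX2H0][CX4H3]
grp_trifluoromethyl,[CX4]([F])([F])[F]
grp_acetylene_H,[CX2H]#[CX2]
grp_imine,[CX3]=[NX2]
grp_hydrazine,[NX3][NX3]
grp_azo,[NX2]=[NX2]
ring_benzene,c1ccccc1
ring_pyridine,c1ccncc1
ring_pyrimidine,c1cncnc1
ring_pyrrole,c1cc[nH]c1
ring_imidazole,c1c[nH]cn1
ring_pyrazole,c1cc[nH]n1
ring_furan,c1ccoc1
ring_thiophene,c1ccsc1
ring_oxazole,c1cnco1
ring_thiazole,c1cncs1
ring_piperidine,C1CCNCC1
ring_piperazine,C1CNCCN1
ring_morpholine,C1COCCN1
ring_pyrrolidine,C1CCNC1
ring_tetrahydrofuran,C1CCOC1
ring_cyclopropane,C1CC1
ring_cyclobutane,C1CCC1
ring_cyclopentane,C1CCCC1
ring_cyclohexane,C1CCCCC1
bond_rotatable,[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]
hb_donor,"[$([N;!H0;v3]),$([N;!H0;+1;v4]),$([O,S;H1;+0]),$([n;H1;+0])]"
hb_acceptor,"[$([O,S;H1;v2]-[!$(*=[O,N,P,S])]),$([O,S;H0;v2]),$([O,S;-]),$([N;v3;!$(N-*=!@[O,N,P,S])]),$([nH0,o,s;+0])]"
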