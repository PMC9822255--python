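# PET oligomer library: composition, condensation molecular weight,
# and externally predicted molecular volume. The 'hypothetical'
# column is an editorial annotation (not derivable from the acronym).
acronym,common_name,topology,n_TPA,n_EG,n_DEG,extra_endgroup,Mw_g_mol,Mv_A3,hypothetical
C[TPA+EG],First series cyclic monomer,cyclic,1,1,0,none,192.17,162.74,True
C[TPA+EG]2,First series cyclic dimer,cyclic,2,2,0,none,384.34,323.69,False
C[TPA+EG]3,First series cyclic trimer,cyclic,3,3,0,none,576.51,484.64,False
C[TPA+EG]4,First series cyclic tetramer,cyclic,4,4,0,none,768.68,645.59,False
C[TPA+EG]5,First series cyclic pentamer,cyclic,5,5,0,none,960.85,806.54,False
C[TPA+EG]6,First series cyclic hexamer,cyclic,6,6,0,none,1153.02,967.49,False
C[TPA+EG]7,First series cyclic heptamer,cyclic,7,7,0,none,1345.19,1128.43,False
C[TPA+EG]8,First series cyclic octamer,cyclic,8,8,0,none,1537.36,1289.38,False
C[TPA+DEG],Second series cyclic monomer,cyclic,1,0,1,none,236.22,205.33,False
C[TPA+EG]+[TPA+DEG],Second series cyclic dimer,cyclic,2,1,1,none,428.39,366.28,False
C[TPA+EG]2+[TPA+DEG],Second series cyclic trimer,cyclic,3,2,1,none,620.56,527.23,False
C[TPA+EG]3+[TPA+DEG],Second series cyclic tetramer,cyclic,4,3,1,none,812.73,688.18,False
C[TPA+EG]4+[TPA+DEG],Second series cyclic pentamer,cyclic,5,4,1,none,1004.90,849.12,True
C[TPA+EG]5+[TPA+DEG],Second series cyclic hexamer,cyclic,6,5,1,none,1197.07,1010.07,True
C[TPA+DEG]2,Third series cyclic dimer,cyclic,2,0,2,none,472.45,408.87,False
C[TPA+EG]+[TPA+DEG]2,Third series cyclic trimer,cyclic,3,1,2,none,664.62,569.82,False
C[TPA+EG]2+[TPA+DEG]2,Third series cyclic tetramer,cyclic,4,2,2,none,856.79,730.76,True
C[TPA+EG]3+[TPA+DEG]2,Third series cyclic pentamer,cyclic,5,3,2,none,1048.96,891.71,True
C[TPA+EG]4+[TPA+DEG]2,Third series cyclic hexamer,cyclic,6,4,2,none,1241.13,1052.66,True
C[TPA+EG]+[TPA+DEG]3,Fourth series cyclic tetramer,cyclic,4,1,3,none,900.84,773.35,True
L[TPA+EG],First series linear monomer,linear,1,1,0,none,210.19,180.63,False
L[TPA+EG]2,First series linear dimer,linear,2,2,0,none,402.36,341.58,False
L[TPA+EG]3,First series linear trimer,linear,3,3,0,none,594.52,502.53,False
L[TPA+EG]4,First series linear tetramer,linear,4,4,0,none,786.70,663.48,False
L[TPA+EG]5,First series linear pentamer,linear,5,5,0,none,978.87,824.43,False
L[TPA+EG]6,First series linear hexamer,linear,6,6,0,none,1171.04,985.38,False
L[TPA+EG]7,First series linear heptamer,linear,7,7,0,none,1363.20,1146.33,True
L[TPA+EG]8,First series linear octamer,linear,8,8,0,none,1555.38,1307.28,True
L[TPA+DEG],Second series linear monomer,linear,1,0,1,none,254.24,223.22,False
L[TPA+DEG]+EG,Second series linear monomer + EG,linear,1,1,1,EG,298.29,265.81,False
L[TPA+EG]+[TPA+DEG],Second series linear dimer,linear,2,1,1,none,446.41,384.17,False
L[TPA+EG]2+[TPA+DEG],Second series linear trimer,linear,3,2,1,none,638.58,545.12,False
L[TPA+EG]3+[TPA+DEG],Second series linear tetramer,linear,4,3,1,none,830.75,706.07,True
L[TPA+EG]4+[TPA+DEG],Second series linear pentamer,linear,5,4,1,none,1022.92,867.02,True
L[TPA+EG]5+[TPA+DEG],Second series linear hexamer,linear,6,5,1,none,1215.09,1027.97,True
L[TPA+DEG]2,Third series linear dimer,linear,2,0,2,none,490.46,426.76,False
L[TPA+EG]+[TPA+DEG]2,Third series linear trimer,linear,3,1,2,none,682.63,587.71,False
L[TPA+EG]2+[TPA+DEG]2,Third series linear tetramer,linear,4,2,2,none,874.80,748.66,True
L[TPA+EG]3+[TPA+DEG]2,Third series linear pentamer,linear,5,3,2,none,1066.97,909.61,True
L[TPA+EG]4+[TPA+DEG]2,Third series linear hexamer,linear,6,4,2,none,1259.14,1070.55,True
L[TPA+EG]+EG,First series linear monomer + EG,linear,1,2,0,EG,254.24,223.22,False
L[TPA+EG]2+EG,First series linear dimer + EG,linear,2,3,0,EG,446.41,384.17,False
L[TPA+EG]3+EG,First series linear trimer + EG,linear,3,4,0,EG,638.58,545.12,False
L[TPA+EG]4+EG,First series linear tetramer + EG,linear,4,5,0,EG,830.75,706.07,False
L[TPA+EG]5+EG,First series linear pentamer + EG,linear,5,6,0,EG,1022.92,867.02,True
L[TPA+EG]6+EG,First series linear hexamer + EG,linear,6,7,0,EG,1215.09,1027.97,True
L[TPA+EG]+TPA,First series linear monomer + TPA,linear,2,1,0,TPA,358.30,299.00,False
L[TPA+EG]2+TPA,First series linear dimer + TPA,linear,3,2,0,TPA,550.47,459.94,False
L[TPA+EG]3+TPA,First series linear trimer + TPA,linear,4,3,0,TPA,742.64,620.89,False
L[TPA+EG]4+TPA,First series linear tetramer + TPA,linear,5,4,0,TPA,934.81,781.84,False
L[TPA+EG]5+TPA,First series linear pentamer + TPA,linear,6,5,0,TPA,1126.98,942.79,True
L[TPA+EG]6+TPA,First series linear hexamer + TPA,linear,7,6,0,TPA,1319.15,1103.74,True
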