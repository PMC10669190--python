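# Study-design registry: 14 capped 21-mer peptide systems.
# notation = ligand + segment center (4=406, 3=327, 2=240) + start conformation
# (H = alpha-helical, E = fully extended); native peptides carry ligand "-".
notation,center,start,ligand,run_ns,ion,n_water
XNN_4H,406,H,XNN,100,1 Cl-,2701
XNN_4E,406,E,XNN,100,1 Cl-,6898
NTD_4H,406,H,-,100,1 Cl-,2731
NTD_4E,406,E,-,100,1 Cl-,5570
XN0_4H,406,H,XN0,100,1 Cl-,2687
XNB_4H,406,H,XNB,100,1 Cl-,2886
XNN_3H,327,H,XNN,100,1 Na+,2701
XNN_3E,327,E,XNN,50,1 Na+,6880
NTD_3H,327,H,-,100,1 Na+,2522
NTD_3E,327,E,-,100,1 Na+,5460
XNN_2H,240,H,XNN,50,-,2980
NTD_2H,240,H,-,100,-,2774
NTD_2E,240,E,-,100,-,3415
XEN_4H,406,H,XEN,50,1 Cl-,2695
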