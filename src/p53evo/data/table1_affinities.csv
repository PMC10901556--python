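# Extant MDM2/p53TAD affinities (uM), motif = p53TAD 15-27 (human numbering).
# kd_motif_native: native p53TAD^15-27 peptide vs same-species MDM2.
# kd_vs_human_mdm2: fish p53TAD^15-27 peptide vs human MDM2.
# kd_human_peptide: human p53TAD^15-27 peptide vs the species' MDM2.
# kd_fulllength_native: full-length p53TAD vs same-species MDM2 (this-study value).
# kd_fulllength_prior: earlier published kinetic value for the human row only.
# All "_err" columns are the reported replicate-based +/- uncertainties, stored
# separately and never folded into the values.
label,species,common_name,paralog,motif_seq,kd_motif_native,kd_motif_native_err,kd_vs_human_mdm2,kd_vs_human_mdm2_err,kd_human_peptide,kd_human_peptide_err,kd_fulllength_native,kd_fulllength_native_err,kd_fulllength_prior,kd_fulllength_prior_err
H. sapiens,Homo sapiens,human,,SQETFSDLWKLLP,0.26,0.02,,,,,0.061,0.003,0.10,0.003
L. oculatus,Lepisosteus oculatus,spotted gar,,SQESFQELWNMVI,0.39,0.04,0.121,0.005,0.37,0.014,0.085,0.005,,
A. anguilla p53TAD_P1,Anguilla anguilla,European eel,P1,SQESFQELWKMMC,0.19,0.02,0.013,0.001,0.9,0.1,0.23,0.02,,
A. anguilla p53TAD_P2,Anguilla anguilla,European eel,P2,SQDETFQALWNTVT,1.2,0.2,0.77,0.02,,,0.06,0.01,,
C. harengus p53TAD_P1,Clupea harengus,Atlantic herring,P1,SQGTFDEIWASNF,2.6,0.2,1.25,0.04,1.8,0.3,0.19,0.04,,
C. harengus p53TAD_P2,Clupea harengus,Atlantic herring,P2,DSPDFEDLWNSIV,0.60,0.03,0.29,0.02,,,0.04,0.01,,
O. kisutch p53TAD_P1a,Oncorhynchus kisutch,coho salmon,P1a,GQCSFQQLWESNM,2.1,0.2,3.15,0.06,0.78,0.1,0.048,0.005,,
O. kisutch p53TAD_P1b,Oncorhynchus kisutch,coho salmon,P1b,SQGSFQQLWETNM,3.5,0.1,5.15,0.09,,,0.06,0.01,,
O. kisutch p53TAD_P2,Oncorhynchus kisutch,coho salmon,P2,SQESFEDLWKMNL,1.16,0.07,0.79,0.03,,,0.07,0.01,,
C. argus p53TAD_P1,Channa argus,northern snakehead,P1,SQDSFRELWESVV,3.3,0.4,1.1,0.3,2.1,0.2,0.10,0.03,,
M. zebra p53TAD_P1,Maylandia zebra,zebra mbuna,P1,SQDSFKELWDQLP,1.6,0.1,0.27,0.04,1.7,0.4,0.19,0.02,,
T. rubripes p53TAD_P1,Takifugu rubripes,Japanese puffer,P1,SQDTFQDLWENVA,4.5,0.8,1.7,0.1,1.1,0.2,0.47,0.03,,
D. rerio p53TAD_P2,Danio rerio,zebrafish,P2,SQEFAELWEKNL,3.6,0.3,4.33,0.05,0.79,0.05,0.049,0.008,,
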