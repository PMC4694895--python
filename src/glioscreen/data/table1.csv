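gene_id,aliases,full_name,microarray_fc,microarray_call,qpcr_fc,qpcr_call,western_fc,western_call,rna_protein_r,correlation_sign,survival,gbm_tissue,gbm_vs_lgg
CENPA,,Centromere protein A,38.5,UP,39.2,UP,8.0,UP,0.76,1,Y,Y,Y
DLG7,DLGAP5|HURP,Discs large homolog 7 (Drosophila),36.0,UP,24,UP,41,UP,0.70,1,Y,Y,Y
PBK,TOPK,PDZ binding kinase,40.7,UP,38.1,UP,24.6,UP,0.74,1,Y,Y,Y
FILIP1L,,Filamin A interacting protein 1-like,16.1,UP,4.5,NS,31.7,UP,0.73,1,Y,Y,Y
CDC6,,CDC6 cell division cycle 6 homolog,26.2,UP,9.2,UP,8.8,UP,0.66,1,Y,Y,Y
NOL4,,Nucleolar protein 4,13.5,UP,30.5,UP,7.1,UP,0.70,1,N,Y,N
MCC,,Mutated in colorectal cancers,12.4,UP,8.1,UP,0.3,DR,0.42,-1,Y,Y,Y
KIF15,,Kinesin family member 15,13,UP,62.7,UP,4.7,UP,0.73,1,Y,Y,Y
MPP6,,Membrane protein palmitoylated 6,10.6,UP,9.8,UP,4.6,UP,0.80,1,Y,Y,N
KIF18A,,Kinesin family member 18A,12.8,UP,11,UP,22.4,UP,0.89,1,Y,Y,Y
EZH2,,Enhancer of zeste homolog 2 (Drosophila),13.7,UP,35.3,UP,17.1,UP,0.92,1,Y,Y,Y
DEPDC1,,DEP domain containing 1,12.2,UP,15.7,UP,49.9,UP,0.52,1,Y,Y,Y
RAPGEF4,,Rap guanine nucleotide exchange factor (GEF) 4,9.1,UP,33.4,UP,0.2,DR,0.59,-1,N,Y,N
HMMR,RHAMM|CD168,Hyaluronan-mediated motility receptor,10.0,UP,25,UP,7.7,UP,0.86,1,Y,Y,Y
ATXN7L4,ATXN7L1,Ataxin 7-like 4,7.4,UP,3.2,UP,0.9,DR,0.40,1,N,Y,Y
P2RY5,LPAR6,Purinergic receptor P2Y G-protein coupled 5,5.7,UP,0.5,NS,0.1,DR,0.52,1,Y,Y,Y
FAM118A,,Family with sequence similarity 118 member A,3.2,UP,0.3,DR,7.3,UP,0.61,1,Y,Y,N
RHBDD1,,Rhomboid domain containing 1,3.3,UP,1.2,NS,2.3,UP,0.05,-1,N,Y,Y
FNDC3B,,Fibronectin type III domain containing 3B,3.3,UP,0.8,NS,17.5,UP,0.63,1,Y,Y,Y
MDM1,,Mdm4 transformed 3T3 cell double minute 1 p53 binding protein (mouse),3.4,UP,3.4,UP,30.4,UP,0.88,1,N,Y,Y
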