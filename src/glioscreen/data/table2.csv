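section,protein_a,protein_b,direct,via
cluster 1,MTOR,CENPA,no,RUVBL1|RUVBL2|DDB1
cluster 1,MTOR,EZH2,no,SIRT1|C7ORF25|PML|AKT1
cluster 1,DLL3,EZH2,no,NRF1
cluster 1,DLL3,KIF18A,no,NRF1
cluster 1,STAT3,EZH2,no,RPS6K5|ESR1|HDAC1|HDAC2|HDAC3|PML|RELA|KDM1A|MYOD1|SRC|MAP3K7|DNMT1|ASXL1
cluster 1,STAT3,CENPA,no,SRRT
cluster 1,STAT3,DLG7,no,SUMO2
cluster 1,STAT3,DEPDC1,no,ELAVL1
cluster 1,CENPA,EZH2,no,HIST1H1A
cluster 1,DLG7,EZH2,no,CDK1
cluster 1,UBC,MTOR,yes,
cluster 1,UBC,STAT3,yes,
cluster 1,UBC,EZH2,yes,
cluster 1,UBC,DEPDC1,yes,
cluster 1,UBC,KIF15,yes,
cluster 1,UBC,KIF18A,yes,
cluster 1,UBC,DLG7,yes,
cluster 2,EGFR,PBK,no,H2AFX|CALM1|HSP90AB1|HSPA5|HSPA8|HSPA1A|PRDX1|TUBB|HBA1|JUP|CDC37
cluster 2,EGFR,RHBDD1,no,FBXO25|UBC
cluster 3,SOX2,CDC6,no,FZR1|BMI1|CDK1
cluster 3,SOX2,HMMR,no,TUBB2A
cluster 3,SOX2,MPP6,no,SKIV2L2
cluster 3,NF1,MPP6,no,SMARCA4
cluster 3,NRF1,HMMR,yes,
cluster 3,NRF1,NF1,yes,
cluster 3,NRF1,MPP6,yes,
cluster 3,UBC,NF1,yes,
cluster 3,UBC,FNDC3B,yes,
cluster 3,UBC,HMMR,yes,
cluster 3,UBC,MPP6,yes,
cluster 3,UBC,CDC6,yes,
across clusters,EZH2,CDC6,no,CDK2|CDK6|RBL2|UBB
across clusters,MCC,DLG7,no,APP
across clusters,MCC,HMMR,no,CSNK1E
across clusters,HMMR,CENPA,no,ACTB
across clusters,PBK,CENPA,no,HNRNPU|H2AFX|HIST4H4|HIST1H1C|HSPA8
across clusters,PBK,KIF15,no,KIAA1377|VIM
across clusters,PBK,CDC6,no,CCNB1|RPS27A|E2F4|MYC
across clusters,PBK,HMMR,no,CALM1
across clusters,PBK,DLG7,no,TRIM37
across clusters,PBK,EZH2,no,RBBP4|CDK1
other,HIF1A,EZH2,no,HDAC1|HDAC2|HDAC3|RELA|ESR1|CTNNB1|SRC
other,EZH2,STAT3,no,HDAC1|HDAC2|HDAC3|RELA|ESR1
other,HIF1A,CDC6,no,MCM3|MCM7|CDKN2A
other,HIF1A,MPP6,no,SMARCA4|NDN
other,HIF1A,HMMR,no,BRCA1|MAPK1
other,HIF1A,MCC,no,VCP|VHL
other,HIF1A,CENPA,no,RUVBL2|PARP1|HSPA8
other,HIF1A,PBK,no,CSNK2A1|HSPA8
other,HIF1A,DLG7,no,SUMO2
other,BMI1,CENPA,yes,XRCC5|PARP1|CBX8|PRKDC|RING1|RNF2|H2AFX
other,BMI1,CDC6,yes,ATM
other,BMI1,PBK,no,H2AFX|KIAA137|TP53|CSNK2B
other,BMI1,EZH2,no,E2F6|MAPKAPK3|USP7
other,BMI1,KIF15,no,KIAA137
other,BMI1,DLG7,no,BTRC
other,BMI1,MPP6,no,UBC
other,SALL2,CENPA,no,DDB1
other,SALL2,PBK,no,RBBP7
other,SALL2,SOX2,no,RBBP7
other,POU3F2,OLIG2,no,SOX10
other,POU3F2,OLIG2,no,EP300
other,POU3F2,HIF1A,no,EP300
other,OLIG2,HIF1A,no,EP300
other,CDK1,PBK,yes,
other,CDK1,CDC6,yes,
other,CDK1,DLG7,yes,
other,CDK1,EZH2,yes,
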