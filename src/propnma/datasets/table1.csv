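study_id,task,modality,source,validation,n_hc,n_mci,n_ad,algorithm,accuracy,sensitivity,specificity
ref27,MCI_conversion,T1,local,NR,18,24,32,Bayes,92,94,89
ref27,MCI_conversion,T1,local,NR,18,24,32,SVM,98,96,100
ref15,AD_vs_HC,T1,ADNI,NR,180,222,122,LR,86,NR,NR
ref15,AD_vs_HC,T1,ADNI,NR,180,222,122,SVM,89,NR,NR
ref13,AD_vs_HC,T1,local,NR,29,30,21,Bayes,78,72,83
ref13,AD_vs_HC,T1,local,NR,29,30,21,SVM,86,82,90
ref9001,MCI_conversion,T1_T2,AddNeuroMed,NR,110,119,116,MP,87,85,90
ref9001,MCI_conversion,T1_T2,AddNeuroMed,NR,110,119,116,SVM,88,86,90
ref24,MCI_conversion,T1,ADNI,NR,231,394,200,LDS,75,89,52
ref24,MCI_conversion,T1,ADNI,NR,231,394,200,SVM,82,87,74
ref19,MCI_conversion,T1,ADNI,NR,70,74,70,ELM,78,69,84
ref19,MCI_conversion,T1,ADNI,NR,70,74,70,SVM,80,83,79
ref11,AD_vs_HC,T1,ADNI,NR,352,531,334,FFR,87,NR,NR
ref11,AD_vs_HC,T1,ADNI,NR,352,531,334,NN,88,NR,NR
ref25,AD_vs_HC,T1,ADNI,NR,162,210,137,CNN,84,NR,NR
ref25,AD_vs_HC,T1,ADNI,NR,162,210,137,SVM,76,NR,NR
ref9002,AD_vs_HC,T1,ADNI,NR,112,180,97,DenseNet,83,89,76
ref9002,AD_vs_HC,T1,ADNI,NR,112,180,97,CNN,76,77,76
ref9003,AD_vs_HC,T1,ADNI,NR,275,413,280,DenseNet,95,94,95
ref9003,AD_vs_HC,T1,ADNI,NR,275,413,280,ResNet,93,94,93
ref9003,AD_vs_HC,T1,ADNI,NR,275,413,280,CNN,85,83,88
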