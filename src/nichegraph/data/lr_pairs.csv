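id,ligand_genes,receptor_genes
PLAU_PLAUR,PLAU,PLAUR
IGF1_IGF1R,IGF1,IGF1R
SPP1_ITGAV,SPP1,ITGAV
TGFB1_TGFBR,TGFB1,TGFBR1+TGFBR2
TNF_TNFRSF1A,TNF,TNFRSF1A
IL1B_IL1R1,IL1B,IL1R1
IL6_IL6R,IL6,IL6R+IL6ST
BMP2_BMPR,BMP2,BMPR1A+BMPR2
LTF_LRP1,LTF,LRP1
TNFSF10_TNFRSF10B,TNFSF10,TNFRSF10B
IFNG_IFNGR,IFNG,IFNGR1+IFNGR2
TSLP_TSLPR,TSLP,CRLF2+IL7R
CXCL12_CXCR4,CXCL12,CXCR4
PDGFB_PDGFRB,PDGFB,PDGFRB
VEGFA_KDR,VEGFA,KDR
WNT5A_FZD1,WNT5A,FZD1
FGF10_FGFR2,FGF10,FGFR2
HGF_MET,HGF,MET
CCL19_CCR7,CCL19,CCR7
APP_CD74,APP,CD74
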