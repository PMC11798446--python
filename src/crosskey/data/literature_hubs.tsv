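study_id	authors	platform	genes
S01	Maddah et al.	Affy.	BUB1;DLGAP5;CDCA8;ASPM;POLQ;WDHD1;CENPE;HELLS;TRIP13;DEPDC1
S02	Zhao et al.	Affy.	CCNA2;CDK1;CCNB1;MAD2L1;RRM2;NDC80;TOP2A
S03	Liu et al.	Affy.	CYP3A4;AOX1;UGT1A4;UGT1A6;DK1;UGT2B15;C CCNB2;CCNB1;CDC20;MAD2L1
S04	Meng et al.	Affy.\Illum.\Agil.	CDK1;CDC20;CCNB2;CCNB1;CCNA2;TOP2A;MELK;KIF20A;PBK;TPX2;AURKA
S05	Rosli et al.	Affy.	CDK1;MAD2L1;TOP2A;CCNA2;CCNB1;CCNB2;KIF11;NCAPG;TTK;AURKA;CDC20;RRM2;NDC80;CENPA;MELKPBK;BUB1B;PRC1;DTL;NUSAP1;KIF2C
S06	Zhang et al.	Affy.	GMPS;ACACA;KRAS;BCL2;ALB;TGFB1;EGFR;STAT3;ERBB2;CD8A
S07	Li et al.	Affy.	SPP1;IGF1;LGALS3;COL1A2;LPA
S08	Li et al.	Affy.	BUB1;CCNA2;BUB1B;CCNB1;CDK1;CDC20;MAD2L1;CCNB2
S09	Tian et al.	Affy.\Illum.	CDC20;RRM2;TOP2A;AOX1 UBE2C
S10	Wan et al.	Agil.	GF1;NDC80;IGF2;CDK1;CDCA8;CCNB1;CENPF;BIRC5;NCAPG;CDCA5;SPC25;CENPU
S11	Zhu et al.	Affy.	CDK1;CCNB1;TOP2A;CDC20;PLK1;CCNB2;BIRC5;FOS;AURKA;AURKB
S12	Wang et al.	Affy.	TOP2A;ITGA2;CDK1;PLK1;CCNB2;ESR1;AURKA;CCNA2;BUB1;BUB1B
S13	Zhou et al.	Affy.\Illum.\Agil.	ASPM;CCNB2;AURKA;MELK;CDKN3;NUSAP1;NCAPG;TOP2A;PRC1
S14	Zhang et al.	Affy.\Agil.	CDK1;AURKA;CCNB1;KIF11;CCNA2;TOP2A;BUB1B;HMMR;TPX2;CDC45
S15	Nguyen et al.	Affy.	TOP2A;NEK2;RRM2;CCNB1;CDK1
S16	Wu et al.	Affy.	CDKN3;CCNB1;CDK1;TOP2A;CCNB2;CCNA2;RRM2 PRC1
S17	Gui et al.	Agil.	MT1X;CAP2;BMI1;TACSTD2
S18	Wang et al.	Affy.	NDC80;TOP2A;CDK1;AURKA;HMMR;CCNB1;FOXM1;CENPF;PTTG1;CDKN3
S19	Zhang et al.	Affy.	GMPS;ALB;ACACA;TGFB1;ERBB2;KRAS;BBCL2;STAT3;EGFR;CD8A
S20	Bhatt et al.	Illum.	DMC1;MSH3;IL10;ALPP;HSD17B7;ZNF223
S21	Jiang et al.	Affy.	TLR1;TLR4;TLR8;TLR7;RIPK2;FOS;YWHAZ;FOSL2;FASLG;HIF1A;CDK1A;CCL4;DDIT3
S22	Zhang et al.	Affy.\Illum.	CDK1;CDC20;CCNB2;AURKA;CCNA2;CCNB1;MAD2L1;BUB1B;TOP2A;BUB1;IGF1;ESR1;FTCD;C8A;CYP3A4;CYP2E1;SPP2;F9;TAT;CYP2C9
S23	Wu et al.	Affy.	TTK;CCNB1;TOP2A;RRM2;PRC1;NCAPG;CDK1;UBE2C;CDKN3;ZWINT;RACGAP1;AURKA
S24	Mou et al.	Affy.\Illum.	TK1;TOP2A;FOS;CDC20;CCNB2;ESR1;CXCL12;VWF;HMMR;FOXO1;ACSM3;ZIC2;RFC4;TXNRD1;COL4A1;CYP3A4;GNAO1;RAP2A
S25	Chen et al.	Affy.	RRM2;ECT2;NDC80;ASPM;CDK1;CCNB1;PRC1;KIF20A;TOP2A;DTL;PBK
S26	Yu et al.	Affy.	TOP2A;CDC6;MAD2L1;CHEK1;CCNB1;UBE2C
S27	Kakar et al.	Affy.	CDK1;CCNB1;CCNA2;CCNB2;NDC80;BUB1;CDC20;NCAPG;BUB1B;MAD2L1
S28	Ji et al.	Affy.\Agil.	CDK1;PBK;ASPM;CCNB1;CCNB2;NDC80;AURKA;KIF2C;TPX2;CENPF
S29	Zhou et al.	Affy.	DTL;RACGAP1;CDK1;CCNB1;ECT2;NEK2;BUB1B;ASPM;HMMR;PBK;TOP2A;RRM2;CDKN3;PRC1;ANLN
S30	Qiang et al.	Affy.	CDK1;CDC20;CCNB2;BUB1;CCNB1;NDC80;BUB1B;CENPF;NUF2;MAD2L1
S31	He et al.	Affy.	CDK1;RRM2;PBK;ASPM
S32	Zhang et al.	Affy.	CCNB1;TOP2A;AURKA;NEK2;NUF2;CENPF;CDKN3;ASPM;PRC1;RACGAP1
S33	Wang et al.	Affy.	CDK1;CCNB2;CCNB1;TOP2A;MAD2L1
S34	Sha et al.	Affy.	TOP2A;DTL;HMMR;CCNB1;PBK;NEK2;RACGAP1;CDK1;PRC1;RRM2;BUB1B;ECT2;ANLN;ASPM
S35	Chen et al.	Affy.\Illum.\Agil.	TOP2A;PRC1;CCNB2;RACGAP1;CDKN3;AURKA;NUSAP1;ASPM;CDCA5;NCAPG
S36	Wang et al.	Illum.	CDKN3;UBE2C;TOP2A;CDC20;ASPM;PBK;KIF20A;CCNB2;NCAPG;CYP3A4
S37	Zhang et al.	Affy.\Agil.	NEK2;TOP2A;ANLN;CENPF;CDC20;ASPM;CDK1;ECT2;CCNB1;CCNB2
S38	Zhang et al.	Affy.\Illum.	ALDH2;CYP2C8;PPTG1;ADH1B;ADH4;CYP2C8;TOP2A;CDC20;CCNB2
S39	Hu et al.	Illum.	JUN;MYC;EGR1;CDKN1A
S40	Li et al.	Affy.	TOP2A;CCNB1;CDK1;BUB1;CCNB2;CENPF;TTK;KIF2C;MELK;HMMR;CENPE;PBK;KIF4A;KIF20A;DLGAP5
S41	Cao et al.	Affy.\Illum.	MCM3;KIF11;PBK;CHEK1;S100A9
S42	Zhang et al.	Affy.	GMPS;ALB;ACACA;TGFB1;ERBB2;KRAS;BCL2;STAT3;EGFR;CD8A
S43	Kim et al.	Affy.	ANLN;BUB1B;ASPM;CCNB1;CDKN3;CDK1;ECT2;NEK2;HMMR;PBK;RACGAP1;PRC1;TOP2A;RRM2
S44	Jiang et al.	Affy.	ANLN;BUB1B;BIRC5;CDC20;CDK1;CDCA5;NCAPG;TOP2A;NEK2
S45	Li et al.	Affy.	BIRC5;CCNB2;BUB1;CDC20;CDK1;CDC25C;CXCL12;CEP55;KIF20AK;FOS;NUSAP1;RACGAP;KIF2C;SPC24;PRC1;TOP2A
S46	Dai et al.	Affy.	ANLN;NDC80;DLGAP5;NUSAP1;PBK;RACGAP1;NUF2;BUB1B;ZWINT;CCNB1;DTL;TOP2A;KIF20A;RRM2;CDKN3;PRC1;HMMR;NPY1R;CCL20;CXL12
S47	Zhu et al.	Affy.	UBE2C;TK;CDK1;NCAPG;RAD51AP1;TOP2A;ASPM;DLGAP5;PBK;NUSAP1
S48	Xing et al.	Affy.\Illum.	TOP2A;CCNB2;PCNA;AURKA;BUB1;CDKN3;RFC4;CEP55;DLGAP5;PRC1;MCM2;CDC20;TPX2;RACGAP1;MCM4
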