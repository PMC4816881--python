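accession	protein_name	sequence	site	fold_change	p_value	functional_group
O15031	Plexin-B2	ISVAGRNdeCSFQPER	N844	2.89	0.0342	RS
O15031	Plexin-B2	ALSNdeISLR	N127	2.08	0.0358	RS
O60637	Tetraspanin-3	TYNdeGTNdePDAASR	N127	2.96	0.0358	RS
O60637	Tetraspanin-3	TYNdeGTNPDAASR	N127	2.98	0.0433	RS
O75882	Attractin	GICNdeSSDVR	N300	2.35	0.0342	IR
P02786	Transferrin receptor protein 1	KDFEDLYTPVNdeGSIVIVR	N251	1.72	0.0433	TT
P05026	Sodium/potassium-transporting ATPase subunit beta-1	FKLEWLGNdeCSGLNDETYGYK	N158	2.79	0.0479	TT
P06213	Insulin receptor	HNdeLTITQGK	N445	2.45	0.0479	RS
P06731	Carcinoembryonic antigen-related cell adhesion molecule 5	TLTLFNdeVTR	N204	2.67	0.0342	AM
P06731	Carcinoembryonic antigen-related cell adhesion molecule 5	TLTLFNVTRNdeDTASYK	N208	3.11	0.0342	AM
P06756	Integrin alpha-V	ISSLQTTEKNdeDTVAGQGER	N874	4.02	0.0342	AM
P06756	Integrin alpha-V	NdeMTISR	N554	4.02	0.0342	AM
P07602	Prosaposin	TNdeSTFVQALVEHVKEECDR	N215	2.59	0.0479	O
P08962	CD63 antigen	CCGAANdeYTDWEK	N150	1.94	0.0394	RS
P10909	Clusterin	EIRHNdeSTGCLR	N291	2.12	0.0342	O
P11117	Lysosomal acid phosphatase	QTPEYQNdeESSR	N177	3.05	0.0383	E
P12821	Angiotensin-converting enzyme	IGLLDRVTNdeDTESDINYLLK	N445	2.62	0.0456	P
P13473	Lysosome-associated membrane glycoprotein 2	LNdeSSTIK	N275	3.09	0.0342	AM
P13473	Lysosome-associated membrane glycoprotein 2	VASVINdeINPNdeTTHSTGSCR	N253	1.96	0.0358	AM
P13473	Lysosome-associated membrane glycoprotein 2	VASVININPNdeTTHSTGSCR	N257	2.06	0.0456	AM
P13688	Carcinoembryonic antigen-related cell adhesion molecule 1	NdeQSLPSSER	N363	2.76	0.0479	AM
P13726	Tissue factor	RNdeNTFLSLR	N169	5.52	0.0342	P
P13726	Tissue factor	NdeNTFLSLR	N169	5.76	0.0358	P
P18564	Integrin beta-6	EVEVNdeSSK	N463	3.71	0.0479	AM
P21589	5'-nucleotidase	LDNdeYSTQELGK	N333	1.67	0.0479	E
P26006	Integrin alpha-3	ELAVPDGYTNdeRTGAVYLCPLTAHK	N86	2.68	0.0433	AM
P30825	High affinity cationic amino acid transporter 1	LCLNNdeDTK	N235	3.48	0.0297	TT
P30825	High affinity cationic amino acid transporter 1	LCLNdeNdeDTK	N234	3.01	0.0342	TT
P35613	Basigin	ALMNdeGSESR	N268	2.91	0.0342	P
P42892	Endothelin-converting enzyme 1	NdeSSVEAFK	N632	1.89	0.0394	P
P42892	Endothelin-converting enzyme 1	DYYLNdeKTENEK	N270	5.64	0.0479	P
P43007	Neutral amino acid transporter A	VVTQNdeSSSGNdeVTHEK	N201	2.58	0.0477	TT
P46059	Solute carrier family 15 member 1	NdeDSCPEVK	N562	4.66	0.0358	TT
P48960	CD97 antigen	WCPQNSSCVNdeATACR	N38	1.87	0.0479	AM
P54760	Ephrin type-B receptor 4	CAQLTVNdeLTRFPETVPR	N203	2.34	0.0342	RS
Q04912	Macrophage-stimulating protein receptor	LPEYVVRDPQGWVAGNdeLSAR	N841	3.26	0.0358	RS
Q08380	Galectin-3-binding protein	DAGVVCTNdeETR	N125	2.43	0.0358	AM
Q08722	Leukocyte surface antigen CD47	SDAVSHTGNdeYTCEVTELTREGETIIELK	N111	6.51	0.0056	AM
Q11206	ST3GAL4	LFGNdeYSR	N61	5.77	0.0088	O
Q12913	Receptor-type tyrosine-protein phosphatase eta	HGSNdeHTSTYDK	N582	3.15	0.0342	RS
Q12913	Receptor-type tyrosine-protein phosphatase eta	VSDNdeESSSNdeYTYK	N391	2.94	0.0342	RS
Q12913	Receptor-type tyrosine-protein phosphatase eta	VSDNESSSNdeYTYK	N396	2.74	0.0383	RS
Q12913	Receptor-type tyrosine-protein phosphatase eta	GPNdeGTEGASR	N525	2.76	0.0427	RS
Q12913	Receptor-type tyrosine-protein phosphatase eta	IHVAGETDSSNdeLNdeVSEPR	N411	1.69	0.0479	RS
Q12913	Receptor-type tyrosine-protein phosphatase eta	SNdeDTAASEYK	N142	2.77	0.0479	RS
Q13641	Trophoblast glycoprotein	CVNRNdeLTEVPTDLPAYVR	N81	1.85	0.0429	RS
Q14108	Lysosome membrane protein 2	ANIQFGDNdeGTTISAVSNdeK	N105	2.03	0.0394	T
Q14108	Lysosome membrane protein 2	ANdeIQFGDNdeGTTISAVSNK	N99	1.78	0.0479	T
Q15043	Zinc transporter ZIP14	ALLNHLDVGVGRGNdeVTQHVQGHR	N77	2.42	0.0479	TT
Q15758	Neutral amino acid transporter B(0)	NdeITGTR	N212	2.93	0.0479	TT
Q7Z7H5	Transmembrane emp24 domain-containing protein 4	QYGSEGRFTFTSHTPGDHQICLHSNdeSTR	N117	2.50	0.0479	T
Q8N271	Prominin-2	ILRNdeVSECFLAR	N725	3.11	0.0433	O
Q92542	Nicastrin	RPNdeQSQPLPPSSLQR	N417	1.66	0.0483	P
Q92673	Sortilin-related receptor	LTIVNdeSSVLDRPR	N871	1.92	0.0479	T
Q92673	Sortilin-related receptor	SRNdeSTVEYTLNK	N1986	1.67	0.0479	T
Q9BXB1	Leucine-rich repeat-containing G-protein coupled receptor 4	TLDLSYNNIRDLPSFNdeGCHALEEISLQR	N362	4.00	0.0358	RS
Q9BXS4	Transmembrane protein 59	LFSICQFVDDGIDLNdeRTK	N90	4.09	0.0342	T
Q9H330	Transmembrane protein 245	ILGDKVNdeNTAVIEK	N551	3.47	0.0433	O
Q9H5V8	CUB domain-containing protein 1	ASVSFLNFNdeLSNCERK	N270	3.33	0.0342	AM
Q9H5V8	CUB domain-containing protein 1	IGTFCSNdeGTVSR	N180	2.93	0.0358	AM
Q9H5V8	CUB domain-containing protein 1	NdeVSGFSIANR	N205	2.33	0.0358	AM
Q9HD43	Receptor-type tyrosine-protein phosphatase H	NdeATTAHNPVR	N203	6.86	0.0342	RS
Q9HD43	Receptor-type tyrosine-protein phosphatase H	ETRNdeATTAPNPVR	N381	2.93	0.0479	RS
Q9HD43	Receptor-type tyrosine-protein phosphatase H	NdeTTNTSVTAER	N434	2.72	0.0479	RS
Q9P2B2	Prostaglandin F2 receptor negative regulator	QRNdeNSWVK	N525	3.60	0.0429	RS
Q9UN76	Sodium- and chloride-dependent neutral and basic amino acid transporter B(0+)	SPIVTHCNdeVSTVNdeK	N174	2.44	0.0420	TT
Q9Y639	Neuroplastin	ANdeATIEVK	N229	2.59	0.0429	AM
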