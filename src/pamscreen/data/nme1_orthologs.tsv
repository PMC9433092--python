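accession	host	name	length_aa	identity_pct
A0A011P7F8	Mannheimia granulomatis	MgrCas9	1049	65.5
A0A0A2YBT2	Gallibacterium anatis IPDH697-78	GanCas9	1035	59.7
A0A0J0YQ19	Neisseria arctica	NarCas9	1070	70.4
A0A1T0B6J6	Haemophilus felis	HfeCas9	1058	65.3
A0A1X3DFB7	Neisseria dentiae	NdeCas9	1074	66.4
A0A263HCH5	Actinobacillus seminis	AseCas9	1059	66
A0A2M8S290	Conservatibacter flavescens	CflCas9	1063	64.2
A0A2U0SK41	Pasteurella langaaensis DSM 22999	PlaCas9	1056	63.9
A0A356E7S3	Pasteurellaceae bacterium	PstCas9	1076	63
A0A369Z1C7	Haemophilus parainfluenzae	Hpa1Cas9	1056	64.8
A0A369Z3K3	Haemophilus parainfluenzae	Hpa2Cas9	1054	65.2
A0A377J007	Haemophilus pittmaniae	HpiCas9	1053	65.2
A0A378UFN0	Bergeriella denitrificans (Neisseria denitrificans)	BdeCas9	1069	68.8
A0A379B6M0	Pasteurella mairii	PmaCas9	1061	63.1
A0A379CB86	Phocoenobacter uteri	PutCas9	1059	63
A0A380MYP0	Suttonella indologenes	SinCas9	1071	67.8
A0A3N3EE71	Neisseria animalis	Nan1Cas9	1074	66.6
A0A3S4XT82	Neisseria animaloris	Nan2Cas9	1078	65.4
A0A420XER8	Otariodibacter oris	OorCas9	1058	64.4
A0A448K7T0	Pasteurella aerogenes	PaeCas9	1056	68.2
A0A4S2QB06	Rodentibacter pneumotropicus	RpnCas9	1055	63.7
A0A4Y9GBC9	Neisseria sp. WF04	Nsp2Cas9	1067	59.6
A6VLA7	Actinobacillus succinogenes (strain ATCC 55618/DSM 22257/130Z)	AsuCas9	1062	64.6
C5S1N0	Actinobacillus minor NM305	AmiCas9	1056	67.7
E0F2V7	Actinobacillus pleuropneumoniae serovar 10 str. D13039	ApsCas9	1054	65.4
F2B8K0	Neisseria bacilliformis ATCC BAA-1200	NbaCas9	1077	66.5
J4KDT3	Haemophilus sputorum	HspCas9	1052	65.2
V9H606	Simonsiella muelleri ATCC 29453	SmuCas9	1063	62.2
W0Q6X6	Mannheimia sp. USDA-ARS-USMARC-1261	MspCas9	1047	65.7
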