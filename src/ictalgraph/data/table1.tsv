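patient	sex	age_years	mri_findings	pathology	onset_type	laterality	engel	implant
1	F	7	FCD (T and Ins)	DEV	SSO	L	IB	DE
2	M	18	Tumor (T)	ACQ	SSO	L	IC	SE+DE
3	F	16	FCD (T)	DEV	SSO	L	IA	SE+DE
4	M	2.2	Fr lesion	ACQ	FSO	R	IA	SE
5	F	18	Normal	NL	SSO	L	IA	SE
6	M	15	Hippocampal Sclerosis (anterior T)	DEV	FSO	L	IA	SE
7	M	5	FCD (T)	DEV	SSO	L	IA	SE
8	M	13	Encephalomalacia (P, superior T)	ACQ	SSO	L	IC	SE+DE
9	F	3	TSC (multifocal)	DEV	SSO	LR	IA	SE
10	M	4	FCD (Fr)	DEV	FSO	LR	IC	SE+DE
11	M	22	FCD	DEV	SSO	L	IA	SE+DE
12	M	13	FCD (Mesial T)	DEV	SSO	L	IA	SE
13	M	10	PMG (Fr, P)	DEV	FSO	L	IB	SE+DE
14	M	4	R frontal pole, superior Fr gyrus	DEV	FSO	L	IA	SE+DE
15	F	8	FCD (Posterior Fr)	DEV	FSO	L	IA	DE
16	F	18	FCD (Fr)	DEV	SSO	L	IA	SE+DE
17	F	7	Parietal lesion	DEV	SSO	L	IA	SE
18	F	6	PMG (P, T, O)	DEV	SSO	R	IA	DE
19	M	15	Normal	NL	SSO	L	IA	DE
20	M	13	Inferior Fr sulcus, pars Tr	DEV	FSO	L	IA	SE
21	F	4	Fr Lesion	Unknown	FSO	R	IA	DE
22	F	18	FCD (Fr)	MCD	SSO	LR	IB	SE+DE
23	F	10	Hippocampal sclerosis	DEV	SSO	L	IVB	SE+DE
24	M	6	FCD (Fr)	DEV	FSO	L	IIIA	SE
25	M	16	Normal	NL	FSO	LR	IIB	SE
26	M	16	Normal (mild gliosis)	NL	SSO	L	IIIA	SE
27	F	13	Normal	DEV	SSO	L	III	SE+DE
28	M	18	FCD	DEV	SSO	L	IIA	DE
29	F	22	Trauma	ACQ	FSO	R	IIB	SE
30	F	7	FCD (Fr operculum)	DEV	SSO	R	IIA	SE+DE
31	F	15	Hippocampal Formation	ACQ	SSO	L	IIIA	DE
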