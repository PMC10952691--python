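# Functional trait catalogue: 46 traits, boolean gene-composition expressions.
# Columns: Id, TraitGroup, TraitName, ShortTraitName, GeneTraitComposition.
Id	TraitGroup	TraitName	ShortTraitName	GeneTraitComposition
1	Carbon	Acetate transporter	ActP	+actP
2	Carbon	Calvin‐Benson‐Bassham cycle	Cbb	+((+cbbS+cbbL),cbbL_formII) + pgk + gapA+tpiA+fbaA+fbp + tkt + rpe + prk + sir+rplA+PPi_PFK
3	Carbon	Glycogen biosynthesis	Glg	+glgC+glgA
4	Carbon	Glyoxylate cycle	GlC	+mdh + CS+(acnA,acnB) + icl + aceB
5	Carbon	Lactate transporter	LakP	+lakP+dctQ+dctM
6	Carbon	Lactate utilization	Lut	+lutA+lutB+lutC
7	Carbon	Polyhydroxyalkanoate synthesis	Pha	+pha
8	Carbon	TCA cycle	TcaC	+CS+(acnA,acnB) + icd + ((+sucA+sucB+lpd),(+korA+korB)) + sucD+sucC+sdhA+sdhB+sdhC+sdhD+(fumA,fumC) + (mdh,mqo)
9	Carbon (and Nitrogen)	Cyanophycin synthesis	Cph	+cph
10	Hydrogen	NiFe hydrogenase‐based hydrogen oxidation	Hup	+hupS+hupL
11	Nitrogen	Ammonium transporter	AmtB	+amtB
12	Nitrogen	Assimilatory nitrate reduction	AsN	+narB+nirB+nirD
13	Nitrogen	Incomplete urea cycle	iUcy	+carA+carB+argF+argG+argH
14	Nitrogen	Nitrate transporter	Nrt	+nrtA+nrtB+nrtC
15	Nitrogen	Urea transporter	Urt	+urtA+urtB+urtC+urtD+urtE
16	Nitrogen	Urease mediated urea degradation	Ure	+ureA+ureB+ureC
17	Oxygen	Cytochrome aa3 based oxygen respiration	CytAA3	+coxA+coxB+coxC
18	Oxygen	Cytochrome ba3 based oxygen respiration	CytBA3	+cbaA+cbaB
19	Oxygen	Cytochrome bc1 complex mediated electron transport	Pet	+petA+petB+petC
20	Oxygen	Cytochrome bd based oxygen respiration	CytBD	+ndhA_to_ndhN+shdA+sdhB+sdhC+cydA+cydB
21	Oxygen	Cytochrome cbb3 based oxygen respiration	CytCBB3	+ccoN+ccoO+ccoP+ccoQ
22	Phosphorous	High‐affinity Na+/Pi symporter	Hnp	+hnp
23	Phosphorous	High‐affinity phosphate transporter	Pst	+pstA+pstB+pstC+pstS
24	Phosphorous	Low‐affinity phosphate transporter	Pit	+pit
25	Phosphorous	Polyphosphate usage	PHK and PHX	PHK, PHX
26	Sulphur	APR and SAT mediated sulphite oxidation	AprSat	+sat + aprB+aprA‐aprM
27	Sulphur	Reverse dissimilatory sulphate reductase mediated thiosulphate oxidation to sulphite	rDsr	+dsrA+dsrB+dsrC+dsrE+dsrF+dsrK+dsrH+tusA+rhd
28	Sulphur	Rhodanese mediated thiosulphate disproportionation	Tst	+tst
29	Sulphur	Sulphate permease	SulP	+sulP
30	Sulphur	Sulphate transporter	CysZ	+cysZ
31	Sulphur	Sulphydrogenase mediated sulphur reduction	Hyd	+hydA+hydB+hydC+hydD
32	Sulphur	Polysulphide reductase	Psr	+psrA+psrB+psrC
33	Sulphur	Sulphide dehydrogenase (flavocytochrome C) mediated sulphur oxidation	Fcsd	+fccA+fccB
34	Sulphur	Sulphide:quinone oxidoreductase mediated sulphur oxidation	Sqr	+sqr
35	Sulphur	Sulphite‐oxidizing enzyme mediated sulphite oxidation	Soe	+soeA+soeB+soeC
36	Sulphur	Sulphur globules proteins	Sgp	sgpCV1,sgpCV2,sgpA,sgpB,sgpC,sgpD
37	Sulphur	Sulphur oxygenase reductase mediated sulphur disproportionation	Sor	+sor
38	Sulphur	Thiosulphate transporter	YeeE	+yeeE
39	Sulphur	Truncated SOX mediated sulphur oxidation from thiosulphate to sulphate	tSox	+soxA+soxB+soxX+soxL
40	Interactions	CRISPR associated proteins	Cas	+cas1 + cas2 + ((cas3,cas7),cas9,cas10)‐cas4‐cas5‐cas6‐cas8‐cse1‐cse2‐csb1‐csb2‐cmr4‐cmr5‐cmr6‐csy1‐csy2‐csy3
41	Interactions	Type I secretion system	T1SS	+lapB+lapC+tolC
42	Interactions	Type II secretion system	T2SS	‐gspC+gspD+gspE+gspF+gspG‐gspH+gspI+gspJ+gspK‐gspL+gspM‐gspN
43	Interactions	Type V secretion system	T5SS	apeE,fhaC,yadA
44	Interactions	Type VI secretion system	T6SS	‐evpJ+tssA+tssB+tssC+tssD+tssE+tssF+tssG+tssH+tssI+tssJ+tssK+tssL+tssM
45	Motility	Flagellum	Fla	+filF+filI+filN+filP+filQ+filR+flhB+flhA+flgB+flgC+filE
46	Motility	Type IV pilus	T4P	+pilE+pilV+pilB+pilC+pilO+pilQ+pilM+pilN+pilP+pilT‐pilD
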