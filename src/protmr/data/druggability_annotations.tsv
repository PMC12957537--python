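uniprot_id	protein	tier	ttd_target_type
P29120	Proprotein convertase subtilisin/kexin type 1 (PCSK1)	Tier3A	literature_reported
P51858	Heparin binding growth factor (HDGF)	Tier3A	literature_reported
O60575	Serine peptidase inhibitor Kazal type 4 (SPINK4)	Tier3A	none
O95861	3'(2'),5'-Bisphosphate nucleotidase 1 (BPNT1)	Tier3B	none
P04275	Von Willebrand factor (VWF)	Tier1	successful
P15515	Histatin 1 (HTN1)	Tier3B	none
P15586	Glucosamine (N-acetyl)-6-sulfatase (GNS)	Tier3B	none
Q8IWU5	Sulfatase 2 (SULF2)	none	clinical_trial
P01298	Pancreatic polypeptide (PPY)	Tier3A	clinical_trial
Q9NNX6	CD209 molecule (CD209)	Tier3B	literature_reported
O43175	Phosphoglycerate dehydrogenase (PHGDH)	none	literature_reported
O75475	PC4 and SRSF1 interacting protein 1 (PSIP1)	none	patented_recorded
P20742	PZP alpha-2-macroglobulin like (PZP)	Tier3A	none
P22888	Luteinizing hormone/choriogonadotropin receptor (LHCGR)	Tier1	successful
P23141	Carboxylesterase 1 (CES1)	Tier1	successful
P36404	ADP ribosylation factor like GTPase 2 (ARL2)	none	literature_reported
Q13976	Protein kinase CGMP-dependent 1 (PRKG1)	Tier2	literature_reported
Q99519	Neuraminidase 1 (NEU1)	Tier3A	successful
P13726	Coagulation factor III, tissue factor (F3)	Tier1	successful
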