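uniprot_id	protein	direction	study
A6NHS7	MANSC domain containing 4 (MANSC4)	Negative	Gudjonsson;Sun;Ferkingstad
P29120	Proprotein convertase subtilisin/kexin type 1 (PCSK1)	Positive	Gudjonsson;Sun;Ferkingstad
P31946	Tyrosine 3-monooxygenase (YWHAB)	Positive	Gudjonsson
P51858	Heparin binding growth factor (HDGF)	Positive	Gudjonsson
Q13137	Calcium binding and coiled-coil domain 2 (CALCOCO2)	Negative	Gudjonsson
Q15113	Procollagen C-endopeptidase enhancer (PCOLCE)	Positive	Gudjonsson;Sun;Ferkingstad
Q8TEY5	CAMP responsive element binding protein 3 like 4 (CREB3L4)	Positive	Gudjonsson;Sun;Ferkingstad
Q9NXS2	Glutaminyl-peptide cyclotransferase like (QPCTL)	Negative	Gudjonsson;Sun
O60575	Serine peptidase inhibitor Kazal type 4 (SPINK4)	Negative	Ferkingstad
O95861	3'(2'),5'-Bisphosphate nucleotidase 1 (BPNT1)	Positive	Ferkingstad
P31946	Tyrosine 3-monooxygenase (YWHAB)	Positive	Ferkingstad
P36871	Phosphoglucomutase 1 (PGM1)	Negative	Ferkingstad
P51858	Heparin binding growth factor (HDGF)	Positive	Ferkingstad
Q9UKK9	Nudix hydrolase 5 (NUDT5)	Positive	Ferkingstad
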