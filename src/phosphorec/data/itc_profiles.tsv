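# ITC thermodynamic profiles of the anti-phosphosite clones A4 and C7
# (wildtype and heavy-chain alanine mutants, Chothia numbering) titrated
# with the phosphorylated Akt peptide; the two "nonphospho" rows are the
# non-phosphorylated-peptide titrations of the wildtypes.
# Kd in nM (triplicate mean +/- SD), enthalpies in kcal/mol.
# dG_printed/TdS_printed are the reported one-decimal values for cross-checks;
# they are never used in the derivation. T_K: assumed 298.15 K (not reported).
clone	antigen	Kd_nM	Kd_sd_nM	dH	dH_sd	T_K	dG_printed	dG_printed_sd	TdS_printed	TdS_printed_sd
A4 WT	phospho	3.34	0.63	-24.4	0.4	298.15	-11.6	0.1	-12.8	0.4
A4 H-S53A	phospho	3.55	1.72	-24.9	0.5	298.15	-11.6	0.3	-13.3	0.3
A4 H-S54A	phospho	6.95	2.32	-23.5	0.2	298.15	-11.2	0.2	-12.3	0.4
A4 H-T56A	phospho	4.00	0.89	-23.0	0.6	298.15	-11.5	0.1	-11.5	0.6
A4 H-R95A	phospho	no_binding
C7 WT	phospho	26.9	14.2	-14.4	0.7	298.15	-10.4	0.4	-4.0	1.0
C7 H-S52A	phospho	664	34	-11.1	0.1	298.15	-8.4	0.0	-2.7	0.1
C7 H-R53A	phospho	no_binding
C7 H-S54A	phospho	95.3	20.9	-13.3	0.5	298.15	-9.6	0.1	-3.7	0.6
A4 WT	nonphospho	1120
C7 WT	nonphospho	no_binding
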