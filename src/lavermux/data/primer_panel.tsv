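# Six-species laver multiplex PCR panel plus universal 18S rRNA internal control.
# Set membership follows the concentration-bearing panel layout (Set 1 = NH, NT, NY, CTRL;
# Set 2 = ND, PS, NS, CTRL). An alternative grouping by market class — stone laver
# {ND, NS, PS} vs traditional laver {NY, NT, NH} — circulates for the same assay but is
# inconsistent with the per-set primer concentrations, so it is not used here.
# Sequences are 5'->3'; whitespace inside sequences is cosmetic and stripped on load.
set_id	species_code	species_name	gene	primer_name	role	sequence	expected_size_bp	concentration_uM
1	NH	Neoporphyra haitanensis	rbcS	HA_F	forward	CCT TCC AGA CCT AAC TGA TGA AC	127	1.6
1	NH	Neoporphyra haitanensis	rbcS	HA_R	reverse	TCC CCA TAA TTC CCA ATA TGA G	127	1.6
1	NT	Neopyropia tenera	rbcL	TE_F	forward	CTA CTT GAA AGC GAA ACA GAT ATA	169	1.8
1	NT	Neopyropia tenera	rbcL	TE_R	reverse	CAC CAC CAA ACT GAA GAA CC	169	1.8
1	NY	Neopyropia yezoensis	rbcL	YE_F	forward	GCT GTT AAA GCT CTT CGC TTG	211	0.8
1	NY	Neopyropia yezoensis	rbcL	YE_R	reverse	AAT CAA GAC CGC CTT TCA GG	211	0.8
1	CTRL	Universal eukaryote control	18S rRNA	18S_F	forward	GGT GCA TGG CCG TTC TTA GT	89	0.2
1	CTRL	Universal eukaryote control	18S rRNA	18S_R	reverse	TGC GCG CAC CTA TTT AGC AG	89	0.2
2	ND	Neoporphyra dentata	rbcS	DE_F	forward	GAG CAA ATT AAT AAG CAG CTT ACT TAC	274	0.6
2	ND	Neoporphyra dentata	rbcS	DE_R	reverse	CTG GCT CGT TAG CAG GTC G	274	0.6
2	PS	Pyropia suborbiculata	rbcL	SU_F	forward	CAG GTG CAA CTG CTA ATA AAG	117	2.6
2	PS	Pyropia suborbiculata	rbcL	SU_R	reverse	GTC CAC AAG TTT TAG CTG CA	117	2.6
2	NS	Neoporphyra seriata	rbcL	SE_F	forward	CTG GTA AAA ATT ATG GAA GAG TGG TG	195	0.32
2	NS	Neoporphyra seriata	rbcL	SE_R	reverse	TCG CGG CCG TTA CGT TTA AG	195	0.32
2	CTRL	Universal eukaryote control	18S rRNA	18S_F	forward	GGT GCA TGG CCG TTC TTA GT	89	0.4
2	CTRL	Universal eukaryote control	18S rRNA	18S_R	reverse	TGC GCG CAC CTA TTT AGC AG	89	0.4
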