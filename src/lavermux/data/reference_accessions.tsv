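# GenBank records carrying the chloroplast rbcL/rbcS markers for the six target laver
# species and the non-target seaweeds used to establish primer specificity. Most species
# have a single record covering both genes. Pyropia ishigecola has only one accession;
# Undaria crenata appears in the wet-lab specificity panel but has no published accession.
species	algae_class	gene	accession
Neoporphyra dentata	red	rbcL	LC521919.1
Neoporphyra dentata	red	rbcS	LC521919.1
Neoporphyra haitanensis	red	rbcL	KC464603.1
Neoporphyra haitanensis	red	rbcS	KC464603.1
Neoporphyra seriata	red	rbcL	LC505532.1
Neoporphyra seriata	red	rbcS	LC505532.1
Pyropia suborbiculata	red	rbcL	AB118580.1
Pyropia suborbiculata	red	rbcS	AB118580.1
Neopyropia yezoensis	red	rbcL	MT876197.1
Neopyropia yezoensis	red	rbcS	MT876197.1
Neopyropia tenera	red	rbcL	AB118576.1
Neopyropia tenera	red	rbcS	AB118576.1
Porphyra koreana	red	rbcL	LC327005.1
Porphyra koreana	red	rbcS	LC327005.1
Neopyropia katadae	red	rbcL	AB118583.1
Neopyropia katadae	red	rbcS	AB118583.1
Pyropia kuniedae	red	rbcL	LC505521.1
Pyropia kuniedae	red	rbcS	LC505521.1
Pyropia ishigecola	red	rbcL	GQ427224.1
Undaria pinnatifida	brown	rbcL	KP298002.1
Undaria pinnatifida	brown	rbcS	KP298002.1
Costaria costata	brown	rbcL	KR336545.1
Costaria costata	brown	rbcS	KR336545.1
Saccharina japonica	brown	rbcL	JQ405663.1
Saccharina japonica	brown	rbcS	JQ405663.1
Saccharina sculpera	brown	rbcL	JX442492.1
Saccharina sculpera	brown	rbcS	AF318981.1
Sargassum fusiforme	brown	rbcL	MN794016.1
Sargassum fusiforme	brown	rbcS	MN794016.1
Gracilaria vermiculophylla	red	rbcL	OP978508.1
Gracilaria vermiculophylla	red	rbcS	OP978508.1
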