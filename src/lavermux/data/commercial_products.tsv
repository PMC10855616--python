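# 40 processed laver products surveyed from Asian markets: declared label and the
# multiplex-PCR detection pattern (+ = amplified by that species' primer pair).
# The 89 bp 18S rRNA internal control amplified in every product (not tabulated).
product_id	country	market	food_type	declared_label	NY	NT	NH	ND	PS	NS
P1	Japan	Online	seasoned	Laver	+	-	-	-	-	-
P2	Japan	Online	seasoned	Laver	+	-	-	-	-	-
P3	Japan	Online	seasoned	Laver	+	-	-	-	-	-
P4	Japan	Online	seasoned	Laver	+	-	-	-	-	-
P5	China	Online	dried	N. haitanensis	-	-	+	-	-	-
P6	China	Online	dried	N. haitanensis	-	-	+	-	-	-
P7	China	Online	dried	N. haitanensis	-	-	+	-	-	-
P8	Thailand	Online	seasoned	Laver	+	-	-	-	+	-
P9	Thailand	Online	seasoned	Laver	+	-	-	-	-	-
P10	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	+	+	+
P11	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	+	+	+
P12	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	+	+	+
P13	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	+	+	+
P14	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	+
P15	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	+
P16	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	+
P17	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	-
P18	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	-	-
P19	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	-	-
P20	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	-
P21	Republic of Korea	Gyeonggi	roasted	Laver	+	-	-	+	+	-
P22	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	-
P23	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	-
P24	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	-
P25	Republic of Korea	Gyeonggi	roasted	Laver	+	-	-	+	+	+
P26	Republic of Korea	Jeolla	roasted	N. dentata	+	-	-	+	+	-
P27	Republic of Korea	Gyeonggi	roasted	Laver	+	-	-	-	+	+
P28	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	-	-
P29	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	+
P30	Republic of Korea	Jeolla	roasted	N. dentata	+	-	-	+	+	-
P31	Republic of Korea	Jeolla	roasted	N. tenera	+	-	-	-	+	-
P32	Republic of Korea	Jeolla	roasted	N. tenera	+	-	-	+	+	-
P33	Republic of Korea	Gyeonggi	roasted	Laver	+	-	-	+	-	-
P34	Republic of Korea	Jeolla	roasted	N. tenera	+	-	-	+	+	-
P35	Republic of Korea	Gyeonggi	roasted	Laver	+	-	-	-	-	+
P36	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	-
P37	Republic of Korea	Jeolla	seasoned	N. dentata	+	-	-	+	+	+
P38	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	-
P39	Republic of Korea	Gyeonggi	seasoned	Laver	+	-	-	-	+	-
P40	Republic of Korea	Gyeonggi	roasted	Laver	+	-	-	-	-	-
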