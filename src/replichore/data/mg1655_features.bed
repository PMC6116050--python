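# MG1655 chromosome feature fixture (BED6 + feature-type column).
# Coordinates are 0-based, half-open, on the 4,641,652 bp E. coli K-12
# MG1655 reference (U00096.3).  oriC is placed at its reference-annotation
# coordinate; ectopic origins are placed at their genetic-map integration
# sites (oriZ 7.4 min / lac-proximal, oriX 59 min / pheA, oriY 76.5 min /
# malT) converted linearly (1 min = L/100 bp).  ter-site and rrn-operon
# coordinates are taken from the reference annotation and are approximate
# (+/- a few kb); downstream tests treat them with tolerances.
# Columns: chrom  start  end  name  score  strand  type
# score: origins 1=active 0=inactive; transcribed features 1=highly transcribed.
# strand: ter sites '+'=blocks clockwise (increasing-coordinate) forks,
#         '-'=blocks counter-clockwise forks; transcribed features give the
#         direction of transcription ('+'=cw, '-'=ccw).
# length=4641652
MG1655	3925744	3925745	oriC	1	.	origin
MG1655	343482	343483	oriZ	0	.	origin
MG1655	2738575	2738576	oriX	0	.	origin
MG1655	3550864	3550865	oriY	0	.	origin
MG1655	1341639	1341640	terA	0	-	ter
MG1655	1682161	1682162	terB	0	+	ter
MG1655	1609157	1609158	terC	0	+	ter
MG1655	1278848	1278849	terD	0	-	ter
MG1655	1246320	1246321	terE	0	-	ter
MG1655	2312906	2312907	terF	0	+	ter
MG1655	2377536	2377537	terG	0	+	ter
MG1655	683700	683701	terH	0	-	ter
MG1655	1088900	1088901	terI	0	-	ter
MG1655	2735500	2735501	terJ	0	+	ter
MG1655	4035531	4040906	rrnA	1	+	transcribed
MG1655	4166659	4172057	rrnB	1	+	transcribed
MG1655	3941808	3946869	rrnC	1	+	transcribed
MG1655	3423423	3429049	rrnD	1	-	transcribed
MG1655	4208147	4213234	rrnE	1	+	transcribed
MG1655	2726070	2731600	rrnG	1	-	transcribed
MG1655	223771	229240	rrnH	1	+	transcribed
MG1655	3435000	3475000	GRP	1	-	transcribed
MG1655	575000	576195	IS5_575	0	.	is_element
MG1655	1394000	1395195	IS5_1394	0	.	is_element
MG1655	2288000	2289195	IS5_2288	0	.	is_element
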