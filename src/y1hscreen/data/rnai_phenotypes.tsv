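# Transcription factors whose RNAi knockdown along the dorsal midline
# (pnr-Gal4 driver) altered adult abdominal pigmentation, with the published
# phenotype categories:
#   A6_female_only        reduced dark pigment in female segment A6 only
#   A5_A6_reduced         reduced/lost dark pigment in A5 and/or A6, one or both sexes
#   multi_segment_reduced reduced/lost dark pigment in multiple segments
#   increased             increased dark pigment in stripes and/or midline peak
# TFs falling in more than one category carry semicolon-separated codes.
tf_id	affected	categories
Chrac-14	1	A6_female_only
hb	1	A6_female_only
Hesr	1	A6_female_only
Hr38	1	A6_female_only
Lim3	1	A6_female_only
noc	1	A6_female_only
SoxN	1	A6_female_only
Abd-B	1	A5_A6_reduced
CG30020	1	A5_A6_reduced
fru	1	A5_A6_reduced
sima	1	A5_A6_reduced
Sox102F	1	A5_A6_reduced
brm	1	multi_segment_reduced
C15	1	multi_segment_reduced
CG1845	1	multi_segment_reduced
lab	1	multi_segment_reduced
sd	1	multi_segment_reduced
vvl	1	multi_segment_reduced
Tip60	1	increased
CG11984	1	increased
bab1	1	increased
ato	1	increased;A6_female_only
BEAF-32	1	increased;A6_female_only
dsx	1	increased;A5_A6_reduced
Eip78C	1	increased;A6_female_only
Hr46	1	increased;A6_female_only
Hr78	1	increased;A6_female_only
jing	1	multi_segment_reduced;increased
Met	1	increased;A6_female_only
pnt	1	increased;A6_female_only
Su(z)12	1	increased;A6_female_only;A5_A6_reduced
ush	1	increased;A6_female_only
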