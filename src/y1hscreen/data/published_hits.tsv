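# Published per-species hit matrix for the yellow enhancer Y1H screen:
# number of enhancer fragments from each Drosophila species (mel, pse, will)
# that each transcription factor bound at p < 0.005 for >= 2 3AT levels, day 7.
tf_id	mel	pse	will
Hr78	4	1	1
CG8765	0	0	2
Hr38	2	0	0
ind	0	0	2
ab	1	0	0
Abd-B	0	0	1
bigmax	1	0	0
C15	0	0	1
caup	1	0	0
CG11085	0	0	1
CG1233	1	0	0
CG1529	1	0	0
CG1621	0	1	0
CG1647	1	0	0
CG17806	0	0	1
CG31666	0	0	1
CG33695	1	0	0
CG5591	1	0	0
CG7101	1	0	0
CG7928	0	0	1
CG8216	1	0	0
CG9437	1	0	0
CG9650	0	1	0
crm	1	0	0
d4	0	0	1
dsx	0	0	1
Eip78C	0	1	0
Gsc	0	0	1
Hey	0	0	1
HLH4C	0	1	0
Hr46	0	1	0
Lim3	0	0	1
NfI	1	0	0
Oaz	1	0	0
Oli	0	1	0
otp	0	0	1
p53	0	0	1
pdm2	0	0	1
pfk	1	0	0
pnt	0	0	1
ro	0	0	1
slp2	1	0	0
stwl	1	0	0
Su(var)3-7	0	0	1
toe	0	0	1
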