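# surface	expansion	kind
# curated fixture dictionary: frequent clinical abbreviations, acronyms and
# recurring typos (surface forms are matched whole-token, case-insensitively)
pt	patient	abbreviation
hx	history	abbreviation
tr	trauma	abbreviation
fx	fracture	abbreviation
lac	laceration	abbreviation
ctsn	contusion	abbreviation
hmtm	hematoma	abbreviation
swlg	swelling	abbreviation
sprn	sprain	abbreviation
wnd	wound	abbreviation
brse	bruise	abbreviation
shldr	shoulder	abbreviation
hd	head	abbreviation
lwr	leg	abbreviation
chst	chest	abbreviation
wrst	wrist	abbreviation
fce	face	abbreviation
kn	knee	abbreviation
hnd	hand	abbreviation
abd	abdomen	abbreviation
ank	ankle	abbreviation
evng	evening	abbreviation
ngt	night	abbreviation
mrng	morning	abbreviation
aftn	afternoon	abbreviation
tdy	today	abbreviation
ystd	yesterday	abbreviation
hm	home	abbreviation
wrkpl	workplace	abbreviation
strt	street	abbreviation
schl	school	abbreviation
prk	park	abbreviation
stn	station	abbreviation
hsbnd	husband	abbreviation
wf	wife	abbreviation
nbr	neighbor	abbreviation
strgr	stranger	abbreviation
bfrnd	boyfriend	abbreviation
cwkr	coworker	abbreviation
brthr	brother	abbreviation
knf	knife	abbreviation
btl	bottle	abbreviation
hmr	hammer	abbreviation
stk	stick	abbreviation
pnch	punch	abbreviation
kck	kick	abbreviation
aggr	aggression	abbreviation
occ	occipital	abbreviation
reg	region	abbreviation
rt	right	abbreviation
lt	left	abbreviation
loc	loss of consciousness	acronym
c/o	complains of	acronym
ed	emergency department	acronym
fractre	fracture	typo
shouder	shoulder	typo
nigth	night	typo
contusoin	contusion	typo
pateint	patient	typo
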