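# lemma	pos	supersenses (';' separates frequency ranks, ',' separates ties within a rank)
# agents
husband	NOUN	NOUN_PERSON
wife	NOUN	NOUN_PERSON
neighbor	NOUN	NOUN_PERSON
stranger	NOUN	NOUN_PERSON
brother	NOUN	NOUN_PERSON
boyfriend	NOUN	NOUN_PERSON
coworker	NOUN	NOUN_PERSON
acquaintance	NOUN	NOUN_PERSON;NOUN_COGNITION
classmate	NOUN	NOUN_PERSON
patient	NOUN	NOUN_PERSON
father	NOUN	NOUN_PERSON
# modes and instruments
punch	NOUN	NOUN_ACT
kick	NOUN	NOUN_ACT
slap	NOUN	NOUN_ACT
aggression	NOUN	NOUN_ACT;NOUN_FEELING
knife	NOUN	NOUN_ARTIFACT
stick	NOUN	NOUN_ARTIFACT
bottle	NOUN	NOUN_ARTIFACT
belt	NOUN	NOUN_ARTIFACT
hammer	NOUN	NOUN_ARTIFACT
stone	NOUN	NOUN_OBJECT,NOUN_SUBSTANCE
# times
evening	NOUN	NOUN_TIME
night	NOUN	NOUN_TIME
morning	NOUN	NOUN_TIME
afternoon	NOUN	NOUN_TIME
midnight	NOUN	NOUN_TIME
today	NOUN	NOUN_TIME
tonight	NOUN	NOUN_TIME
yesterday	NOUN	NOUN_TIME
# locations
home	NOUN	NOUN_LOCATION
workplace	NOUN	NOUN_LOCATION
street	NOUN	NOUN_LOCATION
school	NOUN	NOUN_LOCATION
park	NOUN	NOUN_LOCATION
station	NOUN	NOUN_LOCATION
courtyard	NOUN	NOUN_LOCATION
# body parts
arm	NOUN	NOUN_BODY
head	NOUN	NOUN_BODY;NOUN_PERSON
leg	NOUN	NOUN_BODY
shoulder	NOUN	NOUN_BODY
face	NOUN	NOUN_BODY
wrist	NOUN	NOUN_BODY
chest	NOUN	NOUN_BODY;NOUN_ARTIFACT
knee	NOUN	NOUN_BODY
hand	NOUN	NOUN_BODY
nose	NOUN	NOUN_BODY
ankle	NOUN	NOUN_BODY
abdomen	NOUN	NOUN_BODY
# lesion types
fracture	NOUN	NOUN_STATE
contusion	NOUN	NOUN_STATE
trauma	NOUN	NOUN_STATE;NOUN_EVENT
wound	NOUN	NOUN_STATE
bruise	NOUN	NOUN_STATE
laceration	NOUN	NOUN_STATE
hematoma	NOUN	NOUN_STATE
sprain	NOUN	NOUN_STATE
swelling	NOUN	NOUN_PHENOMENON
occipital	ADJECTIVE	ADJ_ALL
distorting	ADJECTIVE	ADJ_ALL
blunt	ADJECTIVE	ADJ_ALL
# other content words appearing in narratives
pain	NOUN	NOUN_STATE
loss	NOUN	NOUN_ACT
consciousness	NOUN	NOUN_COGNITION
history	NOUN	NOUN_COGNITION
region	NOUN	NOUN_LOCATION
right	ADJECTIVE	ADJ_ALL
left	ADJECTIVE	ADJ_ALL
ladder	NOUN	NOUN_ARTIFACT
stairs	NOUN	NOUN_ARTIFACT
bicycle	NOUN	NOUN_ARTIFACT
ball	NOUN	NOUN_ARTIFACT
door	NOUN	NOUN_ARTIFACT
kitchen	NOUN	NOUN_ARTIFACT
accident	NOUN	NOUN_EVENT
collision	NOUN	NOUN_EVENT
fall	NOUN	NOUN_EVENT;NOUN_ACT
emergency	NOUN	NOUN_STATE
department	NOUN	NOUN_GROUP
reports	VERB	VERB_COMMUNICATION
denies	VERB	VERB_COMMUNICATION
states	VERB	VERB_COMMUNICATION
complains	VERB	VERB_COMMUNICATION
suffers	VERB	VERB_BODY
assaulted	VERB	VERB_CONTACT
attacked	VERB	VERB_CONTACT
beaten	VERB	VERB_CONTACT
struck	VERB	VERB_CONTACT
punched	VERB	VERB_CONTACT
fell	VERB	VERB_MOTION
slipped	VERB	VERB_MOTION
tripped	VERB	VERB_MOTION
crashed	VERB	VERB_MOTION
playing	VERB	VERB_COMPETITION
denied	VERB	VERB_COMMUNICATION
accidental	ADJECTIVE	ADJ_ALL
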