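# Default violence-frame schema: per-field PoS/supersense compatibility sets
# and the seed terms whose mean embedding forms each field's prototype vector.
similarity_threshold: 0.5
fields:
- name: AGENT
  allowed_pos: [NOUN]
  allowed_sst: [NOUN_PERSON]
  seed_terms: [husband, wife, known_person]
- name: MODE_INSTRUMENT
  allowed_pos: [NOUN]
  allowed_sst: [NOUN_OBJECT, NOUN_ARTIFACT, NOUN_STATE, NOUN_SUBSTANCE, NOUN_FEELING, NOUN_ACT]
  seed_terms: [punch, aggression, knife]
- name: TIME
  allowed_pos: [NOUN]
  allowed_sst: [NOUN_TIME]
  seed_terms: [evening, night, today]
- name: LOCATION
  allowed_pos: [NOUN]
  allowed_sst: [NOUN_LOCATION]
  seed_terms: [home, workplace]
- name: BODY_PART
  allowed_pos: [NOUN]
  allowed_sst: [NOUN_BODY]
  seed_terms: [arm, head]
- name: LESION_TYPE
  allowed_pos: [NOUN, ADJECTIVE]
  allowed_sst: [NOUN_STATE, ADJ_ALL, NOUN_PHENOMENON]
  seed_terms: [fracture, contusion, trauma]
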