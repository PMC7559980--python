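# multiword locutions merged into single extended tokens before frame filling
known person
bus station
loss of consciousness
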