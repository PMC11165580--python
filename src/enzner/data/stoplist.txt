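phase
database
case
base
phrase
increase
decrease
release
disease
purchase
phase-
cease
erase
lease
please
chase
showcase
staircase
suitcase
uppercase
lowercase
ukase
vase
ease
unease
grease
crease
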