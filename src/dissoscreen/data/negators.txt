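# negating words, one per line
cannot
cant
couldnt
didnt
doesnt
dont
isnt
neither
never
no
none
nor
not
shouldnt
wasnt
without
wont
wouldnt
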