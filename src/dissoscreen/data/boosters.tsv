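# booster words: term<TAB>strength shift
absolutely	+2
completely	+2
deeply	+1
especially	+1
extraordinarily	+2
extremely	+2
fairly	-1
genuinely	+1
highly	+1
immensely	+2
incredibly	+2
marginally	-1
mildly	-1
moderately	-1
particularly	+1
quite	+1
rather	-1
really	+1
remarkably	+1
seriously	+1
slightly	-1
some	-1
somewhat	-1
totally	+1
truly	+1
utterly	+2
very	+1
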