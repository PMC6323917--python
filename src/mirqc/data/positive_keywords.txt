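# Word stems signalling functional content; matched case-insensitively at
# word-prefix boundaries ("regulat" hits regulates, regulation, regulatory).
express
target
regulat
inhibit
suppress
promot
activat
repress
induc
modulat
silenc
mediat
govern
control
apopto
prolifer
differentiat
migrat
invas
angiogen
tumor
oncogen
pathway
signal
bind
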