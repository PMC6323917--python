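# Word stems signalling measurements, calculations or experimental
# approaches rather than biology; matched at word-prefix boundaries.
measur
normaliz
normalis
quantif
calculat
qpcr
rt-pcr
pcr
blot
plot
incubat
centrifug
transfect
assay
kit
elisa
luciferase
primer
reagent
microarray
cohort
p-value
fold-change
threshold
stain
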