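# Common scientific terms that obscure functional information in word clouds.
# The first four entries are the canonical examples; the rest are curated
# extensions and the list is expected to be refined over time.
expressed
cell
sequence
gene
cells
genes
sequences
mirna
mirnas
microrna
micrornas
mir
using
used
study
studies
analysis
results
result
data
shown
showed
show
found
fig
figure
table
level
levels
respectively
compared
significantly
significant
observed
previously
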