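# mirqc

Quality control and functional summarization for microRNA gene annotations.

Public microRNA catalogs accumulate annotations of very uneven quality:
genuine Drosha/Dicer products sit next to mis-annotated fragments of other
RNAs. `mirqc` implements two desk-scale pipelines for researchers curating
or consuming such annotations:

1. **Read-pattern confidence classification.** Canonical microRNA biogenesis
   leaves a distinctive signature in small RNA-seq data mapped to a hairpin
   precursor: reads stack on *both* arms, the two matures form a duplex with
   ~2-nt 3′ overhangs, and the 5′ ends of the reads are highly consistent.
   `mirqc` reduces a mapped read stack to per-arm statistics and applies the
   standard rule set:

   - **high confidence** — matures annotated on both arms; duplex 3′
     overhangs within [0, 4] nt; ≥ 20 reads assigned to each arm; ≥ 50 % of
     each arm's reads sharing the modal 5′ end;
   - **low confidence** — > 100 reads mapped across the locus while < 30 %
     of the reads on the more abundant arm share a 5′ end (lots of data, the
     wrong shape);
   - everything else is **undetermined** — lack of data is never by itself
     evidence against an annotation.

2. **Literature mining.** MicroRNA gene names are standardized, so they can
   be found in full text with regular expressions (`miR-#`, `miRNA-#`,
   `microRNA-#`, plus exceptional names such as let-7, lin-4 and bantam).
   `mirqc` splits labeled article sections into sentences, recognizes names,
   drops table/reference extracts (> 25 distinct names or > 200 words),
   resolves species and family-level mentions (a bare "let-7" in a human
   paper expands to all 11 human let-7 genes), scores sentences for
   functional content (positive stems like *target*, *regulat*, *inhibit*;
   negative stems for measurement/protocol vocabulary), ranks articles per
   gene by summed sentence score, and builds word-cloud term-frequency
   tables (word clouds are shown only for genes with ≥ 10 sentences).

A seeded simulator (`mirqc.simulate`) generates perfect-stem hairpin loci
with exactly realized duplex overhangs and read stacks with controlled
depth and 5′ homogeneity, so every classifier path and threshold boundary
is testable without downloading sequencing data.

## Worked example

Simulate a canonical locus, classify it, and mine a two-sentence abstract:

```sh
$ mirqc simulate --preset high --seed 1 --out-prefix locus
$ mirqc confidence --hairpins locus.hairpins.fa --structures locus.structures.txt \
    --matures locus.matures.tsv --alignments locus.alignments.tsv --out report.tsv
1 loci: 1 high, 0 low, 0 undetermined -> report.tsv
```

`report.tsv` holds the call, the per-criterion booleans, and the measured
metrics:

```
accession   call  ... total_reads assigned_5p assigned_3p modal_fraction_5p modal_fraction_3p overhang_drosha_end overhang_dicer_end
SIM0000001  high  ... 400         200         200         0.905             0.945             2                   2
```

200 reads per arm (≥ 20), modal 5′ fractions 0.905/0.945 (≥ 0.5) and 2-nt
3′ overhangs at both duplex ends (within [0, 4]) — every high-confidence
rule passes. The literature side:

```sh
$ mirqc litmine --corpus corpus.jsonl --out-sentences sentences.tsv --out-rankings rankings.tsv
2 scored sentences, 1 genes -> sentences.tsv, rankings.tsv
$ cat sentences.tsv
gene_accession  species_code  article_id  score  text
MI0000077       hsa           22685542    4      MicroRNA-21 governs TORC1 activation in renal cancer cell proliferation and invasion.
MI0000077       hsa           22685542    2      miR-21 targets PTEN and regulates growth.
```

Both name variants resolve to the same gene (mir-21, accession MI0000077);
the scores count functional-keyword hits (*governs*, *activation*,
*proliferation*, *invasion* → +4; *targets*, *regulates* → +2), and the
article's rank score is their sum (6). `mirqc wordcloud --sentences
sentences.tsv --gene MI0000077 --out tf.tsv` then builds the stop-word-
filtered term-frequency table.

All of this is equally available as a library — see `mirqc.confidence.classify`,
`mirqc.litmine.mine_corpus` and `mirqc.summarize.term_frequencies`.

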