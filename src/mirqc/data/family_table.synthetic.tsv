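# Synthetic desk-scale stand-in for the miRBase family/gene table, holding
# the 11 human let-7 genes plus a selection of well-known entries; accessions
# follow the miRBase MI format but the table is a packaged fixture, not a
# database export.
species_code	family_key	gene_name	gene_accession
hsa	let-7	let-7a-1	MI0000060
hsa	let-7	let-7a-2	MI0000061
hsa	let-7	let-7a-3	MI0000062
hsa	let-7	let-7b	MI0000063
hsa	let-7	let-7c	MI0000064
hsa	let-7	let-7d	MI0000065
hsa	let-7	let-7e	MI0000066
hsa	let-7	let-7f-1	MI0000067
hsa	let-7	let-7f-2	MI0000068
hsa	let-7	let-7g	MI0000433
hsa	let-7	let-7i	MI0000434
hsa	mir-16	mir-16-1	MI0000070
hsa	mir-16	mir-16-2	MI0000115
hsa	mir-19	mir-19a	MI0000073
hsa	mir-21	mir-21	MI0000077
hsa	mir-23	mir-23b	MI0000439
hsa	mir-26	mir-26a-1	MI0000083
hsa	mir-26	mir-26a-2	MI0000750
hsa	mir-27	mir-27b	MI0000440
hsa	mir-29	mir-29a	MI0000087
hsa	mir-29	mir-29b-1	MI0000105
hsa	mir-29	mir-29b-2	MI0000107
hsa	mir-34	mir-34a	MI0000268
hsa	mir-122	mir-122	MI0000442
hsa	mir-126	mir-126	MI0000471
hsa	mir-130	mir-130a	MI0000448
hsa	mir-133	mir-133a-1	MI0000450
hsa	mir-133	mir-133a-2	MI0000451
hsa	mir-133	mir-133b	MI0000822
hsa	mir-181	mir-181b-1	MI0000270
hsa	mir-181	mir-181b-2	MI0000683
hsa	mir-206	mir-206	MI0000490
hsa	mir-214	mir-214	MI0000290
hsa	mir-221	mir-221	MI0000298
hsa	mir-222	mir-222	MI0000299
hsa	mir-296	mir-296	MI0000747
hsa	mir-328	mir-328	MI0000804
hsa	mir-378	mir-378a	MI0000786
hsa	mir-378	mir-378b	MI0016750
hsa	mir-451	mir-451a	MI0001729
hsa	mir-451	mir-451b	MI0017360
hsa	mir-499	mir-499a	MI0003183
hsa	mir-9718	mir-9718	MI0031597
mmu	mir-21	mir-21a	MI0000569
mmu	mir-1	mir-1a-1	MI0000139
mmu	mir-1	mir-1a-2	MI0000652
dme	let-7	let-7	MI0000416
dme	bantam	bantam	MI0000387
cel	let-7	let-7	MI0000001
cel	lin-4	lin-4	MI0000002
cel	lsy-6	lsy-6	MI0000312
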