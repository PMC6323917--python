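# MicroRNA gene names that do not follow the numbered miR-# scheme.
# Column 2: whether the family takes optional letter / copy-number suffixes.
# The historical list is open-ended; this is a curated best-effort superset.
let-7	suffixed
lin-4	suffixed
bantam	plain
lsy-6	plain
iab-4	plain
iab-8	plain
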