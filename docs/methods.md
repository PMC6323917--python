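# Methods

## Confidence classification of hairpin annotations

### Model and assumptions

A microRNA hairpin processed by Drosha and Dicer yields a mature:star
duplex whose 3′ ends protrude by ~2 nt at both cut sites, and small-RNA
reads from a genuine locus therefore (i) cover both arms, (ii) respect the
duplex register encoded in the secondary structure, and (iii) share 5′ ends
with high consistency, because the 5′ cut position determines the seed
sequence and is under selection. The classifier operationalizes this
signature as six booleans (high confidence) plus two (low confidence) over
a per-locus read profile.

Inputs are taken as given: hairpin sequences (FASTA), one secondary
structure per hairpin (dot-bracket), mature annotations (1-based inclusive
TSV, or mature FASTA located by exact substring search), and pre-mapped,
pre-collapsed read alignments (TSV or single-reference SAM, forward strand
only — hairpins are single-stranded). Alignment is trusted but verified:
any entry whose sequence does not exactly match the hairpin at its stated
start is dropped and counted in a rejection report. Multi-mapping across
hairpins is not re-resolved; the criteria are per-locus.

### Read assignment and profile statistics

A read is assigned to the arm whose mature interval, extended by 2 nt on
each side, covers ≥ 50 % of the read's length; when both arms qualify the
larger overlap wins and exact ties stay unassigned. The extension tolerates
templated 3′ trimming/tailing while loop-spanning fragments remain
unassigned. Counts are collapse counts (the thresholds are read-depth
rules), and count conservation — assigned(5p) + assigned(3p) + unassigned =
total — holds for every stack.

5′ homogeneity is the fraction of an arm's assigned reads sharing the
**modal** observed 5′ start. Comparing reads with each other (rather than
with the annotated end) lets the statistic also critique a mis-annotated
mature whose reads agree with each other but not with the annotation. With
zero assigned reads the fraction is undefined and the criterion fails for
lack of data.

### Duplex overhang geometry

For matures 5p = [s₅, e₅] and 3p = [s₃, e₃] (inclusive ends) on a pair
table *pt*: anchor each mature at its first paired base within a 5-nt scan
window of its 5′ end — i ≥ s₅ for the 5p mature, u ≥ s₃ for the 3p mature.
Then

- overhang at the hairpin-base (Drosha) end = (e₃ − pt[i]) − (i − s₅),
- overhang at the loop (Dicer) end = (e₅ − pt[u]) − (u − s₃).

Values are signed (negative = recessed 3′ end). An end with no paired base
inside the scan window is *undefined*; undefined ends fail the criterion —
high confidence should not rest on unmeasurable geometry. The [0, 4] window
is enforced at **both** duplex ends by default (both cuts leave 3′
overhangs); `overhang_mode="either"` relaxes this to one end.

### Decision rules and parameters

| parameter | default | role |
|---|---|---|
| `min_reads` | 20 | per-arm assigned depth, inclusive |
| `min_modal_fraction` | 0.50 | per-arm 5′ homogeneity, inclusive |
| `min_overhang`, `max_overhang` | 0, 4 | inclusive overhang window, both ends |
| `low_min_total_reads` | 100 | low flag needs total **strictly greater** |
| `low_max_modal_fraction` | 0.30 | and dominant-arm fraction **strictly less** |
| `scan_window` | 5 nt | paired-base search past a mature 5′ end |
| `extension` | 2 nt | read-assignment interval extension |

Inclusive/strict readings follow the printed rules exactly (≥ 20, ≥ 50 %,
> 100, < 30 %, overhang 0–4 inclusive). The dominant arm is the one with
more assigned reads; an exact tie resolves to 5p (the rule set is silent on
ties). High takes precedence: a locus satisfying the high rules is never
reported low. Loci passing neither are undetermined, with all measured
metrics reported so a user can see which criterion failed and why.

The "≥ 20 overlapping reads" rule is applied to reads pooled across all
datasets contributing to the stack; per-dataset accounting would need
dataset labels the collapsed format does not carry (thresholds are
configurable if a user wants a stricter pooled cut).

## Simulator

`make_locus` builds a perfect-stem hairpin analytically: a 5′ flank
(default 6 nt), an `arm_length` (22 nt) front stem, a loop (12 nt, ≥ 3), the
reverse-complement back stem and a 3′ flank. The pair table is constructed
directly, never folded, so the requested duplex overhangs (default 2/2) are
realized *exactly*: measurement is the inverse of construction, verified
for all overhangs 0–6 across seeds. `simulate_reads` draws per-arm reads:
5′ start canonical with probability `homogeneity` (default 0.9), otherwise
uniformly shifted within ±`shift_range` (3 nt, never 0); length jittered
within ±`trim_range` (2 nt); all reads are exact hairpin substrings,
collapsed to (sequence, start, count). The generator is deterministic per
seed, and that determinism is part of its public contract.

Presets: `high` (200 reads/arm, homogeneity 0.9 — passes every rule),
`low` (600 reads/arm, homogeneity 0.05, shift 5 — abundant but scattered),
`sparse` (5/3 reads — undetermined).

What the simulator does *not* model: sequencing errors, non-templated
tailing, imperfect stems with bulges, cross-locus multi-mapping, or
realistic expression distributions. Passing tests therefore demonstrate the
correctness of the statistics and decision logic under clean generative
conditions, not robustness to alignment artifacts in real libraries.

## Boundary sweeps (calibration checks)

`mirqc.sweeps` rebuilds fixture loci and walks each rule across its
boundary; `scripts/acceptance.py` packages the four sweeps:

- per-arm depth k = 1…40 with 100 % homogeneity and 2-nt overhangs: the
  high call first appears at k = 20;
- per-arm depth 1000 with m reads at the canonical start and the rest
  shifted +1, m = 400…600 in steps of 10: since the histogram has two bins
  its true modal fraction is max(m, 1000−m)/1000, and the smallest modal
  percentage yielding a high call is 50;
- all reads on one arm spread near-evenly over 20 start positions (modal
  fraction ~5 %), total n = 50…150: the largest n not flagged low is 100;
- 1000 reads on one arm with the modal start holding p % and the rest
  spread thinly, p = 20…40: the smallest p no longer flagged low is 30.

The sweeps use wide-flank (12 nt) loci so shifted starts stay on the
hairpin, and run in well under a second.

## Literature mining

Sentence splitting is a deterministic rule-based segmenter: split at
`.!?` + whitespace + (capital, digit, or lower-case microRNA-name opener
such as "miR-21 …"), protecting a fixed abbreviation list (Fig., et al.,
e.g., single initials) — decimals are never candidates because no
whitespace follows the dot. The splitter is a pluggable contract; any
segmenter producing `Sentence` objects can replace it.

Name recognition normalizes unicode hyphen variants to "-", then matches
`(microRNA|miRNA|miR)[-␣]?<number><letter?>(-<copy>)?(-<5p|3p>)?`
case-insensitively with word-boundary guards, plus a configurable
exceptional-name lexicon (let-7 and lin-4 with optional suffixes; bantam,
lsy-6, iab-4, iab-8 as plain names — the historical list is open-ended, so
the shipped lexicon is a documented best-effort superset). Overlaps resolve
leftmost-longest. Normalization lower-cases, maps every prefix to `mir-`,
keeps letter/copy suffixes and strips the arm into a separate field.

Filtering eliminates sentences with > 25 distinct normalized names
(counted **before** family expansion, matching the filter's
table-detection intent) or > 200 whitespace tokens; both thresholds pass
inclusively at their printed values.

Species assignment: a sentence naming a subset of the article's species is
assigned exactly those; naming none, it is assigned all of them. A sentence
naming *only* species absent from the article's list still assigns all
article species, and when listed and unlisted species are both named the
listed ones win — the rule set does not specify these cases, so the
package takes the interpretation that foreign names alone never veto.

Family expansion matches by gene name: a gene belongs to a mention when the
gene name minus the mention is empty, a single letter, a copy number, or
letter + copy number ("let-7" → let-7a-1 … let-7i; "let-7a" → let-7a-1..3;
"mir-133a-2" → itself; "mir-21" never matches mir-214). The packaged family
table is a synthetic desk-scale fixture (see its header) holding the 11
human let-7 genes and other well-known entries.

Scoring counts word-prefix stem hits: positives are functional vocabulary
(express, target, regulat, inhibit, …), negatives are
measurement/protocol vocabulary (measur, qpcr, normaliz, …); score =
positive − negative hits, each token counting at most once per lexicon, so
scores are additive over concatenation. Both lists ship as editable config
files — they are meant to be refined. Article ranking sums sentence scores
per (gene, article); ties break by sentence count (desc) then article id
(asc) for reproducibility.

## Term-frequency summaries

Tokens are lower-case alphanumeric-plus-internal-hyphen; tokens shorter
than 3 characters, purely numeric tokens, English stop words and a curated
scientific stop list (expressed, cell, sequence, gene, …) are removed
before counting. Tokenization choices (≥ 3 chars, hyphen-aware) are this
package's own; nothing in the rule set defines "word". Word-cloud
eligibility is ≥ 10 associated sentences, inclusive. Rendering is an
optional matplotlib helper (deterministic golden-angle layout); the tested
contract is the frequency table, since images are not meaningfully
assertable.

## Numerical and degenerate-input choices

- Coordinates: 0-based half-open in memory, 1-based inclusive on disk.
- Modal-start ties take the smallest position; the modal *fraction* is
  unaffected by ties.
- Zero-read arms: modal fraction undefined → relevant criteria fail;
  classification never errors on missing data.
- Duplicate alignment rows are summed; negative counts and
  sequence-mismatched rows are rejected, not silently kept.
- All randomness flows through a single integer seed per simulation; no
  global RNG state is touched.

## Known limitations

- Exact-match read validation: mismatched or soft-clipped alignments are
  rejected rather than tolerated, so stacks from permissive aligners may
  shrink; the rejection report makes this visible.
- The overhang measurement anchors on the first paired base within a fixed
  scan window; highly bulged duplex ends beyond that window are reported
  undefined rather than guessed.
- The sentence splitter and species lexicon are rule-based and
  English-only; recall on heavily formatted text (tables flattened into
  prose) relies on the name/word-count filter.
- Family expansion is only as complete as the loaded family table.
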