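# Methods

## Scope and model

`tmmkit` characterizes the telomere maintenance mechanism (TMM) of a tumor
from tumor/control whole-genome sequencing. Dividing tumors must solve
telomere attrition either by reactivating telomerase (typically through TERT
alterations) or by the recombination-based *alternative lengthening of
telomeres* (ALT, associated with truncating ATRX/DAXX loss). The two routes
leave distinct genomic footprints, and each pipeline stage quantifies one of
them:

1. **Telomere content** — telomeric reads per million reads in the 48–52% GC
   bin, compared tumor vs control as a log2 ratio. ALT tumors gain telomere
   content; telomerase tumors tend to lose it.
2. **TMM mutation annotation** — rule-based grouping into ATRX/DAXX-trunc,
   ATRX/DAXX-nontrunc, the TERT-modification subtypes, mixed, and wild type.
3. **Telomere insertions** — somatic junctions where telomere repeats joined
   non-telomeric sequence, found from discordant pairs and split reads.
4. **TVR singletons** — non-canonical NNNGGG repeats isolated inside runs of
   canonical TTAGGG, whose tumor/control abundance diverges from the
   telomerase expectation in ALT.
5. **Structural context** — breakpoint burden and breakage-fusion-bridge
   (BFB) events called from fold-back inversions.
6. **ALT classifier** — a down-sampled random forest over eight features
   producing a per-sample ALT probability.

## Telomeric read recognition

A read is telomeric when it contains at least ⌊6·L/100⌋ non-overlapping
instances of TTAGGG, TCAGGG, TGAGGG, or TTGGGG on either strand (scanning
left to right, advancing six bases on a match, one otherwise) **and** is
unmapped or mapped with MAPQ < 8. The per-length scaling reduces to the flat
six-instance rule at the standard L = 100; a flat mode is available
(`scale_threshold=False`) for libraries where the flat rule is preferred.
Reads shorter than 30 bp are outside the method's domain and raise
`ShortReadError`. The scan is implemented with a compiled alternation regex,
whose non-overlapping left-to-right semantics are exactly the greedy rule;
tests verify it against an explicit character-scanning oracle.

Telomere content is telomeric reads per million reads with GC fraction in
[0.48, 0.52] (inclusive; N bases excluded from the fraction; secondary,
supplementary and duplicate records skipped everywhere). Telomeric reads
themselves sit at 50% GC and therefore contribute to the denominator — the
definition counts *all* reads in the bin. TERRA counting uses the same scan
with a read-length-dependent threshold k (7 for 45–50 bp, 10 for 75–76 bp,
14 for 99–101 bp; linearly interpolated on the anchors and floored for
intermediate lengths, overridable).

## Insertion calling

Discordant telomere pairs have exactly one telomeric mate; the anchor mate
must be uniquely mapped with MAPQ > 30. Tumor anchors are clustered by
single-linkage with a 1-kb maximum gap (chosen over fixed 1-kb windows to
avoid bin-boundary artifacts; a windowed mode would change no test here). A
cluster is a candidate iff it holds ≥ 3 tumor pairs and no control
discordant pair overlaps its span — the control check uses telomere-discordant
pairs, not arbitrary discordant pairs. Junctions are refined from soft-clipped
reads: a split read supports position p when its clip point is p and the
clipped segment contains ≥ 1 TTAGGG (or CCCTAA; strand-normalized), is
≥ 12 bp long, and is ≥ 80% telomeric. The clip-length and purity gates, plus
the panel-of-normals filter (drop regions recurrent in ≥ 15 panel controls),
replace manual inspection with reproducible automated proxies. Ties between
junction positions break toward most split support, then smallest coordinate.

Sidedness: an insertion is two-sided when a partner in opposite orientation
with the same forward-strand repeat lies within the downstream (increasing
coordinate) 10 kb; pairing is nearest-first and symmetric. Copy-number
change: segments < 10 kb are discarded, the junction is assigned to the
closest remaining boundary within 50 kb (consensus boundaries can be off by
that much); no boundary or equal flanks → neutral, flank difference > 4
copies → complex, otherwise loss/gain of the segment on the junction side
where the telomere now sits (the broken distal fragment). SVs within 10 kb —
including other telomere insertions — set `nearby_sv`; supplied
chromothripsis regions set `in_chromothripsis`.

**Microhomology** is the number of bases the junction can slide left while
the chromosomal flank stays consistent with the repeat phase of the inserted
sequence, computed by base-by-base overlap extension against both the G-rich
repeat and its reverse complement; flanks that themselves end in telomeric
hexamers (interstitial repeats) are flagged ambiguous. Tests check the
implementation against an exhaustive junction-sliding oracle.

## TVR singletons and divergence

Extracted telomere reads are strand-normalized to G-rich orientation, then
scanned at every offset for NNNGGG with the same greedy de-duplication; a hit
is recorded only when all six base qualities are ≥ 20 (the cursor still
advances six on a sequence match, so a low-quality hexamer never creates
spurious off-frame hits). Canonical TTAGGG hits are tabulated but excluded
from variant statistics. An occurrence is a *singleton* when both 18-bp
flanks are exactly (TTAGGG)3; read-edge occurrences with truncated flanks
count in arbitrary context but can never be singletons.

Counts are normalized to total sample reads; tumor/control log2 ratios use a
symmetric +1 pseudocount so patterns absent on both sides give exactly zero.
For each singleton pattern, the expected log2 ratio at a given
telomere-content log2 ratio is taken from an OLS line fitted through the
telomerase (TERT-mod) samples; the *divergence* is the observed minus
expected value. For arbitrary-context TVRs the expectation is the identity
line (expected pattern ratio = content ratio).

## TMM annotation

Truncating ATRX/DAXX = frameshift indel, stop gain, or SV breakpoint in the
gene body; other simple nucleotide variants are non-trunc; intronic-only
deletions are ignored, and a user-supplied (sample, gene) blacklist handles
known false positives that would otherwise need visual curation. TERT
modifications: promoter hotspot mutation (≥ 2 alt reads and ≥ 20% frequency,
unioned with consensus SNV calls; zero coverage is "not callable", distinct
from negative), a plus-strand SV breakpoint within 20 kb upstream of the TSS
(TERT is minus-strand, so upstream runs toward higher hg19 coordinates — the
direction is configurable), and copy number ≥ mean ploidy + 6 at the locus.
Precedence: ATRX/DAXX alteration + any TERT modification → mixed; ≥ 2 TERT
classes → TERT-mult; single class as named; otherwise wild type. All
landmarks live in `TERTConfig` (hg19 defaults), keeping the logic
build-agnostic.

## BFB detection

Inversion-type SVs (same chromosome, same strand on both ends) qualify as
fold-backs when the breakpoints are < 20 kb apart, no other inversion is
interleaved with them (in either order), and a copy-number boundary lies
within 50 kb of either breakpoint — the same positional-uncertainty window
used for insertion CN assignment, since no tighter definition of "at the
inversion site" is defensible given segment-boundary noise. Two or more
fold-backs on one arm (centromere coordinates supplied as configuration;
centromere-spanning inversions are assigned by midpoint and flagged) call a
BFB event.

## Classifier

Features: content log2 ratio, insertion count, breakpoint count, and the
five singleton divergences (TGAGGG, TCAGGG, TTGGGG, TTCGGG, TTTGGG). Samples
with missing features are excluded from training and flagged for prediction.
Training uses stratified 10-fold CV; within each training fold the majority
class is down-sampled to the minority size (per fold rather than globally,
so no test sample ever influences its own training set). The forest uses 500
trees, √8 = 2 features per split, unlimited depth — the conventional
defaults of the randomForest family — all configurable. Out-of-fold scores
are pooled for ROC/AUC; sensitivity and specificity are reported at the 0.5
vote-fraction threshold. The statistics layer exposes two-sided Wilcoxon
rank-sum tests (exact for small tie-free samples), Bonferroni and
Benjamini–Hochberg adjustment, Spearman correlation, and the OLS models of
insertion counts on content and breakpoints with/without interaction.

## Synthetic data: what it emulates, and what it does not

The generator is first-class, tested code that plants every signal the
pipeline looks for: telomeric reads built from hexamer repeats with
configurable per-hexamer TVR substitution rates and singleton rates (a
placed singleton always keeps three untouched t-type flanks); background
read pairs with exact-composition GC (0.50 inside the normalization bin,
0.30 outside, bin membership Bernoulli per read); discordant pairs (MAPQ-60
anchor, unmapped telomeric mate) and soft-clipped split reads whose clip
point equals the planted junction; control-side support and panel recurrence
for filter testing; and class-conditional Gaussian feature cohorts
(telomerase class standard normal, ALT class mean-shifted with the observed
directions — positive content/insertions/breakpoints/TTCGGG/TGAGGG/TCAGGG/
TTGGGG, negative TTTGGG). Output is plain SAM/FASTA/TSV over a small
(~700 kb) random reference; a fixed seed gives byte-identical files.

It deliberately does **not** model sequencing errors, indels, chimeric
artifacts, alignment ambiguity, real GC bias curves, or genome-scale
interval structure. Passing tests therefore demonstrate that the rules are
implemented exactly as stated and recover planted truth under the stated
read-selection contracts — not that the thresholds are optimal on real data.

### Default simulation conditions

Defaults mirror the study conditions where stated: 100-bp reads, the
63 vs 266 class imbalance for down-sampling experiments, planted content
ratios of 2× and 0.5× for recovery checks. Where unstated, values were fixed
once at desk-scale realism: control telomeric fraction 0.01 with 5×10^5
reads per sample for content recovery (≈5,000 control telomeric reads, so
the ±0.1 log2 tolerance sits at ≈4 sampling standard errors); 4,000 control
telomere reads per sample and a 2% per-pattern singleton rate for the
divergence experiment (4× enrichment/depletion of TTCGGG/TTTGGG in the ALT
class, recovered as ≈±2 log2 divergence); 20 planted insertions spanning the
support-threshold grid; 20 seeds for the null-AUC sweep (run with 200 trees;
the null distribution of pooled CV AUC is data-limited, not tree-limited).

## Numerical choices and degenerate inputs

- Repeat counting: greedy non-overlapping scan; regex alternation order is
  irrelevant because all patterns have length 6.
- GC bin boundaries inclusive; all-N reads have undefined GC and fall
  outside every bin.
- Junction ties: most split support, then smallest coordinate.
- Pseudocount +1 on both sides of every TVR ratio.
- Rank-sum test: exact enumeration for ≤ 30 pooled tie-free observations,
  normal approximation otherwise; fully tied input returns p = 1 with a
  warning.
- Regression fits require ≥ 3 finite points and non-degenerate x.
- Zero GC-bin reads, zero contents, uncovered TERT locus, and single-class
  training sets raise errors rather than returning sentinel values.

## Known limitations

- No absolute telomere length (kb) — that needs external calibration.
- No per-chromosome telomere assignment; no proximal/distal placement of
  TVRs (undetermined by short-read WGS).
- Chromothripsis is consumed as an annotation, not called.
- The classifier's headline operating characteristics on real cohorts depend
  on access-controlled data; here they are demonstrated on simulations with
  planted effect sizes.
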