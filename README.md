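# tmmkit

Characterization of **telomere maintenance mechanisms (TMMs)** in cancer from
tumor/control whole-genome sequencing.

Every dividing tumor must counteract telomere attrition, either by
reactivating telomerase (usually through *TERT* alterations) or by the
recombination-based **alternative lengthening of telomeres (ALT)**, which is
strongly associated with truncating *ATRX*/*DAXX* loss. The two mechanisms
leave different footprints in WGS data, and `tmmkit` computes all of them:

- **Telomere content**: reads carrying ≥ 6 telomeric repeats
  (TTAGGG/TCAGGG/TGAGGG/TTGGGG, either strand) per 100 bp that are unmapped
  or have MAPQ < 8, normalized per million reads with GC content in 48–52%,
  compared as log2(tumor/control). TERRA abundance from RNA-seq with
  read-length-dependent thresholds.
- **TMM mutation annotation**: ATRX/DAXX<sup>trunc/non-trunc</sup>,
  TERTp<sup>mut</sup> (relaxed promoter caller: ≥ 2 alt reads, ≥ 20%
  frequency), TERTp<sup>SV</sup> (plus-strand breakpoint ≤ 20 kb upstream of
  the TSS), TERT<sup>amp</sup> (≥ ploidy + 6 copies), TERT<sup>mult</sup>,
  mixed, wild type; plus enhancer-overlap classification of TERT-juxtaposed
  breakpoints.
- **Somatic telomere insertions**: 1-kb candidate regions with ≥ 3
  tumor-specific discordant telomere pairs and none in the matched control,
  junctions refined by ≥ 3 TTAGGG-containing split reads, panel-of-normals
  filtering (≥ 15 controls), one-/two-sided classification (10-kb downstream
  partner rule), copy-number change, nearby-SV/chromothripsis context, and
  junction microhomology.
- **TVR singletons**: NNNGGG telomere variant repeats in arbitrary vs
  singleton context ((TTAGGG)<sub>3</sub>-NNNGGG-(TTAGGG)<sub>3</sub>), with
  per-pattern divergence from the telomerase-sample regression of pattern
  log2 ratio on telomere-content log2 ratio.
- **Breakage-fusion-bridge**: fold-back inversions (< 20 kb span, no
  reciprocal partner, copy-number change at the site); ≥ 2 per chromosome arm
  call a BFB event.
- **ALT classifier**: down-sampled random forest with 10-fold
  cross-validation over 8 features (content ratio, insertion count,
  breakpoint count, 5 singleton divergences), emitting per-sample ALT
  probabilities, plus the rank-sum/Spearman/OLS statistics layer.

A first-class synthetic-data module generates SAM/FASTA/TSV tumor/control
pairs with planted ground truth (telomeric fractions, TVR and singleton
rates, insertion junctions with controlled support, CN/SV tables, cohort
feature matrices), so the whole pipeline is testable without
access-controlled data.

## Worked example

```python
from tmmkit.synthetic_data import SimulationConfig, PlantedInsertion, generate_sample_pair
from tmmkit.telomere_content import compute_telomere_content, content_log2_ratio
from tmmkit.insertion_detection import call_insertions, insertions_to_frame

cfg = SimulationConfig(
    seed=7,
    n_background_reads=20_000,
    telomere_fraction_tumor=0.02,    # ALT-like content gain: 2x the control
    telomere_fraction_control=0.01,
    planted_insertions=[
        PlantedInsertion("chr1", 50_000, "telomere-right", "G",
                         n_discordant_pairs=5, n_split_reads=3),
        PlantedInsertion("chr1", 58_000, "telomere-left", "G",
                         n_discordant_pairs=4, n_split_reads=3, partner=0),
    ],
)
pair = generate_sample_pair(cfg, "example")

tumor = compute_telomere_content(pair.tumor_sam, sample_id="tumor")
control = compute_telomere_content(pair.control_sam, sample_id="control")
ratio = content_log2_ratio(tumor, control)
print(f"tumor content   {tumor.content:8.1f}  ({tumor.n_telomeric_reads} telomeric / {tumor.n_gc_bin_reads} GC-bin reads)")
print(f"control content {control.content:8.1f}  ({control.n_telomeric_reads} telomeric / {control.n_gc_bin_reads} GC-bin reads)")
print(f"log2 ratio      {ratio.log2_ratio:8.3f}")

calls = insertions_to_frame(call_insertions(pair.tumor_sam, pair.control_sam))
print(calls[["chrom", "position", "orientation", "n_discordant", "n_split", "sidedness"]].to_string(index=False))
```

Output:

```
tumor content    66966.4  (417 telomeric / 6227 GC-bin reads)
control content  37073.2  (228 telomeric / 6150 GC-bin reads)
log2 ratio         0.853
chrom  position    orientation  n_discordant  n_split sidedness
 chr1     50000 telomere-right             5        3 two_sided
 chr1     58000  telomere-left             4        3 two_sided
```

The content log2 ratio estimates the planted 2× telomere gain (log2 = 1;
here 0.853 from 417 vs 228 sampled telomeric reads — within sampling error
at this depth). Both planted junctions are recovered at their exact base
positions with their planted support counts, and because they face each
other within 10 kb with the same forward-strand repeat they are classified
as a two-sided insertion pair — a telomere bridging both ends of a
chromosomal break.

A CLI mirrors the library (`tmmkit simulate | content | insertions | bfb |
tvr | classify-train | stats`); run `tmmkit --help`.

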