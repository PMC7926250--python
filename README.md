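# ximark

Quantifying how repressive histone marks accumulate on the inactive X
chromosome (Xi), for computational epigenomicists studying X-chromosome
inactivation (XCI). In the hybrid (C57BL/6 x CAST/EiJ) mouse ES cell system
with an inducible *Xist* allele on the B6 haplotype, SNPs make chromatin
signal allele-resolvable: after doxycycline induction, nChIP-seq fragments
assigned to the B6 allele report Xi-specific accumulation of H4K20me1 and
H3K27me3, and live-cell mintbody imaging reports the same marks' enrichment
inside the growing *Xist* RNA domain. `ximark` implements the full analysis
over a synthetic-data generator with known ground truth, so every stage is
testable without external downloads:

- **Synthetic data** — diploid toy genome with SNPs, allele-tagged
  fragments whose Xi-allele counts follow programmed accumulation curves,
  gene/peak/TPM annotations, planted chromosome-specific repeats, and
  two-channel time-lapse movies.
- **sgRNA repeat-target search** — enumerate PAM-adjacent 22/23-mers
  (N{20,21}GG), score chromosome specificity
  f_c(s)/(1 + Σ_{i≠c} f_i(s)) > 19, and report sub-megabase focal regions R
  whose outside-copy count satisfies n_R ≤ (f_c − 20·Σ_off − 20)/21,
  i.e. region specificity ≥ 20.
- **Allelic counting and normalization** — SNP-based allele assignment,
  largest-overlap window counting over a 10-kb tiling, TMM factors
  (Robinson & Oshlack) on autosomal consensus-peak counts, library scaling
  (10^7/total), t=0 subtraction and 24-h dynamic-range rescaling.
- **Dynamics** — per-window four-parameter log-logistic fits
  f(t) = c + (d−c)/(1 + exp(b(ln t − ln e))), residual filtering
  (< mean + 1.5 SD), ED50 (= e) capped at 24 h, paired Wilcoxon mark
  comparison, IC35-based k-means silencing classes, per-category Pearson
  correlations, scale-regions metagene profiles.
- **Imaging quantification** — *Xist* domain segmentation, background-
  normalized mintbody enrichment traces aligned to *Xist* onset, aggregate
  curves with quartiles, BH-adjusted onset and mark-divergence detection.

## Worked example

Run the full pipeline on the default synthetic design (700-kb induced
chromosome "cX" plus a 600-kb autosome; 2 marks x 5 timepoints
{0,4,8,12,24} h x 2 replicates; 30 imaged cells per mark):

```bash
ximark run-all --seed 0 --out results/demo
```

which prints (abridged):

```json
{
 "ed50_median_h_H4K20me1": 7.629631256046205,
 "ed50_median_h_H3K27me3": 9.480678107432253,
 "ed50_median_difference_h": -1.884025944434649,
 "wilcoxon_pvalue": 0.018042631439243954,
 "onset_delay_min_H4K20me1": 45.0,
 "onset_delay_min_H3K27me3": 45.0,
 "divergence_min": 165.0,
 "h3k27me3_threshold": 0.05552456030348503,
 "gene_classification_accuracy": 1.0,
 "sgrna_sensitivity": 1.0,
 "sgrna_specificity": 1.0,
 "correlation_intergenic": 0.5946176178516088
}
```

Reading the output: the generator programs H4K20me1 inflection times around
7 h and H3K27me3 around 10 h; the fitted per-window ED50 medians (7.6 h vs
9.5 h) recover that ordering and the paired Wilcoxon on windows with ED50
< 24 h for both marks calls it significant (p = 0.018). Both marks' imaging
arms detect mintbody enrichment 45 min after *Xist* domain onset (the
programmed 3-frame delay at 15 min/frame), and the two marks' traces
diverge ~2.5 h after onset, where one mark is programmed to plateau while
the other keeps rising. The planted chromosome-specific repeat is found and
the off-target decoy rejected; gene activity calls match the planted truth,
with the bivalency threshold recovered from the premarking density
crossing. Per-stage tables (tracks, fits, categories, traces) and a
SHA-256 manifest land in `results/demo/`.

Library use mirrors the CLI: `ximark.simulate` generates inputs,
`ximark.sgrna.find_targets`, `ximark.allelic`, `ximark.windows`,
`ximark.dynamics`, `ximark.imaging` expose each stage, and
`ximark.run_all(PipelineConfig(...), outdir)` chains them.

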