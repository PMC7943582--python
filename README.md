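# qclip

Windowed CLIP-seq peak calling, 3'UTR regulatory-feature characterization,
and TRAP-seq knockout differential expression for STAR-family RNA-binding
proteins such as QKI — with a seeded synthetic-data generator that makes the
whole pipeline testable against known ground truth.

## The problem

QKI binds mRNAs at a bipartite response element (QRE): a full binding motif
`ACUAAY` within 20 nt of a half site `YAAY`, typically in 3'UTRs. Mapping
where it binds in vivo (CLIP-seq against IgG and Input backgrounds) and
what its loss does to bound transcripts on cell-type-specific ribosomes
(CRISPR knockout + TRAP-seq) requires a chain of statistics that this
package implements as a reusable, tested library:

- **Peak calling.** The genome is tiled into 50-nt windows per strand;
  reads are counted by their 5' base; a zero-truncated negative binomial
  (ZTNB) fitted to merged CLIP counts over nonzero windows gives upper-tail
  p-values, Benjamini-Hochberg corrected genome-wide (FDR < 0.05), and
  adjacent significant windows merge into peaks.
- **Dual-background enrichment.** Peaks are kept as high-confidence when a
  negative-binomial GLM likelihood-ratio test shows > 2-fold enrichment of
  the CLIP replicates over *both* IgG and Input at FDR < 0.05
  (filtering: >= 5 counts in >= 2 samples).
- **3'UTR characterization.** QRE/PAS scanning (`A[AT]TAAA`), matched-length
  control UTRs with artificial sites, conservation over +/-200 nt flanks
  (equal-variance t test), the relative position of sites between stop
  codon and nearest PAS (100 at the stop, 0 at the PAS), Mann-Whitney UTR
  length tests, and anchor-centered metagene profiles with 95% bootstrap
  ribbons (1000 anchor resamples).
- **Knockout analysis.** TMM-normalized NB GLM contrasts (KO vs WT TRAP;
  TRAP vs Input), an astrocyte/neuron marker quality gate, the mean percent
  change of CLIP targets (t test vs background), and Fisher overlap tests
  of knockout-responsive sets against immature (P7-like) and mature
  (P32-like) gene sets, with Haldane-corrected odds ratios and Woolf CIs.

## Worked example

Run the full synthetic study (generate genome/reads, call peaks, enrich,
characterize UTRs) and the knockout analysis:

```bash
qclip run-clip --seed 1 --outdir out_clip
qclip run-trap --seed 1 --outdir out_trap
```

`run-clip` prints (abridged):

```json
{
 "windows": 63554,
 "windows_significant": 554,
 "peaks": 125,
 "high_confidence_peaks": 115,
 "high_confidence_genes": 100,
 "sensitivity": 1.0,
 "precision": 1.0
}
```

125 merged peaks were called at genome-wide FDR 0.05; 115 pass the dual
2-fold/FDR filter, mapping to 100 genes that recover the generator's 100
planted target genes exactly (sensitivity and precision 1.0). Of all called
peaks, 96.8% lie in 3'UTRs (`peak_features.tsv`), and conservation around
bound sites exceeds matched controls by ~0.80 score units.

`run-trap` prints (abridged):

```json
{
 "marker_check": {"median_log2fc_positive": 2.04, "p_separation": 3.0e-11},
 "target_shift": {"mean_percent_change": -8.45, "p": 6.2e-04},
 "maturation": {"up_vs_p7_or": 4.78, "down_vs_p32_or": 5.03}
}
```

The marker gate confirms the TRAP pull-down (positive markers near the
planted 4-fold, log2 ~ 2); CLIP targets drop by 8.5% on knockout (planted
effect: -10%, partially attenuated by composition normalization — see
`docs/methods.md`); and knockout-up/down transcripts over-represent the
immature/mature maturation sets with odds ratios ~5.

Library use without the CLI mirrors the same stages
(`qclip.simulate_genome`, `qclip.fit_ztnb`, `qclip.nb_glm_lrt`,
`qclip.overlap_test`, ...); `qclip --help` lists the granular subcommands
(`callpeaks`, `enrich`, `utrfeatures`, `metagene`, `trapde`, `setstats`).

## Layout

```
src/qclip/
  genome_model.py     GTF/FASTA model, UTR derivation, feature labels
  synthetic_data.py   seeded generator + ground truth
  peak_calling.py     windowing, ZTNB null, BH, peak merging
  count_model.py      filtering, TMM, NB dispersion, GLM LRT
  utr_features.py     motif/QRE/PAS scanning, controls, conservation
  metagene.py         anchored coverage profiles, bootstrap ribbons
  set_stats.py        Fisher overlaps, shifts, proportions
  pipeline.py         orchestration and reports
  cli.py              command-line interface
docs/methods.md       model, parameter and design documentation
```
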