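# exonrnp

Tools for two computational problems that arise when dissecting how the
polypyrimidine-tract binding protein PTBP1 represses a cassette exon:

1. **Comparative SILAC-MS quantification of exon RNP complexes.** Exon
   ribonucleoprotein complexes purified in three regulatory states — a
   PTBP1-repressed complex, an active early complex, and the exon
   definition complex (EDC) — are compared by mixing pairs of complexes
   assembled in light (¹²C) and heavy (¹³C Arg/Lys) nuclear extract.
   The package computes light/heavy peptide ratios, aggregates them per
   protein (median of log₂ ratios), normalizes to the cap-binding
   proteins CBP20/CBP80 (bound once per capped RNA, hence equimolar in
   every complex), and derives fold changes between states — directly for
   a mixed pair, or by a ratio of ratios that cancels a shared reference
   state:

   fold(A/B) = R̂(A/C) / R̂(B/C),  where R̂ = R / geomean(R_CBP20, R_CBP80)

   A spiked-reference design (three light complexes against one common
   heavy spike) and NSAF spectral counting
   (NSAFᵢ = (SpCᵢ/Lᵢ) / Σⱼ SpCⱼ/Lⱼ) are also implemented.

2. **Positional classification of iCLIP binding clusters.** Clusters
   around PTBP1-repressed exons (≥15 percentage-point ΔPSI upon PTBP1
   depletion) are assigned to zones: **a** distal upstream intron,
   **b** branch point/polypyrimidine tract, **c** exon, **d** downstream
   intron. A cluster midpoint more than 100 nt upstream of the 3'ss AG
   is `a`; within 100 nt, a position-weight-matrix scan of the intron 3'
   end (consensus cucAg) locates the branch adenosine, and midpoints
   more than 25 nt upstream of it are still `a`, otherwise `b`. Per-exon
   zone multisets are summarized into binding architectures
   (distal-only, contains-b, contains-c, mixed, unbound) over a cohort.

Because raw MS and iCLIP data are large and external, a synthetic-data
module generates peptide tables, spectral counts and exon/cluster
cohorts with planted ground truth (fold changes, mixing errors, zone
labels, branch points), so the entire pipeline is testable end to end.

## Worked example

```python
from exonrnp import SilacSimConfig, generate_silac_experiment, quantify_experiment

cfg = SilacSimConfig(
    n_proteins=20, peptides_per_protein=(5, 8), log2_noise_sd=0.2,
    mixing_error=1.3,
    fold_changes={"LUC7L2": {"active_vs_repressed": 1.2, "edc_vs_repressed": 9.6}},
    seed=4)
peptides, truth = generate_silac_experiment(cfg)
result = quantify_experiment(peptides)
row = result["comparisons"]["edc_vs_active"].table.set_index("protein").loc["LUC7L2"]
print(f"{row['fold_change']:.2f}  {row['enrichment_class']}")
```

prints

```
7.43  enriched
```

i.e. the planted 8-fold EDC-over-active enrichment of LUC7L2 is
recovered (7.43 under measurement noise) even though the experiment
carried a 1.3× mixing error, which the CBP20/CBP80 anchor normalization
removed. The same flow is available from the shell:

```bash
exonrnp simulate --seed 4 --out sim/
exonrnp quantify --peptides sim/peptides.tsv --anchors CBP20,CBP80 --out quant/
exonrnp nsaf --counts sim/spectral_counts.tsv --out nsaf.tsv
exonrnp classify --exons sim/exons.bed --clusters sim/clusters.bed \
    --fasta sim/genes.fasta --out clf/
```

`clf/cohort_summary.json` then reports, for the default 95-exon cohort,
56 distal-only exons (58.9%), most of them bound in both flanking
introns.

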