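# ctc-concord

Concordance analysis between circulating tumor cells (CTCs) and bulk tumor
tissue at the mutation and copy-number level.

## What this is for

Single CTCs and small CTC pools isolated from a blood draw can be sequenced
after whole-genome amplification (WGA) and compared with a synchronous bulk
tumor biopsy. Whether that comparison is informative hinges on questions
this package quantifies:

* What fraction of the bulk tumor's somatic SNVs is recovered in CTC
  samples, and how does recovery grow with the number of CTC samples
  analyzed? Recovery curves report median/min/max over sample subsets, for
  all bulk mutations and for those with adequate CTC coverage (≥20×), with
  low-coverage accounting (fraction of sites under 5 reads) and a Wilcoxon
  comparison of bulk VAFs between recovered and missed mutations.
* Are the hundreds of CTC-private mutations artifacts of WGA? Each CTC and
  WBC-control sample gets a 96-class trinucleotide-context spectrum;
  samples are clustered with complete linkage on the distance
  `1 − cor(log(0.01 + f))` over context frequencies `f`. Patient-specific
  clustering argues the private load carries real, patient-specific
  mutational processes.
* Do copy-number profiles agree? Reads in 10 kb windows are normalized to a
  matched control, segmented by circular binary segmentation (permutation
  test, α = 0.01), purity/ploidy-corrected for the impure bulk via a grid
  search over the mixture model
  `R = (ρq + 2(1−ρ)) / (ρτ + 2(1−ρ))`,
  rescaled to ploidy 2, categorized (amp > 4, gain > 2.5, del < 1.5, deep
  del < 0.8), and compared by Spearman correlation of per-window copy
  number.
* A driver-centric "oncoplot" table shows, per sample, the evidence status
  of recurrent catalogued mutations (called / recovered with ≥1 alternate
  read / absent / no coverage) and the copy-number category at driver genes.

Somatic calls are filtered first: a blacklist k-mer context filter
(`TTAACTGACAGC` within ±12 bp, either strand), removal of substitutions
called in more than one patient, and a 20% VAF floor with rescue for
mutations present in the matched bulk.

Because the real patient data such analyses run on is controlled-access,
the package ships a first-class synthetic data generator
(`ctc_concord.simulate`) that emulates the statistical structure of the
problem — clonal tumors with CN segments, impure bulk (purity 0.2–0.35),
WGA allele dropout (0.3) and locus dropout (0.4), Poisson artifact loads
(≈800 per CTC, ≈60 per WBC pool) with patient-specific context spectra —
with full ground truth, so every statistic in the pipeline is validated
against planted parameters. See `docs/methods.md` for the models, defaults
and limitations.

## Worked example

Generate the default three-patient bundle (a concordant triple-negative-like
patient, a concordant HER2-like patient with a uniform ERBB2 amplification,
and a discordant ER-like patient with a CTC-only clone) and run the full
analysis:

```bash
ctc-concord simulate --seed 1 --outdir demo/data
ctc-concord report --dataset demo/data --seed 1 --outdir demo/out
```

`report` prints a per-patient summary; with seed 1 the P3 (ER-like) block
reads:

```json
"P3": {
  "n_bulk_mutations": 193,
  "category_counts": {
    "bulk_only": 93, "ctc_bulk": 100, "ctc_shared": 16,
    "ctc_private": 2201, "excluded": 49
  },
  "low_coverage_fraction": 0.48,
  "union_recovery_all": 0.518,
  "n_cnas_bulk": 7,
  "purity_estimate": 0.37
}
```

Reading this: of 193 bulk mutations, only 51.8% are ever seen in a CTC
sample (the discordant patient; the two concordant patients recover ≈100%),
48% of (bulk mutation, CTC sample) pairs have fewer than 5 reads, and each
CTC sample carries a private mutation load two orders of magnitude above
its bulk overlap. `demo/out/` contains the full reports:
`categories.tsv`, `recovery_curve.tsv`, `vaf_comparison.tsv`,
`vaf_correlation.tsv`, `spectra.tsv`, `distance_matrix.tsv`,
`dendrogram.nwk`, `clusters.tsv`, `segments.tsv`, `cn_windows.tsv`,
`concordance_matrix.tsv`, `cna_dendrogram.nwk`, and one
`oncoplot_<patient>.tsv` per patient — the P3 oncoplot shows the ESR1
driver called in exactly one CTC and absent from the bulk, with the
matching ERBB2 amplification confined to the same CTC.

Real data enters through the same on-disk layout the simulator writes: a
sample sheet (TSV), per-sample site tables (VCF 4.2 with AD/DP, or a TSV
dialect that also carries read support at uncalled sites), per-sample
window counts (BED-like TSV), a reference FASTA, a gene-interval BED and a
catalogue-count TSV.

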