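# Methods

This note documents the models and procedures implemented in `ctc-concord`,
the choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Problem setting

Circulating tumor cells (CTCs) isolated from blood are sequenced singly or
in small pools after whole-genome amplification (WGA), and compared with a
matched bulk tumor biopsy. Three control samples anchor the comparison: the
patient's germline blood (constitutional variants), and a pool of white
blood cells (WBCs) pushed through the same isolation + WGA workflow as the
CTCs, which serves as an amplification-artifact control. The pipeline
quantifies (i) how many of the bulk tumor's somatic SNVs are recovered in
CTC samples and how that grows with the number of CTC samples, (ii) whether
variant allele frequencies (VAFs) agree between bulk and CTCs, (iii) whether
the large load of CTC-private mutations carries patient-specific mutational
context structure (i.e. is not purely artifactual), and (iv) whether
copy-number aberration (CNA) profiles agree between CTCs and bulk.

## Mutation filtering and taxonomy

Calls (not reads) are the pipeline's entry point. Three filters apply:

1. **Blacklist k-mer.** A call is removed iff the motif `TTAACTGACAGC` or
   its reverse complement occurs in the reference window ±12 bp around the
   site. The match is against the flanking *reference* sequence (read-level
   context is not available to a call-level pipeline); removed calls are
   reported so the decision can be audited.
2. **Cross-patient recurrence.** A substitution called in more than one
   patient is removed everywhere; recurrence across unrelated genomes marks
   a systematic artifact. Only called occurrences establish presence.
   Recurrence can be evaluated against a fixed (e.g. unfiltered) callset,
   in which case the three filters are independent predicates and commute;
   the pipeline applies them in the order k-mer → cross-patient → VAF.
3. **VAF floor.** Called variants with VAF < 0.20 are removed unless the
   same substitution is called in the patient's bulk sample ("present in
   the bulk" means *called* in bulk — stricter and reproducible). A VAF of
   exactly 0.20 is kept. Uncalled read-support rows pass through: they
   carry coverage evidence, not assertions.

After filtering, per patient: *bulk mutations* are called in the bulk and
absent from both germline and WBC pool; *CTC mutations* are called in ≥1
CTC sample and absent from the WBC pool. CTC mutations split into
`ctc_bulk` (also a bulk mutation), `ctc_shared` (≥2 CTC samples, not a bulk
mutation) and `ctc_private` (exactly one CTC sample); bulk mutations never
seen in a CTC are `bulk_only`; everything else (WBC- or germline-tainted)
is `excluded`. "Not a bulk mutation" is evaluated against the *defined*
bulk set, so the three CTC categories exactly tile the CTC mutation set —
an invariant asserted on every run.

**Read-level rescue.** For display (the driver oncoplot), each
(mutation, sample) cell carries an evidence status: `called` (caller flag),
`supported` (≥1 alternate read without a call; i.e. recoverable by manual
review), `covered_ref` (reads but no alternate), `no_coverage`.

## Recovery and VAF statistics

For each subset size k of a patient's n CTC samples, the recovered fraction
of bulk mutations (union over the subset) is summarized by median/min/max —
exhaustively over all C(n, k) subsets when C(n, k) ≤ 10⁴, otherwise over
10⁴ seeded *distinct* uniformly drawn subsets. Exhaustive medians are
non-decreasing in k (unions are monotone); this is asserted. Curves are
computed for all bulk mutations and for the nonsynonymous/nonsense subset
(an input annotation; no codon arithmetic is done), each against all bulk
mutations and against "selected" ones (≥20× coverage in ≥1 CTC sample).

Low-coverage accounting reports the fraction of (bulk mutation, CTC sample)
pairs with depth < 5; the pair-wise definition is the headline and
per-sample fractions are also emitted, since a per-patient single number is
ambiguous between the two.

Bulk VAFs of recovered vs missed selected mutations are compared with a
two-sided Wilcoxon rank-sum test — exact enumeration when both groups have
≤25 observations and no ties, otherwise the normal approximation with tie
and continuity correction. VAF agreement uses Spearman correlation
(average ranks, t-approximation p-values), per CTC sample and pooled over
(mutation, sample) pairs. No multiple-testing correction is applied.

## Trinucleotide spectra and clustering

Substitutions are tabulated into the standard 96 classes (six
pyrimidine-strand substitution types × 5′ × 3′ flanking bases, purine
references reverse-complemented). Samples are compared with

    d(a, b) = 1 − cor( log(0.01 + f_a), log(0.01 + f_b) )

over the 96 context *frequencies* f (pseudocount on frequencies, matching
the formula; the log base cancels in the correlation), and clustered by
complete linkage. Spectra are built from each CTC/WBC sample's filtered
calls minus germline-called keys (configurable to private-only). Samples
are sorted by identifier before agglomeration so equal-distance merges are
deterministic and the output is input-order invariant. De novo signature
extraction (NMF and COSMIC refitting) is out of scope.

## Copy number

Reads are counted in fixed 10 kb windows and normalized to a matched
control — the WBC pool for CTC samples, germline blood for the bulk — as
library-size-scaled count ratios: `R_i = (s_i/Σs) / (c_i/Σc)`; windows with
control count < 10 are masked. No recentring is applied at this stage:
under a flat diploid control the scaled ratio of a bulk segment with tumor
copy number q, purity ρ and tumor ploidy τ is exactly
`R = (ρq + 2(1−ρ)) / (ρτ + 2(1−ρ))`, which is the relation the purity
corrector inverts.

**Segmentation** is circular binary segmentation: per chromosome, the
two-sample pooled-variance t statistic of every arc vs its complement is
maximized (arc length ≥ 2 windows); the best split is accepted when its
permutation p-value, `(1 + #{perm ≥ obs}) / (1 + 1000)`, is below α = 0.01,
and recursion continues on the pieces. Permutations are drawn in growing
blocks with early stopping that can only *fail to reject* (stop once enough
exceedances guarantee p ≥ α), so calibration is preserved. A perfect
separation (zero within-group variance with a mean difference) is treated
as an infinite statistic. After recursion, adjacent segments whose
two-sample t falls below 5 are re-merged, weakest first. This pruning step
exists because a maximizing arc test at α = 0.01 scatters false interior
splits over long null stretches (each costing two spurious boundaries);
permutation false rejections sit just above the acceptance threshold
(|t| ≈ 4–5) while genuine copy-number boundaries in window-count data sit
far higher, so a t = 5 undo threshold removes them at negligible cost to
real events. Cost is O(n² · nperm) per accepted split, so very long
chromosomes are expensive; the synthetic genome uses ≤ 500 windows per
chromosome.

**Purity/ploidy correction** (bulk only; CTC samples are treated as pure
because the isolation workflow selects tumor cells) is a grid search over
ρ ∈ [0.05, 1] (step 0.01) and τ ∈ [1.2, 5] (step 0.05). Each segment's
implied `q = (R·(ρτ + 2(1−ρ)) − 2(1−ρ)) / ρ` is snapped to the nearest
integer in [0, 8] and scored by the squared residual between the observed
R and the ratio that integer implies — in *observation space*, because
q-space least squares amplifies segment-mean noise by 1/ρ and is biased
toward ρ = 1 at realistic purities, while a naive ratio-space score rewards
the arbitrarily fine comb of low ρ. Three guards make the objective
well-behaved:

* per-segment residuals are capped at (4σ_s)², σ_s being the segment
  mean's standard error from within-segment window scatter, so genuinely
  non-integer segments (subclonal events) cost the same under every
  candidate instead of dragging the fit toward dense combs;
* the expected noise floor min(σ_s², spacing²/12) is subtracted per
  segment, so neither dense nor wide combs are rewarded for absorbing
  noise;
* a karyotype-style prior (3×10⁻⁴ per unit of |q − 2|, window-weighted)
  penalizes solutions that explain ordinary segments as homozygous
  deletions or high amplifications.

A mild parsimony penalty 5×10⁻⁴·(τ − 2)² breaks the integer-shift
degeneracy of the comb (shifting every q by the same integer with matched
ρ, τ fits identically; depth data alone cannot resolve it, so genuinely
polyploid genomes are reported at their most parsimonious near-diploid
equivalent — a limitation shared by all depth-only correctors). A flat
profile, where every segment rounds to the same integer, is unidentifiable
and flagged degenerate; if no grid point beats the objective threshold the
profile is left uncorrected (ρ = 1).

Copy numbers are then rescaled to a window-weighted mean of 2
(`CN′ = 2q/τ̂` for corrected bulk; `CN′ = 2R/mean(R)` for pure samples) and
categorized with strict inequalities: amp > 4, gain > 2.5, deep deletion
< 0.8, deletion < 1.5, else neutral; boundary values fall to the less
extreme category. The "number of CNAs" is the count of non-neutral
segments (one reasonable reading of an underdefined quantity; labeled as
such in reports). Pairwise sample concordance is the Spearman correlation
of per-window segment-mean CN over windows unmasked in both samples
(window-level, not per-segment), followed by complete-linkage clustering on
1 − ρ.

## Driver oncoplot

Genes are displayed when they carry ≥2 mutation events (sample occurrences,
not distinct variants) whose catalogue occurrence count is ≥20, plus an
always-show list (ESR1 by default) and the configured driver-CNA genes.
Individual variants require a catalogue count ≥20, relaxed to ≥5 for TP53.
The catalogue is a static TSV (gene, protein change, count); no live
database access. CNA cells take the category of the longest-overlap segment
at the gene interval.

## Synthetic data generator

The generator is first-class, tested code; its defaults define the study
conditions the pipeline is validated under.

* **Genome**: 10 chromosomes × 1 Mb of uniform random sequence (≈1000
  windows at 10 kb), with the blacklist k-mer planted at 150 known sites.
  Small enough that a full multi-patient run takes seconds.
* **Clones**: an explicit clone tree per patient; each clone has a bulk
  cancer-cell fraction (child ≤ parent, truncal = 1), a CTC sampling
  weight that may diverge from the bulk fractions, private mutations, CN
  events, and optional named driver mutations. Bulk window counts follow
  the purity mixture ρ·q̄ + 2(1−ρ); bulk VAF of a clonal mutation is
  ρ·CCF / (ρ·q̄ + 2(1−ρ)) (so a truncal het in a CN-2 region has VAF ρ/2).
* **WGA noise**: per-site locus dropout (default 0.4), per-allele dropout
  (ADO, default 0.3) applied to template copies, negative-binomial depth
  (CTC mean 60, shape 2), and Poisson artifact loads (mean 800 per CTC
  sample, 60 per WBC pool) with trinucleotide contexts drawn from a
  patient-specific spectrum (disjoint supports across patients by default)
  and allele fractions uniform on [0.3, 0.9]; 5% of artifacts are planted
  inside blacklist k-mer occurrences. ADO is independent across sites,
  samples and cells — a deliberate simplification of the spatially
  correlated amplification bias of real WGA. Its main visible consequence
  is that recovery *unions* over many CTC samples approach 1 faster than
  in real data, where missingness is correlated across samples; per-sample
  detection rates and category loads are unaffected.
* **Window counts**: negative binomial around the CN expectation, 2000
  reads per window, shape 150 for unamplified samples and 30 for WGA
  samples. WGA material is noisier per window, but the dominant noise term
  in *bulk* copy number is the 1/ρ amplification of the purity correction,
  which is why corrected low-purity bulk profiles come out noisier than
  CTC profiles at equal depth.
* **Emulated caller**: a site is called when depth ≥ 8, alternate reads
  ≥ 3 and VAF ≥ 0.05. Germline blood is deep and clean; nothing somatic is
  called there.
* **Default bundle**: three patients mirroring the structure such studies
  report — one concordant triple-negative-like (truncal TP53 + MYC
  amplification, one subclone), one concordant HER2-like (ERBB2
  amplification in every sample, 10-cell pools), one discordant ER-like
  (bulk-dominant lineage with TP53 and a PTEN loss the CTCs lack; a CTC
  lineage with barely-in-bulk shared mutations; and a CTC-only clone
  carrying ESR1 Y537N plus an ERBB2 amplification absent from the bulk).
  Bulk purity is drawn uniformly in [0.2, 0.35]. Driver loci in carrier
  CTC samples are conditioned on successful amplification (depth floored
  at the caller minimum): the bundle emulates a study whose observed
  samples did show their drivers, rather than re-rolling the WGA lottery
  at the few sites that define each scenario's qualitative structure.
  Mutation loads (120 truncal, ~60 per subclone) are scaled so the
  per-sample category loads sit in the reported real-data regime
  (bulk-overlap tens, private hundreds).

What passing tests on this generator do **not** show about real data:
correlated dropout across samples (union recovery is optimistic),
GC/mappability structure in window counts (no wave artifacts), read-level
errors and mapping ambiguity, and exome capture non-uniformity. The
generator's purpose is to give every statistic a ground truth, not to be a
sequencing simulator.

## Numerical and procedural choices

* All intervals are 0-based half-open; point mutations are 1-based (VCF);
  a single utility converts between them.
* Every randomized operation takes an explicit seed; a run log records the
  seed, a configuration hash and per-stage record counts. Simulation output
  is byte-identical under a fixed seed.
* Subset sampling for recovery curves draws *distinct* subsets, so
  Monte-Carlo mode converges to the exhaustive answer as the budget
  approaches C(n, k).
* Complete-linkage ties are broken by lexicographic sample id (inputs are
  sorted before clustering).
* Degenerate inputs: zero-depth sites have undefined (missing) VAF; empty
  spectra have undefined distances and are excluded from clustering with a
  named error; stretches too short to split are single segments; a profile
  with <3 segments skips purity correction.

## Known limitations

* The purity corrector uses depth ratios only (no SNV multiplicities, no
  karyotype priors beyond the |q−2| term); whole-genome doubling cannot be
  distinguished from its near-diploid equivalent.
* The segmentation undo step (t < 5) can merge genuinely weak events —
  e.g. strongly subclonal CN changes diluted below ~5 standard errors in a
  low-purity bulk.
* The Wilcoxon exact path requires tie-free data; with ties the corrected
  normal approximation is used regardless of sample size.
* Recovery unions over many CTC samples are optimistic relative to real
  WGA data (independence of dropout across samples; see above).
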