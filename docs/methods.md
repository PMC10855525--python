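# Methods

This note documents the statistical model behind `tearvar`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate about real tear-proteomics data.

## Study design assumed throughout

A repeated-sampling design: `n_persons` donors (default 3), both eyes
(OD/OS), `n_days` consecutive days (default 5) — 30 biological samples — with
tear volume (µL) and total protein concentration (TPC, µg/µL) recorded per
sample, and a constant protein amount digested per sample for label-free
DIA-style quantification. Technical variance is estimated from replicate
digests of one sample.

## The synthetic-data generator

### Intensity model

Log-intensity of protein *i* in sample *s*:

```
ln I_is = ln b_i + u_{p(s),i} + λ_i f_{c(i),s} + ε_is  (+ outlier terms)
```

* **Base abundance** `b_i`: two geometric segments. The top 30 proteins span
  ~2 decades (the spread observed among dominant tear proteins such as LTF,
  LCN1, LYZ); the tail runs down to `abundance_decades` (default 5) below
  the top, and its upper level is solved numerically so the top-30 share of
  summed intensity equals `top30_target_share` (default 0.97).
* **Person effects** `u` ~ N(0, 0.3²) per (person, protein), plus
  `n_differential` designated proteins (default 15) shifted by
  `differential_log2fc` (default 2, i.e. 4×) in one person each; these are
  recorded in the ground-truth block.
* **Cluster factors**: each protein belongs to one of 4 clusters
  (Ig/defense, cornification, serum-derived, major tear proteins; curated
  gene symbols — IGHA1, KRT1, ALB, LTF, ... — are given to the most abundant
  members so gene-prefix logic downstream is exercised). Day-to-day factors
  `f` (sd 0.7) are drawn per (cluster, sample) and **orthogonalized across
  samples**: cluster programs are modelled as independent, and at n = 30 raw
  draws would show chance correlations of ±0.2–0.4 that blur the injected
  cluster identity. A small personal program component (sd 0.2) is added on
  top. Loadings λ ~ U(0.8, 0.95); the twelve most abundant proteins are
  damped (×0.6) — the dominant secreted proteins are homeostatically
  regulated and, under closure, an undamped swing of the mass-dominant
  cluster would erase its own correlation signature and cross-couple every
  minor cluster (see "Closure algebra" below).
* **Noise** ε: multiplicative lognormal, `sample_noise_cv` = 0.25; CV maps
  to log-sd via `σ = sqrt(ln(1+cv²))` everywhere.
* **Closure**: every column is rescaled to the same summed intensity —
  a constant protein amount is digested regardless of tear volume — which
  induces the negative correlations among dominant proteins that the
  correlation module must expose.
* **Outliers (reflex-like samples)**: with probability 0.2 (or exactly
  `n_outliers_per_person` when truth-recovery experiments need a fixed
  count), a sample's cornification-cluster intensities are multiplied by 10,
  its volume by 2.5, and all its proteins receive extra lognormal noise
  (cv 0.7). Reflex tears are compositionally distinct fluid: the extra
  compositional perturbation is what makes outliers break Ig-profile
  clustering and lower their intrapersonal sample correlation, as observed
  in real studies; cornification scaling alone would only shift one cluster.
* **Missingness**: logistic detection on log10 intensity (midpoint 4.5,
  slope 3), tuned so the detection-frequency structure matches a real tear
  study of this size: ~170–180 of 320 proteins present in ≥90% of samples,
  ~270 in at least three samples of every person.
* **Metadata**: volume (cv 0.71) and TPC (cv 0.35) are lognormal with a weak
  Gaussian-copula correlation (0.2) — strong enough to be plausible, weak
  enough to stay non-significant at n = 30.
* **Peptides**: each protein's intensity is split over `peptides_per_protein`
  rows by Dirichlet weights; semitryptic rows carry a per-person intensity
  fraction (defaults evenly spaced 0.07–0.13, i.e. ~90% of intensity
  tryptic with a real interpersonal difference); a subset of tryptic rows is
  flagged modified; peptide-level lognormal noise (cv 0.12) is added, and
  sequences/flanking residues are generated consistently with the assigned
  cleavage class.

Identical `(seed, config)` give bit-identical output; technical replicates
derive their stream from the dataset seed and the sample id.

### Closure algebra and why the defaults look the way they do

With a mass share `w_c` and loading λ, a swing `f` of cluster *c* multiplies
every other protein by roughly `exp(−w_c λ f)` after closure. Three published
observations must coexist: (1) strong within-cluster correlation (r 0.5–0.9),
(2) a leave-one-out CV curve whose knee cleanly separates ~3 reflex outliers
per person, and (3) high intrapersonal CV (median ≈ 40–60%, almost nothing
below 20%). A single global noise scale cannot deliver all three: strong
factor swings on the mass-dominant cluster create per-sample compositional
displacements as large as a reflex outlier's. The resolution implemented
here mirrors the biology — the dominant proteins are the *low-variance* ones
(damped loadings), most of the mass swing is removed, minor clusters carry
the correlation signal, and the reflex perturbation (closure displacement +
extra compositional noise) dominates the within-person L1OCV landscape once
cluster normalization has removed the shared factor swings. These parameters
were fixed from this analysis and the detection-frequency calibration before
the acceptance checks were written, and not revisited.

## Analysis choices

* **CV** on linear intensities, sample sd (n−1); group entries with fewer
  than 3 observed values are missing; per-protein summary across a scheme's
  groups is the median. Interpersonal CV is estimated only from
  person-balanced randomized groups of equal size (3 groups of 10 in the
  default design), never from person-vs-person pooling, so it is comparable
  with the intrapersonal estimate at the same n.
* **Technical CV** applies a median-unbiasedness correction
  `cv / sqrt(median(χ²_{n−1})/(n−1))` per protein: with triplicates the raw
  sd underestimates the generating noise by ~17% at the median, so the
  uncorrected summary would systematically misreport the digestion
  protocol's reproducibility. `bias_correction=False` restores the naive
  estimator.
* **L1OCV** is one-shot (each sample scored against its full group), per
  person, requiring groups of ≥4. The knee of the ascending relative-L1OCV
  curve is located by a two-segment linear fit (L-method): the split index
  minimizing the summed SSE of the two fits is the outlier count. A
  max-distance-to-chord rule was evaluated first and systematically
  overcounts by one when the plateau drifts upward (the rank-n point at
  relative 1.0 tilts the chord). Guards: a flat or straight curve (<50% SSE
  reduction over a single line) has no knee; the knee may not flag a
  majority of the group; ties go to the smaller count. The
  `relative_limit` alternative flags samples strictly below the limit
  (default 0.90), keeping boundary samples. An all-identical group is
  degenerate: nothing is flagged, with a warning.
* **Normalization**: scaling statistics ignore missing values and never
  impute. The cluster method derives its partition from total-sum-prescaled
  log2 correlations (average linkage, distance 1−r, cut to exactly k).
  Benchmark metrics: pooled within-person CV (linear), pooled within-person
  MAD of log2 intensities, mean within-person sample correlation (log2);
  methods are ranked by pooled CV. Total-sum scaling targets the grand-mean
  column sum, so rescaling one input column changes the output only by one
  global factor — invisible to every downstream statistic.
* **Correlation**: pairwise-complete Pearson on log2 intensities (log2
  stabilizes the 5-decade range), p from the t-transform of r, pairs with
  fewer than 6 shared observations missing; BH q-values attached for export
  but the key-protein report uses plain p < 0.05 with signs retained,
  because under closure the negative correlations of dominant proteins are
  informative. Missing correlations are imputed as r = 0 for clustering
  only, with the count reported.
* **Differential analysis**: Student-form pooled-variance statistic with
  SAM fudge factor s0 = 0.1 on log2 intensities; proteins require ≥70%
  presence per group; balanced label permutations (n = 250 by default,
  exhaustive enumeration when fewer than 25 distinct relabellings exist);
  the FDR threshold is the loosest |d| cutoff with estimated FDR ≤ target.
  Comparisons are computed in a canonical person order and mirrored, so
  swapping the two persons exactly negates the fold changes and preserves
  significance. Paired eye-level tests use day-matched log2 differences and
  exhaustive sign-flip permutations (2⁵ for the default design); their
  p-values are the two-sided sign-flip probabilities.
* **Peptidoforms**: a peptide is fully tryptic iff its N side is a genuine
  K/R cleavage (cleavage before proline disallowed) or the protein
  N-terminus AND its C-terminal residue is K/R or the protein C-terminus;
  internal missed cleavages are irrelevant. Relative variance divides each
  peptide's intrapersonal CV by the median CV of its protein's peptides
  (median RV = 1 per protein by construction); proteins with one quantified
  peptide are excluded and counted. Class distributions are compared by
  two-sided Mann–Whitney tests.
* **Ig profiling**: IGH*/IGK*/IGL* symbols parse to isotype (A/G/M/D/E from
  the fourth letter; `IGHD` is the delta constant gene, `IGHD#-#` a D
  segment), chain, region (V/D/J segment ⇒ variable) and light type.
  JCHAIN and PIGR are accepted as Ig-associated with a distinct flag but
  excluded from the total-Ig denominator — they are transport/joining
  proteins, not Ig chains. Sample clustering uses row-standardized log2
  relative intensities (the static abundance ladder is common to all samples
  and would otherwise mask the personal signature), correlation distance,
  average linkage, cut to one cluster per person. Top-5 stability is the
  overlap of each sample's top-5 Ig set with the modal set from mean
  relative intensities; ties break by gene name for determinism.
* **Pipeline**: stages run in a fixed order (normalize before outlier
  selection, so the L1OCV operates on cluster-normalized intensities — the
  best-performing normalization); all randomized procedures draw per-stage
  streams from one root seed; the manifest records seeds, parameters, row
  counts and MD5 checksums, and reruns are byte-identical.

## Problem sizes used in the shipped checks

The acceptance checks simulate at the default design (320 proteins × 30
samples): 500 replicate studies for outlier truth recovery, 100 for the
permutation-FDR null, 7 for cluster recovery, 200 repetitions of the
triplicate-digest benchmark (300 proteins), chosen to keep the full test run
in the low minutes while leaving Monte-Carlo error well inside the asserted
margins.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* of a repeated-sampling
tear study: abundance concentration, compositional closure, correlated
protein families, reflex-like outliers, intensity-dependent dropout, and
peptide-class structure. It does not simulate chromatography, spectra,
search-engine identification errors, shared peptides between protein groups,
glycan heterogeneity, or eye-level systematic effects (the generator's two
eyes differ only through sampling noise, which is also why the paired eye
tests are expected null). Passing the truth-recovery checks therefore shows
the estimators are correct and well calibrated under the assumed model — it
does not by itself validate the model against any particular instrument or
cohort.

## Known limitations

* The L1OCV knee is a heuristic; on groups where natural day-to-day
  variation approaches the outlier effect it can flag one sample too many
  (specificity ≈ 0.93 rather than 1 in the shipped benchmark).
* Cluster normalization assumes cluster-coherent distortions; proteins with
  atypical loadings inside a cluster are only partially corrected.
* The permutation FDR is conservative at very small group sizes, where the
  discrete null has limited resolution.
* Peptides are generated with unique parent proteins; multi-mapped peptides
  (dropped from relative-variance analysis in real data) are not simulated.
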