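# Methods

`omicsbridge` implements an integrated differential-expression analysis for a
two-condition (wild type vs mutant), two-biological-replicate design measured
on two platforms: 4-plex iTRAQ LC-MS/MS for proteins (reporter channels
116/117 = wild type, 119/121 = mutant) and digital gene expression (DGE) tag
sequencing for transcripts (libraries W1R/W2R and M1R/M2R).  Because such
studies rarely release raw data, the package ships a synthetic-data generator
with known ground truth; every analysis stage is validated against that truth
or against independent closed forms and counting oracles.

## Proteome quantification

Peptide records carry an identification score and four reporter intensities.
The chain is:

1. **Filter** — keep unique peptides with score ≥ `min_score` (default 20,
   boundary inclusive).
2. **Roll-up** — per protein, channel intensities are summed over peptides
   (robust to single low-intensity peptides; a median-of-peptide-ratios
   variant was considered and rejected because it discards intensity
   information, though the sum is the only roll-up exposed).  Proteins with a
   zero channel sum are flagged unquantifiable, never silently dropped.
3. **Ratios** — mutant/wild-type ratios are formed per replicate pairing,
   119/116 and 121/117, plus the within-condition pairings 117/116 and
   121/119 used only for the replicate null.
4. **Median-ratio normalization** — each ratio column is divided by its
   median, defined as the lower-middle order statistic so the
   post-normalization median is an observed value equal to exactly 1 and the
   operation is exactly idempotent.
5. **Peptide-ratio test** — per protein, the mean of the two pairings'
   peptide-level log2 ratios is tested against the global median protein
   log2 ratio with a two-sided one-sample t-test (the median centering is
   the peptide-level counterpart of step 4; without it, multiplicative
   channel biases would shift every null test).  Zero-variance peptide sets
   get p = 1 when they sit exactly at the center and p = 0 otherwise (the
   limit of the t statistic); both cases are flagged
   `degenerate_zero_variance`.  Proteins with fewer than two usable peptides
   get p = NaN and are never quantified.

### Empirical fold-change threshold

The cutoff for calling a differentially expressed protein (DEP) is derived
from biological variation rather than assumed: for each within-condition
pairing, the symmetric fold change `max(r, 1/r)` of the normalized replicate
ratio is tabulated over proteins, and the empirical quantile (smallest
observed value whose cumulative fraction reaches the level; default level
0.95, with 0.90/0.95/0.99 always reported) becomes the candidate threshold.
The chosen threshold is the maximum across the two pairings — conservative —
floored at a configurable minimum (default 1.0) with optional round-up.
Under a Gaussian noise model with per-channel log2 sd σ the 95% threshold has
the closed form `2**(1.96·σ·√2)`; the acceptance suite verifies the
implementation against it at σ = 0.25 (≈ 1.62).

A protein is a DEP when **both** replicate ratios are ≥ threshold (up) or
≤ 1/threshold (down, the reciprocal bound), its p-value is < `alpha`
(default 0.05), and it has ≥ `min_unique_peptides` (default 2).  On all-null
data with the auto-derived 95% threshold this controls the false-call
fraction well below the nominal 5% budget (the ratio conjunction and the
p-value filter are both active), which the acceptance suite checks with a
binomial 99% bound.

## Transcriptome quantification

Tag counts are normalized to TPM, `count / mapped_to_gene_total × 1e6`.  The
denominator is the library's mapped-to-gene total, not all clean tags: TPM is
meant to be a proportion of the quantifiable signal, and with the all-clean
denominator the per-library sums would not be comparable.  (The alternative
is available by passing explicit denominators.)  Mapping bookkeeping
(raw/clean/to-gene/to-genome/unknown) is validated to sum exactly and
reported as percentages.  Sequencing saturation is assessed by nested
subsampling without replacement (multivariate hypergeometric increments), so
the detected-gene curve is nondecreasing by construction.

### Nonparametric differential expression

For each gene the signal is the pair (M, D): M the log2 ratio of condition
mean TPMs and D the absolute difference of the raw condition means.  A
pseudocount (default 0.5) is added **inside the log only** — it prevents
log-of-zero while leaving D on the raw TPM scale.  The noise model is
empirical: for every gene and each within-condition replicate pair the same
statistics (|M₀|, D₀) are computed and pooled (2 points per gene).  The
probability of differential expression is the fraction of noise points with
|M₀| < |M| **and** D₀ < D, with strict inequalities so ties count against
significance.  This is plain exhaustive counting — deliberately, so the
implementation can be (and is) checked bit-for-bit against an O(genes ×
noise) oracle; no kernel smoothing is applied.  A gene is called when its
probability reaches `q_min` (default 0.8) and |M| reaches `m_min` (default
1, i.e. 2-fold).

## Integration

Proteins map to transcripts through a canonical locus id obtained by
stripping a trailing `.<integer>` isoform suffix (idempotent).  Protein
ratios are aggregated across the two replicate pairings by geometric mean
(mean of log2 ratios); mRNA ratios are M.  The correlation ladder reports
Pearson r (Spearman via configuration; Pearson is the default reading of an
unqualified "correlation coefficient") at four nested levels — DEP ∩ DEG,
DEP vs cognate mRNA under the relaxed filter (|M| ≥ 1, no probability
bound), DEP vs all expressed mRNA, all vs all — plus the direction-restricted
up–up and down–down subsets.  "All expressed" means quantifiable with finite
log ratios; excluded entries are counted in the report, and r is withheld
below three pairs.  GO category tallies count a gene into every category it
is annotated with, with percentages relative to the annotated ids per
ontology and unannotated ids reported separately.

## qPCR validation

Relative quantification uses the Livak 2^−ΔΔCT form with amplification
efficiency fixed at 2: ΔCT(group) = mean target Ct − mean reference Ct over
the group's wells (biological and technical replicates collapsed by mean),
ΔΔCT = ΔCT(MT) − ΔCT(WT), rq = 2^−ΔΔCT.  An efficiency-corrected variant was
deliberately left out: the assay model in the generator has no efficiency
parameter to estimate.  Concordance with the sequencing result is direction
agreement only — sign(log2 rq) = sign(M), zero against nonzero discordant —
because magnitude agreement across a compositional assay and a
reference-normalized assay is not expected even in principle (see
limitations).

## Synthetic-data generator

Every locus receives a baseline log2 abundance pair (mRNA mean 5, protein
mean 10, sd 2 — lognormal baselines matching heavy-tailed omics intensity
distributions) drawn from a bivariate normal with correlation ρ, and a
biological condition-effect pair (sd `sigma_bio`, default 0.5 log2 units)
with the same correlation; ρ (default 0.35) is thus the generative
mRNA-protein coupling at both the abundance and the response level.  A
fraction `frac_de` (default 0.05) of loci additionally carry a large effect:
magnitude uniform on `effect_range` (default 1–3 log2 units), signs split
evenly, protein effect = mRNA effect + N(0, 0.25) jitter so cognate effects
correlate without being identical.

Measurement layers: per protein, 1 + Poisson(`peptides_mean` − 1) unique
peptides (floored at one; shared peptides out of scope), each with a shared
lognormal ionization offset (log2 sd 1), a gamma-distributed identification
score (mean 48, a tail below 20 so the filter bites), per-channel lognormal
reporter noise (log2 sd 0.25) and four multiplicative channel biases.  Tag
counts are negative binomial (dispersion 0.02; Poisson at dispersion 0)
around means scaled so each library's mapped-to-gene total matches its
clean-tag total times the mapped fraction (defaults: clean totals ≈ 3.3M,
73% to genes, 14% to genome, 96% clean/raw — the scale of a typical DGE
experiment).  `exact_counts` mode emits the expected values themselves
(real-valued), giving the fully deterministic noise-free limit.  qPCR wells
encode ΔΔCT = −(realized mRNA effect) plus N(0, 0.25) cycles of noise, with
a condition-invariant `actin` reference; the realized (not just the DE)
effect is used because qPCR assays the same RNA the DGE libraries sample.
The GO map generator is a labelled synthetic stand-in for an external
annotation table.

Randomness: each generator stage draws from its own child stream seeded as
(seed, stage index) in a fixed documented order, so identical configurations
produce byte-identical tables and any stage can be regenerated alone.

### What the generator does not emulate

No spectra, chromatograms or read sequences; no missing reporter channels,
shared peptides or isoform families (every locus has exactly one protein
isoform); no GC/length biases, batch effects or library-preparation
artifacts; mapping categories are bookkeeping only.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every artifact of real data.

## Validation conditions and problem sizes

The acceptance suite runs at sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: 100,000 replicate pairs for the threshold
closed form; 5,000 null proteins for specificity; 3,000 loci × 20 seeds for
coupling recovery; 1,200 loci for the noise-free limit; 50 random instances
(≤ 200 genes) for oracle equivalence.  The coupling-recovery condition uses
`frac_de = 0` (large DE effects would add a second, stronger source of
mRNA-protein correlation and the recovered r would exceed ρ) and small
technical noise (`sigma_reporter = 0.05`, `nb_dispersion = 0.001`): by the
standard attenuation formula r ≈ ρ / √((1 + v_p/σ²_bio)(1 + v_m/σ²_bio)),
measurement variance must be ≪ σ²_bio for the sample correlation to estimate
ρ rather than a diluted version of it.

## Numerical choices and degenerate inputs

* Median = lower-middle order statistic (even n), so normalization maps an
  observed ratio to exactly 1.
* Empirical quantile = left-continuous inverse CDF (smallest value whose
  cumulative fraction ≥ q).
* Strict inequalities in the (M, D) probability; ties are insignificant.
* Correlations are undefined (NaN, with the pair count still reported) for
  fewer than 3 points or constant vectors; fold changes reject nonpositive
  inputs; TPM rejects zero denominators; mapping summaries reject
  inconsistent totals naming the library.
* All tables are TSV with header, validated against named schemas (column
  presence, kinds, duplicate keys) with line-numbered type errors.

## Known limitations

* **TPM is compositional.**  When differential loci shift a library's total
  signal, every gene's M is offset by log2 of the total-weight ratio; the
  absolute effect of a gene is identifiable only up to this composition
  shift.  The noise-free validation therefore compares against the
  closed-form *relative* expectation, and direction concordance is only
  guaranteed for effects larger than the shift (~0.1 log2 units at the
  default DE settings).
* The p-value attached to protein ratios is a plain t-test on few peptides;
  with 2–3 peptides its power is limited and the fold-change conjunction
  does most of the filtering.
* The DE probability is an empirical count, so its resolution is 1/(2 ×
  genes); very small gene sets cannot reach high probabilities.
* No multiple-testing control beyond the probability rule, no protein
  inference from shared peptides, no isotope-impurity correction, and no
  isoform-level expression — all out of scope.
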