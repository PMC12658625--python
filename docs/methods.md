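# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical and design decisions a maintainer would want to know.

## Synthetic panels

`simulate_sources` draws, per site, an ancestral allele frequency uniform on
[0.05, 0.95] and population frequencies under a Balding–Nichols hierarchy:
DOG and the wolf ancestor each drift F_d from the root; the Italian (WIT)
and European (WEU) wolf populations each drift F_w from the wolf ancestor.
Using the additivity of drift variances and the Hudson relation (two demes
that each drifted F from a shared ancestor have pairwise Fst ≈ F), the
targets map analytically to branch parameters:

    F_w = fst_wolf_wolf,   F_d = fst_dog_wolf − F_w / 2,

which requires `fst_dog_wolf ≥ fst_wolf_wolf / 2` (validated). Haplotype
alleles are Bernoulli in the population frequency, so sites are in linkage
equilibrium; the outgroup is monomorphic for the ancestral allele, and REF/
ALT labels are randomized so polarization is exercised. Realized
Weir–Cockerham Fst lands within ±0.02–0.05 of target at the default sample
sizes (checked in the test suite).

**Tract implanting** is a Boolean (Poisson-start) model on the genetic map:
segment genetic lengths are Exp(mean 1/t Morgans) for admixture age t, and
the start intensity per Morgan is λ = −t·ln(1−q), which makes the expected
merged coverage exactly q (vacancy of a Boolean model is exp(−λ/t)). Starts
are sampled from 10/t Morgans left of the origin so coverage is stationary
at chromosome edges. Within a segment the focal haplotype's alleles are
redrawn Bernoulli in the empirical dog frequency. `TractSpec.haplotypes=(0,)`
restricts implants to one haplotype (backcross geometry: all dog ancestry
heterozygous), and `shared_haplotype=True` draws the dog haplotype once per
interval and copies it into every carrier — descent from a single
introgressed ancestor, the geometry of a historical, possibly selected
introgression.

**What the generator does not emulate:** background linkage disequilibrium
(sites are independent given population frequencies), mutation since
admixture, genotyping error, phasing error, and realistic site-frequency
spectra (Balding–Nichols overrepresents intermediate frequencies, so
absolute Tajima's D values are shifted positive genome-wide; all percentile
rules are relative, which is why they still behave). Passing tests therefore
demonstrate correctness of the estimators and the cascade's logic under
idealized signal/noise, not performance on real sequencing data.

## Relatedness

KING-robust kinship and the R0/R1 ratios are computed from pairwise-complete
3×3 joint genotype counts: king = [N(1,1) − 2(N(0,2)+N(2,0))]/(het_i+het_j),
r0 = opposing homozygotes / N(1,1), r1 = N(1,1) / discordant pairs. A pair
with no discordant genotypes but positive N(1,1) (a duplicate) gets r1 = ∞.
Both a strict joint rule (all three thresholds) and a "≥ 2 of 3" rule are
exposed; the default is joint. Worth knowing: a parent–offspring pair has
theoretical R1 ≈ 0.5 exactly at intermediate allele frequencies, so the
joint rule is a coin flip on that axis and the 2-of-3 rule is the robust
detector for first-degree relatives.

## Supervised ancestry and pedigree class

q̂ maximizes the binomial genotype likelihood with per-site mixture
frequency π = q·f_DOG + (1−q)·f_WOLF over q ∈ [0,1] (bounded Brent), using
pseudocount-smoothed reference frequencies (x+0.5)/(n+1). Finite reference
panels bias non-admixed individuals upward (the estimator sits at a boundary
and reference noise is asymmetric): with ~10 wolf references the floor is
roughly 0.03–0.04, falling below 0.015 with ~25. Interpret small q̂ against
a cohort baseline rather than against zero; the pipeline's `admixed_q_min`
is configurable for exactly this reason.

Pedigree classification compares the observed (hom-dog, het, hom-wolf)
triple by Euclidean distance to the F1/BC1w/BC2w/BC3w templates and to the
Hardy–Weinberg triple at q = hom_dog + het/2. Because the independent triple
borrows q from the data, it fits any one-haplotype geometry within
≈ 0.61·het² — the `recent_admixture` flag (pedigree beats independent) is
deliberately conservative, and the class label itself is the robust output.

## D-statistics

The frequency formula (not pattern counts) is used so unphased genotypes
suffice; positive D means excess P1–P3 sharing. Standard errors come from an
equal-weight delete-one jackknife over contiguous physical blocks (default
5 Mb); equal-bp blocks make Patterson's weighted variant unnecessary.
Note that for an individual carrying a few long tracts, the jackknife SE is
dominated by between-block heterogeneity, not site count — z grows with the
number of independent tracts/blocks, which is why whole-genome data detects
1%-level admixture and a single 50-Mb chromosome cannot.

## Local-ancestry HMM

States are dog-allele dosages {0,1,2} over the two haplotypes. Per-bin
emissions multiply genotype probabilities given two independent haplotypes
with alt-probabilities from (f_DOG, f_WOLF) as appropriate; empty bins emit
1 for every state. Transitions compose two independent per-haplotype chains
with switch probability 1 − exp(−τ·d) toward stationary (q, 1−q) over the
inter-bin genetic distance. (q, τ) are fitted by a coarse likelihood grid
followed by EM whose M-step maximizes the expected complete-data
log-likelihood numerically (L-BFGS-B over q ∈ [1e-4, 1−1e-4],
τ ∈ [1e-3, 1e4]); the E-step likelihood sequence is non-decreasing (tested).
Posterior decoding uses scaled forward–backward (exact against path
enumeration to 1e-10); bins are assigned at max posterior > 0.9, else
unassigned.

This is a genotype-level simplification of read-based local-ancestry models:
appropriate for accurately called high-coverage genotypes, with no
contamination or ascertainment model. Two practical limits surfaced by the
synthetic experiments: (i) *reference contamination* — if a large fraction
of the wolf reference carries the same introgressed haplotype as the focal
sample, in-region wolf frequencies shift toward dog and the region becomes
undetectable (at ~40% carrier haplotype frequency the emission evidence
actually favors WOLF); detection is comfortable up to roughly 25% carrier
frequency with ≥ 40 SNPs per bin. (ii) *genome-fraction prior* — an
individual whose only dog ancestry is one short region has genome-wide
q̂ ≈ 0, which suppresses the posterior unless per-bin emissions are strong.

**Sharing filter.** The per-bin count of Italian tracks in a dog state is
thresholded at the (100−top_pct) percentile of the positive-count
distribution (computed over bins with count > 0 — including zero bins would
trivialize the cut), ties included; any European dog-state occupancy
excludes a bin; only strictly adjacent eligible bins merge (a 1-bin gap
splits regions). Percentile base and tie policy are configurable.

## Window scans and validation

f_d uses the ABBA-BABA numerator with the dynamic donor pD = max(p2, p3) in
the denominator; the output column is also the quantity reported as "df" in
window-scan vocabularies. f_dM extends it to signed values (when p1 > p2 the
denominator is −S(pD, p2, pD, p4) with pD = max(p1, p3)); |f_dM| ≤ 1
per window always, whereas f_d is bounded only where the donor assumption
(p2 ≥ p1 toward P3) holds — another reason f_dM is the primary validation
statistic. Windows with fewer than 10 informative sites are masked and
excluded from percentile baselines. Windowed Fst is Weir–Cockerham as a
ratio of averages; percentile outliers are computed within each chromosome
with ties at the cut included. A candidate region is D-validated when one
overlapping window is in the top 0.1 percentile for *both* f_d and f_dM
(same window by default; relaxable to same region), and Fst-validated when
one overlapping window is in the lowest 1 percentile of Fst(Italian wolves,
dogs).

## Selection statistics

Tajima's D uses the standard constants and requires complete genotypes
within the scanned group (sites with missing calls are dropped so n is
constant). NCD2(tf) = sqrt(mean (MAF_i − tf)²) over SNPs plus fixed
differences versus the outgroup (contributing MAF = 0); low values indicate
frequencies pinned near tf, so outliers come from the lower tail; tf
defaults to 0.5 ({0.3, 0.4, 0.5} sensible). EHH partitions carrier
haplotypes by identity from the core outward; iHH integrates EHH by
trapezoid over genetic distance, truncated at EHH < 0.05 or a gap > 200 kb;
iHS = ln(iHH_A/iHH_D) standardized within 50 derived-frequency bins of
width 0.02 (bins under 10 SNPs merged with neighbors); outliers need both
|z| above the α = 0.01 normal quantile and −log10 p in the chromosome's top
1 percentile. SNPs with derived frequency outside [0.05, 0.95] are skipped.

## Dating

Around a focal SNP (window ±0.5 Mb by default, echoing a 1-Mb analysis
window), a consensus core haplotype is built from carriers; each carrier
side-length to first consensus mismatch is recorded in Morgans, censored at
the window edge with its censoring point kept. Under the model that
recombination breaks the shared haplotype at rate t per Morgan per side,
the censored-exponential MLE is t̂ = (#uncensored)/(Σ lengths); the 95% CI
is a parametric bootstrap (draw Exp(t̂), re-censor at the observed limits,
re-fit, percentile interval). An optional Poisson mutation term
(μ·t·bp-span per intact side) sharpens the likelihood when mismatch counts
are supplied; without it the estimator is a pure recombination clock and μ
is metadata. MCMC mode runs 10 Gaussian random-walk chains (proposal sd 10,
50,000 iterations, posterior from the final 10,000 each, flat prior on
t > 0) with a split-chain Gelman–Rubin check; it summarizes the same
likelihood and agrees with the MLE within sampling error. Years = mean of
the per-rate generation estimates × 4.4 (the wolf generation time), with
mutation rates 4×10⁻⁹ and 4.5×10⁻⁹ carried as the standard pair.

This consensus-mismatch decay model is a deliberate simplification of
importance-sampling TMRCA machinery: it supports exact closed-form checks
and honest recovery/coverage tests at desk scale, at the cost of ignoring
the reference panel's haplotype structure and mutation–recombination
interplay.

## Enrichment

Genes containing ≥ 1 SNP with per-site Weir–Cockerham Fst strictly above
0.95 (Italian wolves vs dogs) are flagged. The null places intervals of
exactly the flagged sizes uniformly at random (non-overlapping; chromosome
choice proportional to length; no exclusion mask — none is described for
this design) 1000 times; the statistic is pooled bp overlap with
DOG/DOGWOLF-assigned bins across admixed individuals divided by
(n_admixed × total gene bp). Pooled aggregation and the mean of
per-individual proportions coincide when every individual shares the
denominator, so only the pooled form is implemented. The two-sided
empirical p uses the +1 correction, minimum 2/(reps+1); the verdict
(enriched/depleted/neutral at α = 0.05) mirrors a distributional
comparison. Calibration caveat: with few genes or very clumped tracts the
overlap statistic has a large atom at zero and the discrete two-sided p is
conservative; calibration is exercised where the statistic is effectively
continuous.

## Pipelines

`run_recent` chains relatedness filtering → provisional leave-one-out q̂ →
non-admixed reference selection → per-individual q̂, D-statistic, local
ancestry and pedigree class. `run_historical` decodes every wolf against a
combined dog vs (Italian+European) wolf reference, applies the sharing
filter, validates candidates with the window scans, runs the selection
statistics, and dates validated regions showing the required selection
signals. The dating trigger defaults to a negative-Tajima outlier AND an
iHS outlier ("multiple concordant signatures"); `dating_signals: ihs`
relaxes it, because at desk scale the two signals conflict structurally — a
haplotype frequent enough to depress Tajima's D saturates the leave-one-out
references and stops being detectable as a dog region, while a detectable
(~25%-frequency) haplotype contributes intermediate-frequency variants and
pushes Tajima's D positive. Config defaults equal the published settings
(10-kb bins, posterior 0.9, 100 kb/10 kb and 50 kb windows, percentiles
10/0.1/1, Fst > 0.95, 1000 shuffles, μ ∈ {4, 4.5}×10⁻⁹, 4.4 y/generation);
every override is logged, and a manifest (parameters, seed, version) makes
outputs re-derivable.

## Problem sizes

The test and acceptance fixtures use a 50-Mb chromosome with 5,000 SNPs for
local-ancestry recovery (the density regime where 10-kb bins hold ~1–2
SNPs each is deliberately stressed by fitting τ and q rather than fixing
them); an 8×50-Mb genome with 60,000 SNPs for per-individual genome-wide
statistics (individual-level z > 3 needs many independent tracts/blocks);
and a 20-Mb chromosome with 80,000 SNPs for the historical cascade (window
validation wants ≳ 200 SNPs per 100-kb window, the whole-genome density
regime). Null calibrations run at 100–200 replicates, recovery studies at
50–100.
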