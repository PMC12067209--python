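# Methods

## Model

### Gene universe and genotypes

A simulated genome is a set of genes, each on exactly one chromosome-arm
segment, with a transcript length and a baseline expression level
`baseline_mu` (expected transcripts per cell in the diploid control).
The default genome spreads genes uniformly over 20 maize-style arms
(10 chromosomes × short/long), so a single arm carries ~5% of genes —
a realistic share for one arm of a 10-chromosome genome. Baseline
expression is lognormal (meanlog 3.0, sdlog 1.0), giving the right-skewed
abundance spectrum of bulk RNA-seq; lengths are lognormal around ~2 kb.

A genotype assigns an integer dose *d* ∈ {1..4} to a small set of varied
arms on background ploidy 2. The varied unit is deliberately the *arm*,
not the chromosome: an arm translocation varies one arm only, so genes on
the sister arm of the same chromosome are trans.

### Effect classes

Each gene carries one effect class with expected aneuploid/control ratio
r<sub>g</sub>:

| class | partition | ratio |
|---|---|---|
| dosage_effect | cis | d/2 |
| compensation | cis | 1 |
| inverse | trans | 2/d |
| direct | trans | d/2 |
| no_change | trans | 1 |

At d = 2 every class gives 1, and dosage_effect × inverse = 1 for every
dose (the inverse effect exactly offsets a dosage effect). Classes are
drawn per partition from user-set mixtures. The defaults — cis 60%
dosage effect / 40% compensation; trans 30% inverse / 10% direct / 60%
unchanged — encode the qualitative picture of arm aneuploidy in plants:
partial compensation in cis, inverse modulation as the most common trans
response, most trans genes unchanged. They are simulator knobs, not
estimates.

With two or more varied arms, a trans gene's per-arm ratios compose by a
selectable mode: `multiplicative` (product; the default, since observed
extreme combination responses look multiplicative), `additive`
(1 + Σ(r−1), floored at 10⁻⁶ so the composed ratio stays positive), or
`dominant` (largest |log r| wins, a rebalancing model). Which mode real
trans responses follow is an empirical question; the simulator asserts
none of them as true.

### Counts are compositional

True per-cell abundance is A<sub>g</sub> = baseline_mu<sub>g</sub> ·
r<sub>g</sub> · s, where s is an optional genome-wide scale modelling a
pure transcriptome-size change. Each sample yields L reads (default
2×10⁷, a 50M-read-pair library after filtering) distributed as
L · A<sub>g</sub>/ΣA. Consequently the recorded true size factor
T = ΣA/Σmu is invisible in the counts: scaling all A by 0.5 leaves the
count matrix bit-identical (the scaling is applied before the
normalising sum, and division by an exact power of two commutes with
it). Every ratio the analysis pipeline computes is therefore
r<sub>g</sub>/T, not r<sub>g</sub> — relative measures cannot see
transcriptome size, and the test suite asserts this closed form at zero
dispersion.

One consequence worth stating explicitly: a *genome-wide* inverse effect
(all trans genes at 2/d) rescales the transcriptome itself (T ≈ 2/d), so
on the library-normalised scale the trans median sits near 1, not at
2/d. The absolute response is recovered only after multiplying by the
size factor — which is exactly what the genome-normalised estimator
measures. Similarly, the noiseless cis median under a pure dosage effect
is (d/2)/T with T = 1 + f(d/2 − 1) for cis expression share f ≈ 5%,
i.e. ~1.463 rather than exactly 1.5 in trisomy.

### Count noise

Counts are gamma-Poisson with a single genome-wide dispersion φ:
var = μ + φμ² (Γ(shape 1/φ, scale μφ) mixing a Poisson). φ = 0
short-circuits the draw and returns the expectations exactly, giving
bitwise-reproducible oracles. The default φ = 0.05 corresponds to ~22%
biological CV per replicate, typical of well-controlled bulk RNA-seq.

### ddPCR panels

A paired panel measures, per sample, 10 cDNA amplicons (one per panel
gene, concentration ∝ per-cell transcript abundance) and 6 gDNA
amplicons (concentration ∝ arm copy number) from co-extracted nucleic
acid. Per-amplicon efficiencies are drawn once and shared between the
aneuploid and control panels (same primer pair), so they cancel in
aneuploid/control ratios; measurement noise is mean-one lognormal with a
stated CV (default 0.10). Droplet Poisson statistics are not modelled:
the analysis consumes concentrations, not droplet counts. gDNA amplicons
must sit on arms unvaried in the genotype, so per-genome normalisation
is dose-neutral and the estimator unbiased; placing one on a varied arm
is a configuration error. One sample per genotype is simulated,
matching a single 10-estimate panel per combination.

## Analysis pipeline

RPKM (raw × 10⁹ / (library × length), libraries defaulting to column
totals) → arithmetic replicate means per group → low-expression filter
(remove iff mean<sub>aneu</sub> + mean<sub>ctl</sub> < 1, strict, on the
normalised scale) → per-gene ratio → cis/trans partition (cis kept
separate per varied arm; trans excludes the cis genes of every varied
arm) → per-partition 0.05-bin distributions and medians.

Numerical conventions: bins are half-open and left-closed [k·w, (k+1)·w);
a display cap (default 3.0) pools larger ratios into one overflow bin,
while medians always use uncapped values; a zero control mean with
positive aneuploid mean yields an infinite ratio that is flagged,
excluded from medians and counted in the overflow rather than dropped;
the even-n median is the mean of the central pair.

Distribution comparisons use the two-sample Kolmogorov–Smirnov test
(D as the supremum of |ΔECDF| over the merged sample points, which
handles ties; p from the asymptotic Kolmogorov distribution with
effective size nm/(n+m) — adequate at thousands of genes, measured
rejection 3.6% at nominal 5% for n = 200) and Bartlett's test for
equality of variances (k−1 df chi-square). The differential-expression
caller is Welch's unequal-variance t on log₂(normalised + 0.5) with
Benjamini–Hochberg adjustment and calls at q < 0.05; its fold change is
the difference of group means on the log scale, so call sign and test
direction always agree. Degenerate genes (zero variance in both groups)
get the noiseless-limit p of 1 (equal means) or 0 (unequal). Modulation
summaries report, per cis arm, % unchanged = 100(n − n_DE)/n, and for
trans the %SU/%SD/%DE of significantly up-/down-regulated genes.

## Size estimation

Per-genome expression averages cDNA/gDNA over the six amplicons *before*
forming the aneuploid/control ratio (damping per-primer efficiency
differences), then divides by the per-transcriptome ratio of the same
gene from the normalised counts. The ten estimates pass a single-pass
outlier rule — remove E<sub>g</sub> iff |mean − E<sub>g</sub>| ≥ 2 ×
sample SD (n−1; boundary removes; SD = 0 removes nothing) — and the
retained set is summarised as mean ± SE. The significance test against
T = 1 is a one-sample t on the *log* estimates (multiplicative
measurement noise makes the log the natural scale for a
ratio-of-ratios); a spread within float rounding of zero is treated as
exact. At zero noise the pipeline returns the simulated T exactly for
any T, independent of which six unvaried arms host the gDNA amplicons.

### Known calibration limits

The ten per-gene estimates are *not* independent: all share the same six
gDNA normalisers (and, weakly, the library totals), contributing a
common multiplicative error of CV ≈ cv·√2/√6 ≈ 0.058 at cv = 0.1 that
the one-sample t-test cannot see. Measured over simulations at T = 1
(cv = 0.1, φ = 0.05), the nominal-5% test rejects ~12% untrimmed and
~17% after the 2-SD trim (which is itself mildly anticonservative at
n = 10). Error propagation for the same noise gives SD(mean)/T ≈ 0.09,
so the mean lands within 10% of the true T in only ~74% of runs. Both
are structural consequences of the shared-normaliser design of the
assay, not of the implementation; p-values near the threshold should be
read accordingly, and tighter calibration would need replicate gDNA
panels or an explicit shared-error model.

## What the simulator does and does not emulate

Emulated: per-gene expected ratios by effect class, multi-arm
composition, partial-compensation mixtures, a global size scaling
invisible to counts, overdispersed replicate counts, paired cDNA/gDNA
panels with shared efficiencies. Not emulated: read-level artefacts
(alignment, multimapping, organelle contamination), isoform structure,
batch effects, gene-specific dispersions, correlated co-regulation
beyond the shared class structure, droplet-level quantification, or
endoreduplication. Passing tests therefore validate the *analysis
machinery and its closed-form behaviour*, not the biology of any real
dataset.

## Reproducibility

All randomness descends from one integer seed via spawned sub-seeds
(genome, assignment, counts, ddPCR), so a fixed configuration produces a
byte-identical output tree; configs round-trip losslessly through YAML
and each run records a hash of its scientific configuration. Default
problem sizes (2000 genes, 3 replicates, 200-replicate calibration
suites) keep a full pipeline run in seconds and the whole test suite
under a minute on one CPU.
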