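# Methods

## Problem setting

The *FCGR3B* gene (low-affinity Fc gamma receptor IIIb, chromosome 1q23.3)
is copy-number variable, and its promoter is so similar to the *FCGR3A*
paralog that genotyping assays must target paralogous sequence variants.
`mlpacall` implements the complete analysis chain for an MLPA
(multiplex ligation-dependent probe amplification) copy-number study of this
locus in a rheumatoid-arthritis case-control cohort: peak normalization,
integer copy-number calling, qPCR cross-validation, a mechanistic model of
why an indel under a probe's ligation site silences that probe, two-probe
indel genotyping, and the association statistics. A synthetic cohort
generator reproduces the statistical structure the analysis assumes so every
stage can be tested end to end without access to the original samples.

## MLPA normalization

Each MLPA probe contributes one fluorescence peak per sample. The dosage
ratio of a target probe is its peak height divided by the sum of the three
control-gene peaks (*CREBBP*, *EXT1*, *EP300*) of the same sample; this
cancels per-sample DNA amount and injection efficiency. Ratios are then
rescaled per probe within each assay batch so that the cohort median equals
2.0 — the assumption being that the median individual is diploid at the
locus. The median (not the mean) is used; even-sized cohorts take the
midpoint of the central pair. Samples whose control-peak sum is not finite
and positive are flagged and excluded from medians and downstream fits but
retained in all outputs, so group accounting stays auditable. An explicit
peak height of 0 is treated as a biological zero (candidate homozygous
deletion), never as missing data.

## Integer copy-number calling

Normalized ratios for a CNV probe cluster on an integer lattice with
per-copy spacing u. Calling proceeds in three steps.

**Model selection.** A 1-D Gaussian mixture is fitted for K = 1 ..
max_cn + 1 components (default max_cn = 6), k-means++-initialized with five
seeded restarts, and K is chosen by BIC; ties within 2 BIC units resolve
toward the smaller K. K is additionally capped at n/2 so every component
can hold at least two samples. Inputs with at most max_cn + 1 distinct
values (noise-free data, as produced by the simulator at sigma = 0) are
modeled directly as point masses — EM on zero-variance clusters is
ill-posed.

**Labeling.** Components must be mapped to integer copy numbers. Because of
the median-to-2 anchoring, the natural primary rule anchors the
highest-weight (modal) component at CN 2, giving u = modal mean / 2. That
rule is provably wrong for a probe that counts only a subset of copies: when
a common allele silences the probe, the modal individual may carry one
countable copy, the lattice sits at 0, 2u, 4u, ... and the modal anchor
labels it 0, 2, 4, ... Three candidate units are therefore evaluated —
modal mean / 2, the median spacing between adjacent component means, and
modal mean — and each is scored by the weighted squared distance of
component means from their nearest lattice integers. Candidates are
rejected outright when they label the modal component outside {1, 2, 3}
(implausible split of the central class) or when all substantial components
(weight >= 1%) share a common label factor >= 2 (the classic signature of a
half-sized unit). The surviving candidate with the smallest lattice
residual wins; unpopulated interior classes are tolerated and only break
ties. Components whose labels collide after rounding are merged
moment-matched; a component below 0.3 u is labeled CN 0, a fixed fraction
of the unit so the rule is scale-free. If a single class remains the probe
is flagged `no_cnv` and yields constant CN 2 calls — the behavior of a
reference gene, or of the third *FCGR3B* probe whose failure has no known
sequence explanation.

**Assignment.** Samples are assigned to the maximum-posterior component;
the posterior is recorded and calls below 0.9 are flagged low-confidence
(the threshold is configurable; the flag never suppresses the call). Two
refinements keep rare classes callable. First, copy numbers with no fitted
component (interior holes, and everything between the top fitted class and
max_cn) receive low-weight components at their lattice positions
(weight 0.5/n), so a 5-copy sample in a cohort with three such individuals
is called 5 rather than absorbed by the 3-copy cluster. Second, a fitted
component whose standard deviation exceeds twice the cohort-typical
per-copy relative spread (the weighted-median sd/mean of well-populated
classes) has its assignment variance reset to the typical value — a sparse
high-copy tail swallowed by one broad component would otherwise dominate
its neighbors. Ratios below 0.3 u are called CN 0 outright.

## qPCR quantification (delta-delta Ct)

Replicate Ct values (triplicates by default) are averaged arithmetically; a
replicate standard deviation above 0.5 cycles sets a QC flag but does not
remove the sample. With amplification efficiency fixed at 2 (perfect
doubling, no efficiency correction), the relative quantity is
Q = 2^-(Ct_target - Ct_reference) and copy numbers are anchored to the
cohort: CN_i = 2 Q_i / mean(Q), which forces mean(CN) = 2 exactly and makes
the estimate invariant to constant Ct shifts. A calibrator-sample variant
(the textbook formulation) is available but not the default. Platform
concordance is measured by Pearson correlation of continuous estimates
against MLPA integer calls; rounding before correlating is an option, off
by default.

## Ligation model and indel genotyping

An MLPA probe is two half-oligos hybridizing side by side; only a sealed
nick amplifies. The model is deliberately binary: signal requires (i) both
half-probes to hybridize somewhere on the allele (edlib infix alignment
within 20% edits) and (ii) the 2w bases spanning the junction — the last w
of the upstream half and the first w of the downstream half — to occur
contiguously in the allele. Any substitution or indel inside the window
breaks condition (ii). The window defaults to w = 10 and is exercised at
w in {4, 8, 10}; no thermodynamic modeling is attempted because nick
integrity alone reproduces every qualitative behavior of interest.
Promoter coordinates are TSS-anchored (-1 immediately upstream of the
transcription start, no position 0); applying a variant keeps the anchor
fixed so downstream coordinates survive indels.

The -256A>TG indel (the adenine 256 bases upstream of the TSS replaced by
TG, net +1 base) falls exactly on probe #1's junction: probe #1 therefore
counts wild-type copies only, probe #2 (junction far from the indel) counts
all copies, and per sample mt = CN(probe #2) - CN(probe #1),
wt = CN(probe #1). Pairs with CN(probe #1) > CN(probe #2) are physically
impossible, flagged invalid, reported, and excluded from association —
never repaired. Genotypes are classed WT>MT / WT=MT / WT<MT, and group
allele totals sum per-individual copy counts (a CNV locus does not obey 2n
accounting). Samples typed on only one probe stay usable for CNV-only
analyses.

Because the true inter-probe spacer sequence is not bundled, the reference
used by the model is a synthetic 600-bp promoter embedding the published
half-probe target sequences, with probe #1's junction adenine at -256 and
seeded random sequence elsewhere; construction is rejected and redrawn
until every junction window is unique on the wild-type allele and the
mutant allele retains exactly the probe #2/#3 junctions. Conclusions about
junction chemistry do not depend on the spacer sequence.

## Association statistics

Contingency tables are collapsed to 2x2 by summing "exposed" columns
against the rest. Odds ratios use the cross-product with Woolf (log-normal)
95% intervals; a zero cell triggers the Haldane-Anscombe +0.5 correction
and tags the result. Chi-square tests are Pearson without Yates correction
(df = (r-1)(c-1); the genotypic 3x2 test has 2 df); stratified 2x2 tests
use the continuity-uncorrected Cochran-Mantel-Haenszel statistic, which in
the single-stratum default reduces to (N-1)/N times the Pearson statistic.
The allelic test counts every gene copy once. No multiple-testing
correction is applied by default. All p-values are two-sided.

## Synthetic cohorts

Defaults mirror the study conditions: 518 cases / 304 controls; control
copy-number class probabilities 1 copy 6.7%, 2 copies 83.9%, high 9.4%
split 3:4:5 copies as 8% / 1% / 0.4%; each copy independently mutant with
frequency 40.7%. Case class probabilities are produced from the control
distribution by per-class odds rescaling (odds multiplied by the class OR,
transformed back, renormalized), so null and alternative simulations share
one code path. Per-copy indel status is i.i.d. — no linkage between CNV
state and the indel is modeled, a documented simplification. True probe
signals come from the ligation model applied to each individual's copies;
the uninformative probe is rendered phenomenologically (always 2) because
its real failure mode is unexplained.

MLPA peaks: control peaks are drawn around scale/3 with multiplicative
lognormal noise (sigma = 0.07 by default, a plausible spread for clean MLPA
data — the true dispersion of the original assay is unpublished); target
heights are expected ratio x realized control sum x median-1 lognormal
noise, so the modal class median is exact and normalization is unbiased;
zero-signal probes emit half-normal near-zero peaks (sd 0.3 sigma,
vanishing at sigma = 0); a per-sample lognormal DNA-amount factor
multiplies everything and cancels in ratios. qPCR: target mean
Ct = baseline - log2(max(copies, 0.5)/2) with Gaussian replicate noise
(sd 0.15 cycles); the half-copy floor makes zero-copy samples amplify very
late rather than never. All randomness flows from a single seed;
identical parameters give byte-identical cohorts.

What the generator does **not** emulate: batch drift between runs, peak
shape and electrophoresis artifacts, paralog cross-hybridization,
linkage/haplotype structure, and the unexplained behavior of the third
probe (reproduced phenomenologically only). Passing recovery tests
therefore demonstrates internal consistency of the pipeline under the
stated noise model, not robustness to every failure mode of real capillary
data.

## Verification choices and problem sizes

Tests freeze hand-computed or closed-form expectations for every worked
example, cross-check the odds-ratio/CI and chi-square implementations
against independent implementations (statsmodels' 2x2 machinery; a
textbook chi-square oracle), and exercise invariants (scale invariance,
idempotence, anchoring conservation, call monotonicity, conservation
wt + mt = total) as property tests. Cohort-level checks use: a noise-free
round trip at the study sizes (must recover every individual exactly); a
sigma = 0.07 cohort of 800 (caller accuracy >= 99%, mutant-allele frequency
within 3 binomial SE of the generating 40.7%); 500 null cohorts of 150/150
at sigma = 0.05 for type-I calibration of the full pipeline
(Kolmogorov-Smirnov uniformity of allelic p-values); and 200 truth-level
replicates at 518/304 for recovery of an injected low-CN odds ratio of 2.0.
These sizes are the package's own defaults for its validation suite, chosen
to give stable statistics at interactive runtimes.

## Known limitations

- The caller assumes a common per-copy unit across classes (linear dosage
  response); saturation or probe-specific compression would bias high-CN
  calls.
- Lattice labeling needs the modal class to be CN 1-3 after median-to-2
  normalization; cohorts dominated by homozygous deletion would defeat it.
- The binary ligation model ignores partial destabilization by mismatches
  outside the junction window.
- Exact zero-copy ratios are only meaningful if the control-sum QC passed;
  a failed control reaction and a homozygous deletion are distinguished
  solely by the QC flag.
- Association machinery offers no covariate adjustment (no logistic
  regression) and no exact inference beyond the Haldane correction.
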