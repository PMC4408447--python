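# Methods

This note documents the models implemented in `aldorecur`, the defaults they
ship with, and the design choices made where more than one reasonable
construction exists.

## Recurrence statistics

The chance probability of observing the same protein-altering mutation
repeatedly is decomposed into two independent binomial events.

**De novo recurrence.** With per-base per-proband de novo rate
µ (default 1.4×10⁻⁸) and n probands, the probability that a *specified* base
is hit twice or more is the binomial tail P(X ≥ 2), X ~ Bin(n, µ).  Because
the coincidence could have occurred at any protein-altering base, the
per-site tail is corrected for the exome target size T (default 24.75 Mb).
Two corrections are exposed: the linear union bound T·P_site (the primary
statistic) and the independence form 1 − (1 − P_site)^T; at these magnitudes
they agree to ~2×10⁻⁶ relative.  The exact binomial tail is used rather than
the C(n,2)µ² approximation; the two agree to <1 % whenever nµ < 10⁻⁴, which
the test suite asserts on a parameter grid.

**Additional carriers.** The probability that k of m further unrelated
subjects carry a variant of population allele frequency q is the binomial
pmf with per-subject carrier probability set equal to **q itself, not 2q**.
Under Hardy–Weinberg the heterozygote frequency is ≈2q, so this convention
*understates* the chance probability by ~2^k and is therefore conservative
when the statistic is used as evidence against the chance hypothesis.  Both
P(X = k) (primary) and P(X ≥ k) are reported; for rare q they agree to 2
significant figures.

**Biallelic loss of function.** For a cumulative loss-of-function allele
frequency q (summed over all qualifying alleles, so compound heterozygosity
and homozygosity are both covered), the expected biallelic subject frequency
is q² and is reported together with its reciprocal.  The arithmetic is exact
in the input; no rounding is forced to match any externally quoted "1 in N".

## ARR screening with censored values

Laboratory reports censor at detection limits, so every measure is a value
plus a relation (equal / below / above).  The aldosterone:renin ratio is
computed by interval arithmetic on the consistent-value sets: the ratio
interval is [a_lo/r_hi, a_hi/r_lo], mapped back to a censored scalar (an
exact aldosterone over "<r" renin yields the lower bound a/r, reported as
">a/r").  When both operands are censored on conflicting sides the ratio
carries no information and is returned flagged indeterminate rather than as
a number.  Ratios are reported to 1 decimal; thresholds are applied to the
unrounded value.

Classification rules: ARR > 20 (ng/dl per ng/ml/hr) with aldosterone
> 15 ng/dl; or aldosterone/direct-renin > 2.4 with aldosterone > 15; or a
marginal ratio (above threshold with aldosterone ≤ 15) accompanied by
hypokalemia (K⁺ < 3.5 mmol/l).  "Marginal" is not precisely defined in the
clinical sources; the rule implemented here (threshold ratio without the
aldosterone criterion, rescued only by unexplained hypokalemia) is an
interpretation and is labelled as such in the classifier output.  Censored
inputs are evaluated conservatively — a rule fires only if every value
consistent with the censoring satisfies it; in particular a ">x" bound
satisfies a strict ">t" threshold only when x ≥ t.

## Cohort variant searches

Variants are keyed by (chrom, pos, ref, alt) after minimal-representation
trimming (shared suffix, then shared prefix; full left-alignment requires a
reference sequence and is out of scope).  The recurrent-novel-variant search
keeps protein-altering consequences (missense, nonsense, frameshift,
canonical splice, in-frame indel, stop-loss — a configurable set), drops
anything present in a reference database, and returns variants carried by at
least `min_subjects` distinct subjects.

Gene burden uses the two-sided Fisher exact test on the 2×2 carrier table,
with the common two-sided convention (sum of all tables with point
probability ≤ the observed one); the test suite checks it against direct
hypergeometric enumeration.  Multiple-testing correction is Bonferroni over
a caller-supplied gene count.  The dominant/recessive mode labels how
carriers were defined upstream and does not change the arithmetic.

## Haplotype sharing and mutation age

**Intervals.** The phased shared interval scans outward from the focal
variant and stops at the first marker where any pair of carrier haplotypes
differs; its length is the distance between the two innermost discordant
markers ("flanked by" convention).  The unphased bound uses the only
genotype configuration that excludes sharing without phase — two carriers
homozygous for different alleles — and therefore always contains the phased
interval (asserted property).  Sides with no discordance are bounded by the
map edge and flagged censored.

**Age model.** Physical distance maps to recombination fraction through the
Haldane function θ = (1 − e^(−2d))/2 with d in Morgans from a single average
rate (default 2.9 cM/Mb); at sub-megabase scales this is numerically linear,
so the choice of map function is inert but stated.  Conditional on g
generations to the common ancestor, the ancestral segment survives to marker
k with probability S_k = (1 − θ_k)^g.  A first discordance at marker j
arises from a breakpoint in interval k ≤ j followed by chance matches at
markers k..j−1 (probability ∏f_m, f = population frequency of the
ancestral-haplotype allele) and a mismatch at j (1 − f_j), plus a survival
term with a marker mutation at j (rate 2×10⁻⁸/generation by default):

    P(j | g) = Σ_{k=1..j} (S_{k−1} − S_k) ∏_{m=k..j−1} f_m (1 − f_j)
               + S_j (1 − (1 − µ_m)^g)

A censored side contributes S_M + Σ_k (S_{k−1} − S_k) ∏_{m=k..M} f_m.  With
the mutation term off, these probabilities sum to one over all outcomes
(enumeration-checked).  Carrier sides are independent; the total
log-likelihood is their sum.  This is a recombination-clock model in the
ESTIAGE family; numerical equivalence with any particular published program
is not claimed, and all validation is self-consistent (data simulated from
this model, re-estimated by it).

**Estimation.** Grid search over integer g (default 1..5000) — the
likelihood is cheap, unimodality is not guaranteed, and generation counts
are integer-scaled.  The 95 % CI is the profile-likelihood region logL ≥
logL(ĝ) − χ²₁(0.95)/2.  Monotone likelihoods put the estimate at a grid
boundary; this is flagged, not treated as an error (it is the correct answer
for degenerate observations such as fully censored sharing).  The ancestral
haplotype defaults to the carrier consensus (ties to the first-listed
carrier) and can be supplied explicitly.

## Channel model and trace analysis

**Forward model.** Gating is Hodgkin–Huxley m²h with Boltzmann steady
states.  Availability includes a non-inactivating floor:
h∞(V) = h_floor + (1 − h_floor)/(1 + e^((V − V_h)/k_h)), which produces the
small sustained current and the repolarization tail currents measured by the
fraction-non-inactivated protocol.  τ_m(V) is a bell (fast deactivation at
hyperpolarized potentials, ~1.5 ms at −90 mV; peak ~3.7 ms near the
activation midpoint).  τ_h(V) decays e-fold per 30 mV of depolarization from
its −20 mV reference and blends smoothly (logistic crossover at −70 mV) into
the slow recovery time constant at deep potentials, so envelope protocols at
−90 mV recover with τ ≈ τ_rec.  The unitary current is linear in driving
force, i(V) = γ(V − V_rev) with V_rev = +60 mV (no measured reversal is
available; the value is configurable).

Within each constant-voltage segment the gate ODEs are linear and are
integrated *analytically* at every sample, so the deterministic simulator is
exact for piecewise-constant protocols at any sampling interval.

**Stochastic engine.** The open-channel count at each sample is an exact
binomial draw, X(t) ~ Bin(N, m(t)²h(t)), and I = iX + Gaussian background.
Mean N·p·i and isochronal variance N·i²·p(1 − p) therefore hold exactly by
construction — precisely the moments non-stationary noise analysis consumes.
Samples are independent across time: single-sweep autocorrelation is *not*
reproduced, and no analysis in this package depends on it.  This buys exact
moment laws and large speedups over per-gate Markov simulation.  Seeds are
explicit everywhere; no global random state is used.

**Fitters.** Activation is fitted on the peak I–V jointly with the linear
driving force, I(V) = G_max(V − V_rev)/(1 + e^((V_half − V)/k)); a
conductance-first mode is provided but current-mode is the default, since
peak currents are the primary measurement.  Peak detection uses the signed
extremum after baseline subtraction (inward currents negative; ratios use
magnitudes).  Exponential fits use log-linear initialization followed by
nonlinear least squares; initializers are data-driven, never random, so all
fitters are deterministic given their input.  Window current is the
trapezoid integral of min(activation, availability) over a voltage grid on
normalized curves.

**Noise analysis.** Isochronal mean and variance are computed across
repeated identical sweeps over the repolarization-tail segment.  Background
variance (final 50 ms of the holding segment) is subtracted.  The unitary
current is the initial slope of variance vs mean restricted to |⟨I⟩| ≤ 30 %
of its maximum — the "initial slope" region is not precisely defined by the
underlying method, and sensitivity to this cutoff is part of the test suite.
The slope is estimated by ordinary least squares followed by one
inverse-variance reweighted pass (the sampling variance of a sample variance
scales with the squared true variance, so high-current isochrones are much
noisier); the reweighting is deterministic and roughly halves the estimator
spread.  N and the open probability are reported only when the quadratic
term of the variance–mean parabola is resolved (negative with |b| > 3 SE);
low-open-probability data cover only the initial limb and the analysis then
explicitly withholds N and p rather than reporting garbage.

## Calibration of the default parameter sets

The wild-type and M1549V defaults are calibrated **closed-loop**: parameters
were adjusted until the observables produced by the *full analysis pipeline*
(not the raw model parameters) sit at the published values — fitted
activation V_half −38.9 / −44.2 mV, fraction non-inactivated 2.4 / 6.7 %,
recovery τ 871.4 / 1689.0 ms, noise-recovered unitary current 273.7 /
285.0 fA, and a ~10× inactivation slowdown.  Two consequences are worth
stating plainly:

* the m-gate midpoint differs from the fitted V_half (the open probability
  goes as m²h, and peak currents reflect kinetics as well as steady state);
  the defaults store the gate midpoints (−42.16 / −49.29 mV) that *produce*
  the published fitted values;
* each variant's γ is set so that the noise-analysis *estimate* lands on the
  published unitary current; the initial-slope estimator carries a small
  (≈1–4 %) curvature bias that the calibration absorbs, so the generative γ
  values (1.86 / 2.05 pS) are not themselves the published numbers.

The mutant channel count default (2000 vs 5000) reproduces the reduced
whole-cell current density; density comparisons simulate cell-to-cell
variability with a lognormal channel-count spread.

## Problem sizes and numerical choices

Default study sizes: I–V families of 15 steps (−90..+50 mV, 10 mV) at
0.1 ms sampling; inactivation prepulses −90..−20 mV in 5 mV steps, 5 s long,
0.5 ms sampling; envelope recovery at 9 log-spaced intervals (25 ms–6.4 s);
noise ensembles of 300 sweeps (oracle checks) to 2000 sweeps (calibration
closure) at 0.02 ms sampling with N = 5000 channels.  The age-estimation
generator uses 40 markers per side at 100 kb spacing with
Uniform(0.2, 0.9) ancestral-allele frequencies, 3–4 carriers, and 50
replicates per condition for recovery studies.  Exponential-fit convergence
tolerances are 10⁻¹²; ARR reporting rounds to 1 decimal after thresholding;
the age grid is integer 1..5000.

## What the generators do and do not emulate

The channel simulator reproduces ensemble means and isochronal variances of
an m²h channel population under step protocols; it does not model leak,
series resistance, capacitive transients, P/4 subtraction, drift between
sweeps, or single-sweep autocorrelation.  The haplotype generator implements
exactly the likelihood's generative model (single breakpoint per side,
marker-wise chance matching, independent sides), so age-recovery tests
demonstrate internal consistency of estimator and model — not robustness to
gene conversion, phasing error, genotyping error, or frequency
misspecification, none of which are modelled.  The toy cohort generator
plants one recurrent novel variant and draws separable lab panels; it makes
no attempt at realistic exome-wide variant frequency spectra.  Passing tests
therefore validate the arithmetic and the estimators under the stated
models; they do not certify performance on real recordings or genotypes.

## Known limitations

* The age estimator's CI is a profile-likelihood interval; coverage is
  verified by simulation at the default map (≥90 % at g ∈ {20, 100, 500})
  but is not guaranteed under marker maps far sparser or denser.
* Burden testing assumes equal capture/coverage between case and control
  cohorts; no coverage harmonization is attempted.
* The unphased sharing bound uses homozygous-discordant exclusion only; it
  is a bound, not an estimate, and is censored at the typed region's edge.
* Allele normalization trims to minimal representation without a reference
  sequence; fully left-aligned comparison across call sets needs upstream
  normalization.
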