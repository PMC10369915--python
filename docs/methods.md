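# Methods

## Screen model and enrichment statistic

A bacterial peptide-display selection is modeled as sampling from a
defined library of fixed-length peptides. The library contains
single-tyrosine phosphosite peptides (the signal class), optional
multi-tyrosine peptides (excluded from specificity analyses because
the phosphorylated position is ambiguous), and tyrosine-free negative
controls, which cannot be phosphorylated and therefore measure the
non-specific background of bead capture and sequencing.

Reads are counted by exact translated match: the peptide-coding region
(a configurable offset/length within each read; default the whole read
in frame 0) is translated and must equal a library peptide exactly.
Synonymous codons therefore collapse correctly, and reads with
ambiguous bases, stop codons, partial codons, or no exact match are
tallied with reasons rather than silently dropped. No mismatch
tolerance is applied: the library is a defined set, so a
one-substitution read is most likely a sequencing error of an unknown
template and counting it would blur neighboring library members.

The enrichment statistic is the plain frequency ratio
`score_i = f_i(selected) / f_i(input)` with a shared pseudocount
(default 1 read per peptide in both samples) so dropout peptides stay
finite; pseudocount 0 is supported for exactness checks. Replicates
are averaged on the score scale (arithmetic mean), and peptides from
different libraries screened under the same conditions are
concatenated, each keeping its own replicate count; no imputation is
performed. The statistic deliberately stays a ratio — no
variance-stabilized or count-regression scoring — because the
downstream analyses (cutoff calibration, logos) operate on ranks and
ratios, and the controls provide an empirical null.

## Hit calling and logos

The hit cutoff is either fixed by the user or calibrated as the
smallest control score (never below a configured floor, default 0)
such that at most `max_control_fraction` (default 2%) of controls
score above it. Comparison is strictly greater-than, which makes hit
counts unambiguous at ties. Hit calling uses the mean score over
replicates by default; a stricter per-replicate mode (every replicate
above the cutoff) is available because with few replicates the two
conventions can differ for borderline peptides.

The logo matrix compares the amino-acid composition of the hit set to
the full single-tyrosine library at each position relative to the
phosphotyrosine (pTyr = 0, excluded; window default −5…+5 clipped to
the offsets the library actually covers):

    value(p, a) = log2( (n_hit(p,a)+pc) / (N_hit(p)+20·pc) )
                − log2( (n_lib(p,a)+pc) / (N_lib(p)+20·pc) )

with a shared pseudocount (default 1 occurrence). Log base 2 is a
configuration option; 2 is the default so that "twice the library
frequency" reads as +1. Cells where a residue is absent from both
sets at pseudocount 0 are defined as 0 (no evidence either way). With
a pseudocount, absent-from-hits residues get the finite negative value
of the formula. The scanning-mutagenesis matrix is
`log2(score_variant / score_wildtype)` per (position, substitution),
with wild-type cells exactly 0 by construction; variants with input
counts below a configurable floor are flagged missing rather than
imputed, because for weak binders the screen cannot distinguish
neutral from loss-of-function substitutions.

## Synthetic screens

Selection is modeled as a single multiplicative reweighting: input
counts are Multinomial(depth, input frequencies) and selected counts
Multinomial(depth, probabilities ∝ input frequency × weight). One
round suffices to give enrichment scores the statistical structure the
pipeline assumes (expected score `w_i / E[w]` under uniform input).
The generator does not model expression bias, PCR jackpotting, or
phosphorylation efficiency; passing recovery tests therefore
demonstrates correctness of the scoring mathematics and sampling
machinery, not robustness to those real-data artifacts. Default depths
(10^5–10^6 reads per sample) and library sizes (hundreds of peptides)
are chosen so multinomial noise is a few percent per peptide, the
regime the statistic is designed for. All randomness flows from one
explicit seed per call through `numpy.random.default_rng`; there is no
global RNG state.

## Binding models

Direct fluorescence polarization titrates receptor R against a fixed
fluorescent probe L. The bound-probe fraction uses the exact
ligand-depletion quadratic, not the hyperbolic approximation, because
probe concentrations comparable to tight K_D values otherwise bias
fits. Competition mode titrates an unlabeled competitor I at fixed R
and L; the three-species equilibrium is solved exactly via the cubic
in free receptor (trigonometric closed form — the physical cubic has
three real roots, exactly one in [0, R] — followed by Newton polish to
machine precision, which also guards against cancellation when the
constants span many decades). IC50/Cheng–Prusoff shortcuts are never
used: they systematically bias tight binders when the probe is
appreciably depleted. Mass balance is asserted to 1e-9 relative on
every call, and the test suite checks the solver against an
independent damped fixed-point mass-action iteration.

Fits are bounded nonlinear least squares (`scipy.optimize
.least_squares`) over {log K, signal_free, signal_bound} with the
constant log-parameterized (enforcing positivity and making the SE a
relative error via the delta method), three starts spread over the
titrated range to avoid local minima, and cost tolerance 1e-10.
Standard errors come from the Gauss–Newton covariance with residual
variance estimated on n − p degrees of freedom. A fit whose amplitude
is numerically zero (flat signal) is flagged unconverged rather than
raised. Note that with ~12-point designs the studentized error
(estimate − truth)/SE behaves like a t-statistic with ~9 degrees of
freedom, so a ±2·SE interval covers ~92% rather than the Gaussian
95% — the calibration the acceptance study measures.

Fold-changes between domain variants are ratios of geometric-mean K_D
over replicate fits (fold > 1 = tighter variant), with a two-sided
Welch t-test on log K_D and a back-transformed CI whenever both sides
have ≥2 replicates. Units are µM throughout; callers convert nM on
load.

## Activation and energetics

Activation curves are fit as
`rate(c) = basal + (max − basal)·cⁿ/(EC50ⁿ + cⁿ)` with n fixed to 1 by
default (the observed curves are simple and saturating; Hill mode is
retained as a robustness check). The basal rate is a fitted parameter
so zero-activator points inform it. The rate axis is standardized
internally before fitting, which makes the EC50 exactly invariant to
affine rescaling of the rates; a Gauss–Newton polish with the analytic
Jacobian drives the gradient to machine zero so the reported optimum
does not depend on trust-region stopping. Degenerate inputs (a single
distinct concentration) return a no-transition flag. Each curve is fit
independently; no shared maximal rate is imposed across peptides,
since peptide-specific endpoint differences would otherwise leak into
EC50.

The K_D–EC50 relationship is summarized by Pearson correlation and a
linear fit on log10–log10 axes; zero variance on either axis is
reported as undefined rather than silently returning 0 or 1.

Double-mutant cycles use `ΔΔG = RT·ln(K_D,state/K_D,wt)` (negative =
tighter) and `ΔΔG_int = ΔΔG_AB − ΔΔG_A − ΔΔG_B =
RT·ln((K_D,AB·K_D,wt)/(K_D,A·K_D,B))`, which is zero for additive
cycles, symmetric in the two mutations, and negative when the double
mutant binds tighter than additivity predicts. Equivalently
`ΔΔG_int = RT·ln(fold_in_wt / fold_in_other_background)`, so coupling
can be computed directly from reported fold-changes: a mutation whose
effect is attenuated by the second mutation couples positively
(sub-additive), one whose effect is enhanced couples negatively.
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T defaults to 298.15 K (the assay
temperature is exposed as a parameter and recorded with every derived
energy); kJ output is a flag.

## Problem sizes and numerical choices

The test and acceptance studies run at desk scale by design:
weight-recovery screens use 10^6 reads per sample over ~120 peptides
(multinomial error well under the ±0.05 slope tolerance), logo
recovery uses 440 peptides at 3×10^5 reads, solver cross-checks use
10^4 random systems spanning six decades of concentration and
affinity, and fit-calibration studies use 100 seeded repeats per fit
type at noise levels of 1–2% of the signal dynamic range, matching
plate-reader behavior. Noise on titrations is additive Gaussian
(instrument noise), not Poisson, by the same reasoning.

## Known limitations

- Exact-match counting cannot use reads from libraries whose coding
  constructs include indels or degenerate codons at fixed positions.
- The one-round multiplicative selection model ignores bead-capture
  kinetics and avidity; true screens may compress or expand the
  dynamic range of weights, which affects absolute scores but not the
  rank-based analyses.
- Gauss–Newton standard errors are first-order; for very asymmetric
  likelihoods (poorly constrained tight binders) profile-likelihood
  intervals would be preferable.
- The logo treats positions independently; context-dependent
  preferences (detectable by the scanning-mutagenesis matrix) are
  averaged over.
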