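# Methods

This note documents the statistical model behind `lipquant`, the defaults
it ships, the numerical choices made where the design was open, and what
the synthetic-data generator does and does not emulate.

## Experimental design and input model

An experiment is one compound against one proteome: a vehicle control plus
seven compound dilutions, four replicates each (32 samples). The input is a
long-format peptide quantification table (modified peptide sequence,
protein accession, sample, intensity) as exported by DIA search engines.
Intensities are taken as already quantified and normalised upstream; the
package performs no cross-run normalisation. Missing intensities are a
first-class state and are never imputed. Protein groups are carried as a
single verbatim accession string; where a single accession is needed (PFL
and annotation joins, benchmarking truth), the first accession of the group
is used. How peptides shared between groups should be apportioned is left
open and flagged, not resolved.

## Differential testing

For each positive dose, replicate *i* is paired with vehicle replicate *i*
and the per-peptide statistic is the vector of log₂(treated/vehicle)
ratios. Pairing by replicate index matches block-randomised acquisition,
where replicate order carries shared batch structure; an unpaired variant
(mean-vehicle denominator) is available via `replicate_log2_ratios`'s
caller but index pairing is the default. Pairs with a missing, zero or
negative member are dropped; a peptide with fewer than two surviving pairs
is untestable at that dose.

The test is a one-sample two-sided t-test of mean log₂ ratio = 0 with
n − 1 degrees of freedom. Four-replicate LiP data regularly produce ties,
so the degenerate conventions are explicit: sd = 0 with mean 0 gives p = 1;
sd = 0 with mean ≠ 0 gives the machine-minimum p and a degeneracy flag.

Multiple testing is corrected per dose-vs-vehicle comparison (never pooled
across doses) with Storey q-values using the single-λ estimator,
π₀ = min(1, #{p > λ}/(m(1 − λ))) at λ = 0.5. The single-λ form is preferred
over the smoother for determinism and small-sample robustness; λ is
configurable. q-values are monotone in p and capped at 1.

Candidate filters ship as three presets: `train` (q < 0.01,
|log₂FC| > 0.58), `rank` (q < 0.01, |log₂FC| > 0.46, restricted to doses
within [EC50, 1000 × EC50] of the compound's known EC50, falling back to
the nearest dose when none fall inside, or to all doses when the EC50 is
unknown), and `smap` (single-dose calling, q < 10⁻⁴ and linear fold change
1.5). Both printed fold-change cutoffs are shipped because the training and
automated-ranking stages use different values; the automated pipeline
default is `rank`. A peptide passes if any admitted comparison satisfies
both cutoffs.

## Dose–response model

The 4PL curve is f(x) = lower + (upper − lower)/(1 + (x/ec50)^slope). The
vehicle (x = 0) is included as a fit point at the no-drug asymptote rather
than excluded or given a pseudo-dose: it anchors the baseline with four
replicates. Responses are the per-sample intensities divided by the mean
vehicle intensity of the peptide, and all replicate points are fitted (not
replicate means) so the error structure propagates into R².

Fitting is nonlinear least squares (trust-region reflective) over
(lower, upper, log₁₀ ec50, slope), initialised from the extreme-dose group
means, the dose nearest the half-range crossing, and slope ±1; both slope
signs are attempted and the smaller residual sum kept. The 4PL is invariant
under swapping the asymptotes while negating the slope, so the reported
direction comes from the asymptote values (vehicle asymptote vs
infinite-dose asymptote), not the slope sign. R² is computed against the
pooled mean and clamped to [0, 1]; non-converged fits carry R² = 0. An EC50
outside [min positive dose/100, max dose × 100] — including the bound
itself, where the constrained optimiser parks unbracketable midpoints — is
reported as non-converged: extrapolated midpoints are not interpretable.
The protein-level EC50 is the median of its called peptides' EC50s
(midpoint convention for even counts).

## Scoring

- **c₁** is the 4PL R² (0 when non-converged or unfittable).
- **c₂ = 1 − PFL frequency.** The PFL counts, per protein, the panel
  experiments in which it passed the candidate filter while not being that
  experiment's annotated target; the frequency divides by the panel size,
  repeated experiments counting separately. Proteins never observed as
  non-target hits are absent from the library and look up as frequency 0.
  The linear complement is the simplest monotone map of "less frequent →
  more weight" onto [0, 1].
- **c₃ = min(n, 5)/5**, where n is the number of the protein's candidate
  peptides whose best q ranks in the top 10% of all candidate peptides. The
  denominator of "top ten percent" is the candidate list (not all
  quantified peptides); the cap of 5 makes typical strong multi-peptide
  hits saturate. Both are configurable.
- **c₄ = min(−log₁₀ q*, 10)/10**, where q* is the minimum q over the three
  smallest doses strictly above the compound's known EC50 (the component-IV
  dose set), falling back to the ranking window when the EC50 is unknown.
  The cap of 10 saturates at q* = 10⁻¹⁰.

The combined score is 6 · Σ wₖcₖ with default weights
(0.69, 0.1033, 0.1033, 0.1034): the dose–response correlation carries 69%
and the remainder is split equally with the rounding remainder on w₄, so
the maximum attainable score is exactly 6. Peptides rank descending by
score with a fully deterministic tie-break (smaller q*, then lexicographic
peptide); the protein score is the maximum over its peptides. Calling uses
the strict inequality score > 1.5; `derive_threshold` recomputes the
threshold from control experiments as median(non-target scores) + 3 sample
standard deviations, and promiscuous compounds (e.g. pan-kinase binders)
should be excluded from the control set because their "non-target" labels
are unreliable.

### Weight training

`train_weights_lda` fits a two-class linear discriminant (positives =
peptides of known targets, ≥ 10 required) against 400 freshly resampled
background peptides, five times, and averages the per-repeat weights.
Per-repeat weights are absolute standardized coefficients (|coefficient| ×
pooled within-class sd) normalised to sum 1: raw coefficients would inflate
low-variance noise features through the inverse covariance. Whether to
standardise before averaging was an open choice; standardisation is used
because all components are constructed positively oriented and on [0, 1].
Shrinkage (lsqr, auto) keeps the fit defined when a component is constant.
A run is flagged unstable when any component's per-repeat sd exceeds 0.05
(±5 points of score weight): informative panels measure ≤ ~0.03, while
positives drawn from the background distribution measure 0.05–0.14.

### Benchmarking

PPV is TP/(TP + FP) over the top k = 50 ranked peptides by default (a
peptide is a true positive when its protein is in the truth set); when the
ranking is shorter than k the full list is used, with a warning. ROC/AUC is
tie-aware (rank statistic); the `LiPQuantResults.roc` convenience ranks the
whole quantified proteome, entering filter-missed proteins at score 0 so
they count against sensitivity. External ranked lists can be benchmarked by
supplying (length − rank) as the score.

## Binding-site approximation

Peptides are mapped onto a PDB chain by exact substring match of the bare
sequence (bracketed/parenthesised modification annotations and underscores
stripped, innermost first); zero or multiple matches are errors — the
caller must disambiguate. The top 3 of the protein's peptides among the
proteome-wide top 15 contribute (2 are accepted when only 2 qualify); a
span with under half of its residues resolved is rejected. The center of
mass is mass-weighted over all present atoms (hydrogens included when
present; crystal structures usually lack them, which is accepted). The
neighborhood is every residue with an atom within 4 Å of the COM, and the
reported minimal distance is the minimum over the COM point and the
neighborhood atoms against all ligand atoms — the COM participates because
the reported quantity is the distance between the peptide-derived reference
point (with its surrounding residues) and the ligand. `within_vdw` is
min_distance ≤ 4 Å. The random-peptide null redraws k contiguous spans
(lengths uniform in 7–25, tryptic-like) and applies the same geometry; it
is a documented approximation, not a tryptic digest model. All geometry is
invariant under rigid transforms to numerical tolerance, and residue labels
use author numbering.

## Synthetic data

The generator emulates the dose–response design: responder peptides of
target proteins follow the 4PL model with configurable EC50 (jittered
log-normally around the compound EC50 and clipped to the dosed range),
direction (50/50 unless fixed) and dynamic range; the background is flat.
Every observation is multiplied by lognormal noise with unit mean and a
configured coefficient of variation (MS intensity error is multiplicative
and right-skewed), and observations are then dropped uniformly at random.
Panels share a contaminant pool: a firing contaminant shifts at every dose
with random per-dose sign and magnitude ≥ its configured log₂ shift — a
drug-independent structural responder that passes differential filters but
shows no sigmoidal trend, which is exactly the population the PFL and the
dose–response component exist to suppress.

Defaults, chosen once as a plausible desk-scale proteome: 120 proteins,
Poisson(4) peptides per protein, 5 targets × 4 responders, vehicle + 7
half-log doses from 1 nM to 1 µM, 4 replicates, compound EC50 10 nM,
3-fold responder dynamic range, 10% noise CV, 2% missingness, baselines
log-normal around 10⁶. The end-to-end checks score a panel member against a
PFL built from six sibling experiments, because a run containing recurring
structural responders is the condition the scoring system is designed for.

What the generator does **not** emulate: peptide-level intensity–missingness
coupling (uniform missingness by default; an intensity-dependent variant is
off by default since no missingness model is prescribed), fragment-level
quantification, retention-time structure, search-engine effects,
between-replicate correlation (so index pairing confers no advantage on
synthetic data), and realistic peptide/intensity distributions. Passing
tests therefore demonstrate the machinery's correctness and its behaviour
under controlled noise, not performance on real DIA output.

## Problem sizes and numerical conventions

The shipped tests run the recovery property at 100 responder peptides and
the end-to-end screen at 10 simulation seeds with 7-experiment panels of
~480-peptide proteomes — sizes chosen to exercise every pipeline stage at
desk scale. Statistical oracles in the tests are independent computations
(incomplete-beta t CDF; loop-form Storey formula) rather than second calls
into the implementation. Floating-point conventions: q-value/score
comparisons at 10⁻⁹, geometry at 10⁻⁶ Å, strict inequalities at thresholds
(score > 1.5, p-side filters q < 0.01).

## Known limitations

- With four replicates the t-test has 3 degrees of freedom; genuine
  responders with modest dynamic range can sit just above q = 0.01 in
  signal-poor runs. The upstream fragment-level testing of commercial DIA
  software is more powerful than peptide-level testing on the same design.
- EC50s are point estimates; no confidence intervals are provided.
- The 0.58 vs 0.46 fold-change presets reflect two pipeline stages of the
  original design; whether the discrepancy is intentional is unknown, so
  both are shipped and the ranking stage uses 0.46.
- Binding-site estimates require an exact sequence match to the deposited
  chain; mutations, conflicts or engineered constructs need caller-side
  renumbering.
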