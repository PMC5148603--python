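# Methods

`hdxpulse` analyzes pulse-labeled hydrogen–deuterium exchange mass
spectrometry (HDX-MS) of protein unfolding.  Because no raw spectra are
distributed with the package, every analysis stage is exercised against a
synthetic-data generator whose parameters define the ground truth; the
pipelines must recover those parameters through their own measurement
chain.  This note describes the models, the defaults and their rationale,
the numerical choices, and what the synthetic round trips do and do not
demonstrate about real data.

## Isotope envelopes

Envelopes are stick spectra in neutral-mass space.  The natural isotopic
distribution of a composition is computed by convolving per-element
isotope distributions in nominal-mass bins, each bin carrying the
abundance-weighted mean mass of its isotopologues; this is exact in
abundance (verified against brute-force isotopologue enumeration to
1e-9) and accurate in mass to well below the ~1 Da questions the package
asks.  Isotope masses and abundances are pinned constants
(`hdxpulse.constants`); the H→D mass difference is 1.00628 Da and the
proton mass 1.00728 Da.

Deuteration convolves an envelope with Binomial(n, p): all `n`
exchangeable backbone amides (residues minus the N-terminus minus
non-terminal prolines) incorporate deuterium independently with a single
probability `p`, capped by the D2O fraction of the labeling buffer (0.70
by default).  No per-site rate spectrum, side-chain hydrogens, or
back-exchange is modeled; the package quantifies fraction-unfolded and
relative-uptake readouts that are referenced to their own controls, for
which this coarse model is sufficient.  Fine-structure peaks within one
nominal bin are merged into abundance-weighted sticks (0.3 Da tolerance);
merging preserves total abundance and centroids exactly.  Mixtures of two
envelopes merge cross-envelope peaks at a tolerance capped by half the
smallest intra-envelope stick gap, so mixing can never collapse structure
that either input resolves.

The diagnostic hydrolase-domain peptide (residues 131–165 of the lipase
substrate) has no published sequence; its stand-in is an averagine
composition at 3800 Da with 31 exchangeable amides.  Only envelope
geometry (width, centroid separation), not chemical identity, enters the
fraction-recovery problem; all values are configurable.

## Synthetic data

Two preset families define the study conditions:

* **Empirical presets** pin the generating unfolded fraction to a printed
  study value (spontaneous 7.0% at 5 min and 29% at 30 min; 60.3% with
  1 µM inhibitor at 5 min; 87% with 2 µM at 10 min; 8% with the
  full-length protectant, 79% and 69% with its separate domains; 74% with
  0.25 µM at 30 min against a 28.6% control).  They bypass the kinetic
  model because the two spontaneous fractions are not mutually consistent
  under a single first-order rate.
* **Kinetic presets** generate time courses from a two-state model,
  `u(t) = 1 − exp(−(k_spont·t + k_cat_eff·g(t)))`, with
  `k_cat_eff = efficacy × [inhibitor]/[substrate]` and
  `g(t) = (1 − e^(−k_decay·t))/k_decay` (or `t` for a stable inhibitor).
  The wild-type-like preset uses efficacy 1.6 min⁻¹ and
  `k_spont = 0.0114 min⁻¹`, calibrated so the spontaneous curve passes
  through 29% at 30 min.  The E15K-like preset uses efficacy 0.6 min⁻¹
  and a first-order inhibitor-activity decay `k_decay = 0.05 min⁻¹`,
  chosen so progress curves visibly flatten over tens of minutes; the
  functional form of the decay is a modeling choice, not a measured fact.

Pulse labeling snapshots the population: the folded state is partially
exchanged at `p_folded = 0.25` per amide (≈14 Da centroid separation from
the unfolded state; the study gives no number for the folded-state
incorporation, so this is a declared assumption) and the unfolded state
exchanges at the full 0.70 D2O fraction.  Noise is per-peak multiplicative
Gaussian (CV 3%) plus an additive baseline (SD 0.5% of the tallest
stick), with negative intensities clipped to zero — a minimal model
adequate for recovery testing, not an instrument calibration.  Replicates
default to 3.  Every spectrum's random stream derives from
(seed, preset name, time index, replicate), making all outputs
bit-reproducible.

Continuous labeling mixes a closed state exchanging by EX2 kinetics slowed
by a protection factor, `p_closed(t) = d2o·(1 − exp(−k_int·t/PF))` with
`k_int = 1 s⁻¹`, with a cooperatively opened, fully exchanged state of
weight `w(t) = 1 − exp(−k_open·t)`.  The bundled 159-residue inhibitor
presets tile the sequence with 12-residue peptides: the destabilized
N-terminal helix (residues 19–43) gets PF 2000 with `k_open` 5×10⁻⁴ s⁻¹
(wild-type-like) or 5×10⁻³ s⁻¹ (E15K-like, the only parameter that
differs), the second helix (85–111) PF 5000 with `k_open` 10⁻⁴ s⁻¹, and
loops PF 10 with no cooperative opening.

## Deconvolution

The unfolded fraction is the area share of the high-mass component in a
constrained two-Gaussian least-squares fit of the stick intensities
(`scipy.optimize.least_squares`, trust-region reflective).  Constraints:

* component centroids within ±3 Da of the folded/unfolded reference
  centroids (taken from noiseless t=0 and full-deuteration envelopes);
* component widths within a band derived from the references
  (0.9×/1.1× of their fitted unimodal widths; a fixed band is available
  via configuration).  The width band matters: the folded mode is
  right-skewed (binomial p = 0.25), and with a generous width bound the
  high-mass component drifts wide and low to absorb that tail,
  inflating small fractions by up to ~3 percentage points.  With
  reference-derived bounds the residual bias of the whole chain is
  within ±1 point at 2–10% unfolded and within ±0.5 point above 20%.
* amplitudes nonnegative; widths fit independently (the two states need
  not share a width).

Model selection fits one and two Gaussians and accepts bimodality iff
`BIC_unimodal − BIC_bimodal ≥ 6` (a strong-evidence convention).  An
accepted unimodal fit is assigned fraction 0 or 1 when its centroid lies
within 20% of the folded→unfolded span of the corresponding reference;
anything in between is flagged ambiguous and reported as NaN — flagged,
never imputed.  Consequences worth knowing: generating fractions below
~2–3% are usually classified unimodal and read as 0 (a detection floor),
and the residual Gaussian-vs-binomial mismatch means the zero-noise chain
is exact only to ~0.5 point at mid-range fractions and ~1 point below 10%.
Intensities are rescaled to unit maximum before fitting, so every result
is invariant to the overall intensity scale.

## Kinetics

Replicate fractions are aggregated to mean ± SD per time point (single
replicates report SD as missing, not 0).  The spontaneous (inhibitor-free)
course is subtracted pointwise, with SDs combined in quadrature and
negative differences clipped at zero and flagged.  Initial rates are
ordinary least squares through the origin on (time, corrected fraction) —
through the origin because catalyzed unfolding is zero at t=0 after
background subtraction.  Points whose corrected fraction exceeds the
depletion cutoff (default 0.30, the operationalization of "substantial
substrate depletion") are excluded with machine-readable reasons, as are
points beyond the linear-phase cap (default 10 min) when an
inhibitor-decay variant is analyzed.  Fewer than two usable points
withholds the estimate rather than extrapolating.  The catalytic
unfolding efficacy is the slope of molar rate (µM/min, = fraction rate ×
substrate concentration) against inhibitor concentration (µM); both
free-intercept and through-origin regressions are computed
(`statsmodels` OLS) and the free-intercept slope is primary, since the
regression form used in the original analysis is not stated.

The acceptance pipelines simulate triplicate courses at 1.0/0.5/0.25 µM
(wild-type-like) or 2.0/1.0/0.5 µM (E15K-like) inhibitor with a parallel
spontaneous control, on the time grid (0.5, 0.625, 0.75, 0.875, 1.0) min.
The grid samples only the early phase — by design, since the efficacy is
defined by initial rates where substrate depletion is negligible.  Two
properties of this design were chosen from the closed-form model before
simulation: every concentration keeps the through-origin fit in its
near-linear regime (corrected fractions ≤ 0.15), and the
spontaneous-subtraction bias (the control sits below the bimodality
detection floor at these times) is identical across concentrations, so
the free-intercept regression absorbs it.  Sampling deep into the
depletion regime instead makes the recovered slope depend strongly on
which points cross the cutoff.  The depletion cutoff and linear-phase cap
remain active as guards.

A global weighted nonlinear fit of the two-state model across conditions
(`fit_kinetic_model`) is provided as an alternative to the piecewise
linear analysis; it recovers generating parameters within 10% at default
noise and prefers (by AIC) the inhibitor-decay model on E15K-like data.

## Uptake analytics

Deuterium uptake is the centroid shift from the undeuterated envelope;
sticks below 1% of the tallest stick are excluded from the centroid, the
standard centroiding safeguard (near-baseline sticks at a long mass lever
arm would otherwise dominate the centroid variance).  Relative uptake
divides by a fully exchanged control (theoretical
`n_exchangeable × d2o × 1.00628` for synthetic data); values above 1 are
flagged, not clipped.  Heat maps project peptide values onto residues by
unweighted mean of covering peptides (shortest-peptide priority is an
option); uncovered residues are missing, never 0.  Butterfly differences
(variant − reference, per peptide and time) are called significant beyond
the largest replicate SD in the compared datasets, used symmetrically
about zero — the original study's rule, not a formal multiple-testing
procedure (a Welch test could be added, but is deliberately not the
default).  The EX1 diagnostic is the envelope's second central moment over
time: a mixture obeys `σ² + w(1−w)d²`, so cooperative opening inflates
the width at intermediate opened fractions; a series is called
"EX1-containing" when the maximum variance exceeds the earliest variance
by a factor (default 2).  This heuristic can fire on pure-EX2 series whose
incorporation probability crosses ~0.5 (where binomial variance peaks) —
a known limitation; it is reliable when the earliest time point is either
well below or near saturation, as in the bundled presets.

## What the round trips show — and what they do not

Passing recovery tests show that the measurement chain (envelope
synthesis → noise → two-Gaussian deconvolution → kinetics) is unbiased to
within the study's own uncertainties *under the generator's assumptions*:
well-separated two-state envelopes, uniform per-amide incorporation,
uncorrelated per-peak noise, no back-exchange, no chromatographic or
charge-state artifacts, and exactly two populations.  They do not
validate peptide identification, retention alignment, vendor-format
processing, or deconvolution of more than two coexisting states — all out
of scope.

## Numerical choices and degenerate inputs

* Envelope truncation: peaks below 1e-5 of the maximum are dropped and
  the envelope renormalized.
* Fits require ≥4 sticks above 1% of the maximum; degenerate
  single-stick envelopes pin the width at its lower bound and are
  flagged.
* Non-convergence is flagged with the fraction reported missing.
* BIC uses an RSS floor of 1e-12 to avoid log(0) on exact fits.
* Time courses require strictly increasing times; mismatched grids in
  spontaneous subtraction are an error unless interpolation is requested.
* Seeds: every stochastic entry point requires an explicit integer seed;
  per-spectrum streams derive from `SeedSequence([seed, crc32(preset),
  time index, replicate])`.

## Problem sizes

The shipped test suite and the acceptance script use 50 replicates per
fraction-recovery condition, triplicate kinetic courses at three
concentrations plus control on five early time points, and 20 tiled
peptides × 3 labeling times × 3 replicates for the continuous-labeling
comparisons.  The full suite runs in well under a minute on one CPU.
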