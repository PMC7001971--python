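# Methods

## Förster theory

The overlap integral is computed as J = ∫ f̄_D(λ) ε_A(λ) λ⁴ dλ with the
donor emission spectrum area-normalized over its tabulated range
(∫ f̄_D dλ = 1, no extrapolation) and the acceptor absorption spectrum
scaled so its peak equals the acceptor's molar extinction coefficient —
the standard convention, since extinction coefficients are quoted at the
absorption maximum.  Both curves are linearly interpolated onto the
union of their wavelength grids restricted to the overlapping range and
integrated by the trapezoidal rule; protein spectra are smooth and
typically tabulated at 1 nm, where the trapezoid's O(h²) error is a few
parts in 10⁶.  Disjoint supports return J = 0 with a warning rather
than an error, since zero overlap is a physically meaningful answer.

The Förster radius uses R₀⁶ = 8.79×10⁻⁵ · κ² · n⁻⁴ · QY_D · J with J in
M⁻¹cm⁻¹nm⁴ and R₀ in Å.  This prefactor bundles 9000 ln10 / (128 π⁵ N_A)
with the unit conversions; with κ² = 0.6667 (freely rotating dipoles),
n = 1.33 and QY_D = 0.8 it reproduces all four published radius values
for the mNeonGreen pairs (64, 61, 57, 61 Å) at the printed precision,
which is the package's self-consistency check on the constant.

## Spectral unmixing and sensitized-emission efficiency

A mixed emission scan y(λ) at donor-only excitation is decomposed as
y ≈ W_D·f̄_D + W_A·f̄_A (+ optional constant baseline) with references
area-normalized and interpolated to the scan grid.  Weights are
constrained non-negative (they represent photon counts; scipy's NNLS /
bounded least squares).  References whose unit-scaled design matrix has
condition number above 10⁸ are rejected as collinear.  Efficiency is
E = 100·W_A / (W_A + W_D·QY_A/QY_D), i.e. each emission weight is
converted back to excitation events through its quantum yield and E is
the acceptor's share.  An alternative literal reading
E = 100·W_A·(QY_A/QY_D)/(W_D + W_A) is available behind
`convention="literal"` for comparison; the sensitized-emission form is
the physically consistent one (it is exactly inverted by the forward
model and maps W_A = 0 → 0, W_D = 0 → 100%).  Direct acceptor
excitation at the donor excitation wavelength is *not* subtracted —
the efficiency formula has no such term — but the scan generator can
inject it, and `analysis/02_spectral_fret.py` quantifies the resulting
upward bias (≈6.5 points at a 10% direct-excitation component on a
true 29%).

## TCSPC tail fitting

Decays are fit with m(t) = Σᵢ aᵢ exp(−t/τᵢ) + c by weighted least
squares with Neyman weights σ² = max(counts, 1) — standard TCSPC
practice, well-behaved for empty bins.  Tail mode: the default window
runs from two bins past the peak (discarding the rising edge, so no
instrument-response deconvolution is needed) to the last occupied bin;
windows shorter than 3× the parameter count are rejected.  Initial
values come from a count-weighted log-linear regression of the tail
(split in half for the biexponential: late half → slow component,
early half → fast), with the offset initialized to the mean of the last
5% of bins.  The Levenberg–Marquardt minimizer (lmfit) runs with tight
tolerances (1e-12) so noiseless model data is recovered to ≲1e-6 ns;
non-convergence flags the result instead of raising.  Model selection
accepts a second component only when it lowers reduced χ² by more than
20% (relative); reduced χ² ≤ 1.5 marks a fit as "well described".

Known numerical property: Neyman weighting couples the weights to the
noise, biasing τ̂ low at small photon budgets (≈−0.5% at 10⁵ photons,
≈−0.1% at 10⁶, but several percent below ~10⁴ photons over 256 bins).
ROI-level fits aggregate enough photons that this is negligible;
per-pixel lifetime maps need generous per-pixel budgets (the map tests
use ≥2×10⁴ photons/pixel) and should be read as qualitative below that.

Histogram geometry defaults to 256 bins over 12.5 ns — one period of an
80 MHz pulsed Ti:Sapphire source — and is configurable throughout.

FLIM-FRET efficiency is E = 100·(1 − τ_DA/τ_D).  Negative values
(τ_DA > τ_D) are reported, not clipped, so donor-reference variability
stays visible; the donor-only τ_D is a user-supplied convention (pooled
vs day-matched donor controls give slightly different printed
efficiencies, which is why efficiencies are not always recomputable
from rounded lifetimes alone).

## Per-cell slope heterogeneity

For each segmented cell, red pixel intensity is regressed on green by
ordinary least squares after scalar background subtraction (median of
all off-mask pixels per channel, or the 5th percentile when no masks
exist; negatives clip to zero).  Red is the response because the
diagnostic phenotype is "green signal present, red absent" — a slope
near zero.  OLS rather than total least squares because only the
relative, condition-matched comparison of slopes carries meaning, not
the absolute ratio.  Cells need ≥50 pixels by default to stabilize the
slope.  Segmentation is a deterministic connected-components surrogate
(threshold on green+red, minimum area) standing in for hand-drawn ROIs;
external label masks are always accepted.  Histograms default to
Freedman–Diaconis binning, overridable with explicit edges.

## Maturation mixture model

Maturation follows first-order kinetics, f(t) = 1 − 2^(−t/t_half) —
half-times are the only published kinetic quantity, and a single
rate constant is the simplest model consistent with them.  A population
at mature fraction f emits an amplitude-weighted donor-decay mixture
(1−f, f) on (τ_D, τ_DA = τ_D(1−E_true)): amplitude weighting because
each tandem molecule carries exactly one donor, and dark acceptors are
taken as fully non-absorbing.  The apparent efficiency at f is obtained
by building the mixture decay (noiseless expectation by default, or a
seeded Poisson realization), fitting a single exponential in tail mode
— the standard FLIM protocol — and applying the lifetime-ratio formula.
E_app rises continuously and monotonically from 0 at f = 0 to E_true at
f = 1 and always lies at or below f·E_true·100 up to fitting tolerance:
a monoexponential fit of the mixture is pulled toward the long
donor-only component, so a partially dark acceptor dilutes the signal.

The fully-mature tandem efficiency defaults to E_true = 0.27 with
τ_D = 3.05 ns — the plateau that fast-maturing acceptors reach —
so named scenarios ("NG-mRuby3" etc., via `tandem_scenario`) configure
realistic simulations directly from the bundled fluorophore constants.
Note that the published *in vitro* half-times (136.5 min for mRuby3)
would complete maturation within a day; a FRET rise that continues over
several days implies a much slower effective in-cell rate (the
time-course driver uses 2 days to emulate that shape) and/or dark
states beyond slow maturation, which are deliberately not modelled.

## Permutation statistics

Two-sample tests permute group labels on the pooled sample.  Below 10
pooled observations every C(n_a+n_b, n_a) assignment is enumerated and
p = k/K exactly; otherwise the permutation distribution is sampled
(default 10⁶ draws, seeded, chunked argsort of uniform variates) with
the +1 correction p = (#extreme + 1)/(n_perm + 1) so p is never zero.
The statistic defaults to the difference of group means (difference of
medians available), two-sided throughout; ties are compared with a
relative tolerance of 1e-12 so exact ties are not lost to floating
point.  Calibration: at n = 12 per group the Monte Carlo test's type-I
error at α = 0.05 stays inside [0.04, 0.06] over 10⁴ null replicates
(1999 draws per replicate in that battery, which preserves the nominal
level while keeping the battery fast).

## Synthetic data: what it emulates, and what it does not

Generators are seeded (`numpy.random.default_rng`) and bit-reproducible;
every generator returns a truth table sufficient to score the
downstream estimate, and every noiseless limit is exactly inverted by
the corresponding analysis stage — that is the package's core
correctness argument.

- **Spectra** are skew-normal bands on a 1 nm grid with the mode pinned
  to the requested peak — smooth, unimodal stand-ins for protein
  spectra, not measured curves; absolute overlap integrals from them
  depend on the assumed bandwidths.
- **Emission scans** follow the sensitized-emission forward model with
  optional Gaussian noise and an optional direct-excitation term.
- **TCSPC decays** place a photon budget multinomially over closed-form
  exponential bin integrals (plus optional uniform background); there
  is no instrument response function, pile-up, or afterpulsing, which
  is consistent with tail-only fitting.
- **FLIM stacks** are non-overlapping elliptical cells of Poisson
  per-pixel decays on dark background; no optics (PSF), no bleed-through.
- **Two-channel images** give each cell a shared log-normal expression
  texture (σ = 0.4) so the red/green ratio — the true slope — is
  constant within a cell, plus constant background and Poisson shot
  noise.  Cell-to-cell mature fractions draw from Beta distributions
  around the kinetic mean (concentration 30 by default), which captures
  the observed heterogeneity without asserting its mechanism.
- **Cohort time series** apply the first-order kinetics per day with
  per-cell Beta jitter.

Passing tests on these data demonstrate that the analysis chain inverts
its own forward models at realistic photon budgets and noise levels;
they cannot certify behaviour under instrument effects the generators
omit (IRF, bleed-through, photochromism, saturation).

## Problem sizes

Default simulated fields are tens of pixels across with 8–40 cells and
photon budgets of 2×10³–2×10⁴ per pixel (10⁵–10⁶ per ROI) — enough for
the fit biases quoted above while keeping every driver and the full
test battery fast on a single core.  All sizes are parameters.

## Known limitations

- No IRF deconvolution, phasor analysis, or pile-up correction.
- Per-pixel lifetime maps inherit the low-count Neyman bias (above).
- The heterogeneity surrogate segmentation is intensity-threshold based
  and will merge touching cells; external masks are the remedy.
- κ² is a single number, not a distribution; refractive index is
  wavelength-independent.
- Maturation is two-state (dark → mature); photochromic or reversible
  dark states are out of scope.
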