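# fretkit

Analysis toolkit for characterizing Green/Red FRET pairs built from
fluorescent proteins — specifically an mNeonGreen donor paired with the
red acceptors mRuby3, mScarlet-I, mCherry and mScarlet.  The package
implements the full measurement chain used in such a characterization:

- **Förster theory** — spectral overlap integral
  J = ∫ f̄_D(λ) ε_A(λ) λ⁴ dλ and Förster radius
  R₀ = (8.79×10⁻⁵ κ² n⁻⁴ QY_D J)^(1/6) Å;
- **spectral (intensiometric) FRET** — non-negative linear unmixing of a
  mixed emission scan into donor/acceptor reference components, with
  sensitized-emission efficiency
  E = W_A / (W_A + W_D·QY_A/QY_D) × 100%;
- **FLIM-FRET** — Poisson-weighted tail fitting of TCSPC decay
  histograms (mono- or biexponential plus offset), per-pixel lifetime
  maps, and the lifetime-ratio efficiency E = (1 − τ_DA/τ_D) × 100%;
- **expression heterogeneity** — per-cell OLS regression of red on
  green pixel intensities; dark (immature) acceptors give slopes near 0,
  and slope histograms across a field quantify construct heterogeneity;
- **maturation modelling** — first-order chromophore maturation
  f(t) = 1 − 2^(−t/t_half) feeding a dark/mature donor-decay mixture,
  predicting the apparent (monoexponential-fit) efficiency at any mature
  fraction;
- **statistics** — two-sample permutation tests with exact enumeration
  below 10 pooled observations and seeded Monte Carlo (default 10⁶
  draws) above;
- **synthetic data** — seeded generators for every input modality
  (spectra, emission scans, TCSPC histograms, FLIM photon cubes,
  two-channel confocal images, multi-day cohorts), each returning a
  ground-truth table, standing in for the spectrometer and microscope.

## Layout

The analysis itself lives in numbered drivers under `analysis/`
(Förster radii, spectral FRET, FLIM-FRET, slope heterogeneity,
maturation time course), each a thin script over the library in
`src/fretkit/` that prints what it found and writes its tables under
`results/`.  A `fretkit` CLI exposes the individual operations
(`fretkit forster`, `unmix`, `efficiency`, `fit-flim`, `lifetime-map`,
`stats`, `maturation`, `run`).

## Worked example

```python
>>> from fretkit import ForsterContext, forster_radius, flim_fret_efficiency
>>> forster_radius(4.65e15, 0.8, ForsterContext(0.6667, 1.33))
64.14694102950627
>>> flim_fret_efficiency(2.22, 3.05)
27.213114754098356
>>> flim_fret_efficiency(2.92, 3.05)
4.2622950819672045
```

The first number is the Förster radius (Å) of the mNeonGreen/mRuby3
pair from its overlap integral of 4.65×10¹⁵ M⁻¹cm⁻¹nm⁴ — about 64 Å,
the largest of the three pairs, which is why mRuby3 is *predicted* to be
the best acceptor.  The second and third numbers are lifetime-ratio
efficiencies: a donor lifetime dropping from 3.05 ns to 2.22 ns
corresponds to 27% FRET (the fast-maturing acceptors), while a drop to
only 2.92 ns is 4% (the mRuby3 tandem one day post transfection) — the
measured ordering is the reverse of the spectral prediction, and the
maturation model in `analysis/05_maturation_timecourse.py` shows why: a
mostly-immature (dark) acceptor population dilutes the donor decay with
the unquenched lifetime.

Running `python analysis/03_flim_fret.py` simulates one field per
construct and prints the recovered group means (~0% donor-only, ~27%
for the mScarlet-I and mCherry tandems, single-digit efficiency for the
mostly-dark mRuby3-like group) together with permutation p-values for
every group pair.

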