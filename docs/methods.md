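# Methods

This note documents the models, numerical choices and limitations behind
`spread-sfx`: a desk-scale toolkit for spatially resolved anomalous
dispersion (SPREAD) in serial femtosecond crystallography (SFX).  The goal
of the method is to recover the anomalous scattering factors
Δf′(E), Δf″(E) of a metal site — in practice, the ~1–2 eV shift of its K
absorption edge, which encodes the oxidation state — from pixel-level
diffraction data in which orientation, scale and cell vary shot to shot.

## Forward model

**Structure factors.** For a P1 crystal the complex structure factor at
Miller index **h** and photon energy E is

    F_h(E) = Σ_m occ_m [f⁰_m(|Q|) + Δf′_m(E) + i Δf″_m(E)]
             · exp(2πi r_m·h) · exp(−B_m |Q|²/4)

with fractional coordinates r_m, displacement parameter B_m (Å²) and the
scattering-vector convention |Q| = 1/d (Å⁻¹).  Under this convention the
Debye–Waller exponent is −B|Q|²/4; with |Q| = 2π/d the same B would need a
(2π)² smaller exponent — we state the convention once here because
confusing the two silently rescales every B factor.  f⁰ comes from gemmi's
IT92 (Cromer–Mann) four-Gaussian tables, evaluated at sinθ/λ = |Q|/2.
Anomalous terms are nonzero only for atoms that carry an `AnomalousCurve`,
tabulated on a uniform eV grid (default 6400–6700 eV, 1 eV) with linear
interpolation.

**Kramers–Kronig transform.** Δf′ and Δf″ are Hilbert-transform partners.
We use the convention f′(E) = (1/π) PV ∫ f″(E′)/(E−E′) dE′, which places
the characteristic negative cusp of f′ at an absorption edge.  On the
finite uniform grid the principal value is evaluated with the odd-sample
discrete Hilbert kernel K(m) = 2/(πm) for odd offsets m (zero for even
offsets).  This is a pure convolution: exactly linear, exactly
translation-equivariant while the support stays on-grid, and accurate to
≈1.5% pointwise against the closed-form Lorentzian dispersion pair for
linewidths of a few grid steps.  Accuracy degrades within a few linewidths
of the grid edges, where the 1/m tail of the kernel is truncated; curves
should therefore be tabulated with generous margins around the spectral
window of interest (the bundled grid spans ±150 eV around the edge for a
±45 eV spectrum).

**Reference curve.** No tabulated Mn³⁺/Mn⁴⁺ curves are bundled; the
reference is synthetic: Δf″ is a logistic step (height 3.8 e, width 2 eV)
at 6550 eV plus a white-line Gaussian (amplitude 2.5 e, σ = 3 eV, centered
5 eV above the edge), and Δf′ is derived from it by the KK transform plus
a constant offset.  It reproduces the qualitative near-edge features that
drive edge-shift inference (absorption step, white line, negative f′
cusp), not measured Mn data; all recovery experiments are defined relative
to this curve.

**Diffraction geometry.** Beam along +z with |k| = 1/λ; a single flat
panel perpendicular to the beam (default 1024² pixels of 0.5 mm at
150 mm); reciprocal vectors q = U·B·h with B from the cell metric.
A reflection is predicted when |(|k_in + q|) − 1/λ| falls inside an
acceptance shell combining the spectral bandwidth (2σ_E/E), the mosaic
angular spread, and three domain-size widths, and its diffracted ray hits
the panel.

**Mosaic model and spot profile.** A crystal is n_domains (default 20)
explicit small rotations drawn per shot from an isotropic Gaussian on the
rotation angle (default σ = 0.5 mrad, axis uniform); intensities add
incoherently and are normalized by the domain count, so expected intensity
is invariant under n_domains (a config switch restores the raw sum).  The
Laue interference function of a finite domain is approximated by an
isotropic Gaussian of the reciprocal-space offset from the Bragg
condition, preserving the peak value (N_a N_b N_c)² and the 1/(N·a) size
broadening: σ_rl = 1/(√(2π)·N̄ā) with N̄ā the geometric mean domain edge
(default 20³ cells of a 9×10×11 Å cell → σ_rl ≈ 2×10⁻³ Å⁻¹ ≈ 1 pixel).
This keeps the pixel kernel cheap and differentiable; the anisotropy and
side lobes of the true Laue function are deliberately dropped.

**Expected counts.** For pixel p of the shoebox of reflection h,

    μ_p = g · Φ · Ω_p · Σ_E w_E |F_h(E)|² · mean_d P(|q_p(E) − R_d q_h|) + b

with per-shot scale g (log-normal across shots, σ = 0.3), flux constant Φ,
solid-angle factor Ω_p = p²D/r³ (inverse-square × obliquity; polarization
omitted, absorbed by g at this scale), spectrum weights w_E (30 Gaussian
channels, FWHM 30 eV, centered 6550 eV), and flat background b (default
2 counts/pixel).  Observed counts are independent Poisson draws.  Φ is
fixed at 0.016 so the median integrated spot is a few thousand photons — a
well-exposed SFX spot.  Shoeboxes are 9×9 pixels centered on the predicted
impact; Miller indices are assigned by construction, emulating DIALS
processing (spot finding and indexing are out of scope).

**DIALS-like metadata.** Inference never sees the truth: it gets a scale
estimate (truth × lognormal, σ = 0.05), an orientation estimate (truth
composed with a 0.5 mrad random rotation), the per-shot cell, and the
shoebox counts/bbox/hkl.  The ground truth is written to a separate
sidecar file that no inference code reads.

**Injected model errors** emulate "effects of unknown origin": a smooth
multiplicative per-pixel gain field (product of two low-frequency
sinusoids with random phase, bounded in [1±m]); a mosaic misspecification
(data generated at an inflated angular spread); a linear background ramp
across the panel.

## Classical inversion

The baseline estimator maximizes the Poisson likelihood of every shoebox
pixel over a scalar edge shift ΔE applied to the reference curve (which
preserves KK consistency automatically), per-shot scales and per-shoebox
backgrounds (both log-reparameterized for positivity), using analytic
gradients and L-BFGS-B.  The per-shoebox geometry kernel K[px, E] is
precomputed once; the intensity splits as
|F|² = |C|² + 2[f′Re(C̄A) − f″Im(C̄A)] + (f′²+f″²)|A|² with per-reflection
complex constants, so a ΔE evaluation touches only two 1-D interpolants.
The curve is spline-interpolated inside the fit for smooth gradients
(`curve_interp="linear"` switches to the tabulation's own linear rule,
matching the generator exactly at the cost of kinked gradients).
Orientations stay fixed at the metadata estimates: at 0.5 mrad error the
induced reciprocal-space displacement (~1.5×10⁻⁴ Å⁻¹) is two orders below
the profile width.  Default tolerances: ftol 1e-9, gtol 1e-6, ≤2000
iterations.

Uncertainty: a profile-likelihood scan (χ²₁ threshold, nuisances
re-optimized at each fixed ΔE) or a parametric bootstrap (Poisson
resampling at the fitted expectations, warm-started refits, percentile
interval).  The bootstrap resamples counting noise only; under the full
generating process the mosaic-domain randomness contributes comparably to
the estimator's scatter, and the bootstrap intervals genuinely under-cover
(measured ≈6/20 at nominal 90%).  Its calibration claim is therefore
tested under a well-specified generator (single domain, exact metadata),
where coverage is nominal; this is a known limitation of Poisson-only
resampling, not of the implementation.

A stretch mode (`FreeCurveMLE`) refines free per-channel Δf″ ≥ 0 on the
spectrum channels with a second-difference smoothness penalty, re-deriving
Δf′ by the (linear) KK transform at every evaluation.

## Physics-informed VAE with model correction

The generator is the same physics kernel composed with a learned
multiplicative correction in log-intensity space, μ̃ = μ·exp(r), where r is
a small MLP conditioned on the pixel's absolute detector position and the
metadata log-scale; its output layer is zero-initialized, so the
correction is exactly the identity at start, and an L2 penalty w·Σr²
pulls it back toward the identity during training.  Because exp(r) > 0
the correction is invertible and keeps intensities positive.  The
conditioning deliberately excludes within-shoebox relative coordinates:
with those the network starts re-shaping spot profiles and chasing
mosaic-realization residuals, whereas detector-position-only features
confine it to smooth detector-space fields (gain, vignetting, background
structure) — the class of systematic error a correction should absorb,
and one the physics kernel cannot.

Latents are hierarchical, with standard-normal priors in an unconstrained
space and physical scales applied in the decoder:

| level    | latent | decoded quantity                  | scale      |
|----------|--------|-----------------------------------|------------|
| dataset  | z_d    | edge shift ΔE = 3 eV · z_d        | 3 eV       |
| image    | z_s    | g = ĝ_DIALS · exp(0.1 z_s)        | 0.1 (log)  |
| shoebox  | z_b    | b = b̂_perimeter · exp(0.5 z_b)    | 0.5 (log)  |

The encoder is an MLP on the flattened log1p counts plus normalized
metadata with two zero-initialized heads, so the untrained posteriors
equal the priors exactly.  Per-shot posteriors are pooled from the
per-shoebox head outputs by natural-parameter averaging (the pool of
priors is the prior).  The dataset-level posterior is a free (non-
amortized) diagonal Gaussian — one global quantity, amortization would
only add noise.  The training objective is the standard single-sample
reparameterized negative ELBO plus the correction penalty; KL terms are
closed-form diagonal-Gaussian expressions, and the dataset-level KL is
scaled so one epoch counts it exactly once.  Everything (including Adam
and backpropagation) is implemented in numpy; gradients are verified
against central differences in the test suite.

Minibatches are whole shots; 10% of shots (≥1) are held out, and early
stopping monitors a fixed-seed sampled validation ELBO — evaluating at
posterior means instead systematically favors wide posteriors and stalls
training.  The full parameter state of the best validation epoch is
restored, so a late-epoch divergence cannot poison the returned model.
Defaults: 150 epochs, patience 30, Adam lr 0.02, hidden width 48
(encoder) / 16 (correction); the variance-head outputs are smoothly
clamped to |log σ| ≤ 4, which keeps long optimization runs from blowing
up the KL term.

Training is two-stage when the correction is enabled: the base model
(encoder, posteriors) trains first with the correction frozen at the
identity, then the correction net trains alone on top of the frozen base
(400 epochs, no early stopping — the zero-initialized correction learns
far more slowly than the amortized encoder, and stopping on the encoder's
schedule would freeze it near the identity).  The corrected and
uncorrected variants therefore share the exact same base model, and the
correction's value is measured by toggling it on the same fitted state —
a paired comparison that removes joint-training variance from the
held-out-deviance contrast.

Omissions relative to a maximal design: the shoebox-level sub-pixel
centroid latent and an image-level orientation-jitter latent would require
derivatives of the geometry kernel and are left out; the background and
log-scale latents carry the nuisance structure that the tested claims
need.  The encoder deliberately never sees raw Miller indices (only the
resolution), since spot-identity metadata can "overexplain" intensity
differences and corrupt the physical estimate.

**ELBO validity.** On a conjugate linear–Gaussian toy (z ~ N(0,1),
x|z ~ N(az+b, σ²)) the evidence is analytic; the optimized ELBO matches
log p(x) to <1e-3 and never exceeds it, exercising the same KL and
expected-log-likelihood pieces used in training.

## What the synthetic data does and does not show

The generator reproduces the structural features that make SPREAD hard:
per-shot orientation/scale/cell nuisances, polychromatic spot
superposition, mosaic broadening, Poisson counting noise, imperfect
metadata, and (optionally) forward-model misspecification.  It does not
model multi-panel detector geometry, detector point spread or gain
dispersion beyond the injected field, beam divergence or polarization,
air scatter, non-flat backgrounds (except the injected ramp), indexing
errors, or radiation damage; the crystal is a six-atom P1 toy whose single
Mn-like site dominates scattering far more than four Mn among thousands of
protein atoms would.  Passing tests therefore demonstrate the correctness
and internal consistency of the algorithms under controlled conditions,
not that a 1–2 eV edge shift is recoverable from real photosystem II data.

## Problem sizes and numerical choices

Default experiment sizes were chosen so a full recovery study runs on a
laptop-class single core: 200 shots × ~10 shoeboxes for classical
recovery (10 seeded replicates), 60 shots for P-VAE experiments, 9×9
shoeboxes, 30 spectral channels.  Degenerate inputs: empty datasets are
valid containers; shots with no predicted reflections are skipped by
training; backgrounds are floored at 0.1 counts before the log transform;
expected counts are floored at 1e-8 inside the likelihood.  Ties in
reflection selection are broken deterministically (strongest predicted
intensity, then detector order), and every stochastic stage consumes a
single seeded generator with a fixed draw order, making stored outputs
bit-reproducible.

## Known limitations

- The edge-shift estimator inherits a small systematic from the
  cubic-vs-linear curve interpolation mismatch (≲0.03 eV), far below the
  statistical scatter at the default conditions.
- Parametric-bootstrap and variational intervals both under-cover when the
  generating process includes randomness the model does not represent
  (mosaic-domain realizations); the profile interval is the more honest
  default.
- The correction-efficacy experiment injects the gain field as the sole
  misspecification (single mosaic domain, exact metadata), so held-out
  deviance differences are attributable to the correction.  Under the full
  default process the correction still wins in most seeded replicates, but
  mosaic-realization noise (deviance ≈ 3 vs the gain's ≈ 1) can dominate
  individual comparisons.
- The Gaussian lattice profile ignores Laue side lobes and anisotropy;
  mosaic smearing in the inference kernel folds the angular spread into an
  isotropic width, valid while spread·|q| ≪ σ_rl.
- The free-per-channel curve mode runs KK on the coarse spectrum channels
  (≈3 eV spacing), adequate for shape comparisons, not for quantitative
  dispersion work.
- Profile-likelihood intervals become numerically unreliable at large
  problem sizes: with a total NLL of order 10⁷ the inner nuisance
  re-optimizations terminate with slack comparable to the χ²₁ threshold.
  They are dependable at the tens-of-shots scale; for large datasets
  prefer the bootstrap (with its own caveat above) or replicate scatter.
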