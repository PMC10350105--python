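# spread-sfx

A desk-scale toolkit for **spatially resolved anomalous dispersion
(SPREAD)** in serial femtosecond crystallography (SFX): simulate
pixel-level diffraction-spot data with wavelength-dependent anomalous
scattering, invert it for the K-edge shift of a metal site with a
classical gradient-based maximum-likelihood fit, and quantify uncertainty
with a physics-informed variational autoencoder (P-VAE) that can also
*correct* a deliberately mis-specified forward model.

**Who it is for.** Method developers at the crystallography / machine-
learning interface who want a small, fully synthetic, end-to-end testbed
for SPREAD-style inference: every experiment here runs in minutes on one
CPU, ships with its own ground truth, and is bit-reproducible from a seed.

## The problem and the model

The oxidation state of a metal atom shifts its K absorption edge by
~1–2 eV.  That shift is imprinted on SFX diffraction data through the
anomalous scattering factors Δf′(E), Δf″(E) in the structure factor

    F_h(E) = Σ_m occ_m · [f⁰_m(|Q|) + Δf′_m(E) + i Δf″_m(E)]
             · exp(2πi r_m·h) · exp(−B_m|Q|²/4),       |Q| = 1/d,

with Δf′ and Δf″ coupled by the Kramers–Kronig relation.  Each still shot
contributes small pixel patches ("shoeboxes") around predicted spots; the
expected count in a pixel sums |F_h(E)|² over the polychromatic spectrum
and over mosaic domains, scaled by an unknown per-shot factor, plus
background, with Poisson noise.  The inference targets the scalar edge
shift ΔE applied to a reference Mn-like curve; per-shot scales and
per-shoebox backgrounds are nuisance parameters.

Two solvers are provided:

- `EdgeShiftMLE` — pixel-wise Poisson maximum likelihood with analytic
  gradients (L-BFGS-B), profile-likelihood or bootstrap intervals;
- `PVAECorrector` — a hierarchical P-VAE (dataset-level edge shift,
  per-shot scale, per-shoebox background) whose generator embeds the
  physics kernel plus a penalized, identity-initialized multiplicative
  correction, trained by a reparameterized ELBO (pure numpy, hand-written
  backprop).

See `docs/methods.md` for the full model, numerical choices and
limitations.

## Worked example

```bash
cat > smoke.yaml <<EOF
simulation:
  n_shots: 15
  seed: 3
  edge_shift_ev: 2.0
pvae:
  n_epochs: 40
  patience: 15
EOF
spread simulate --config smoke.yaml --out smoke.h5
spread fit      --config smoke.yaml --data smoke.h5 --out fit.json
spread pvae     --config smoke.yaml --data smoke.h5 --out post.h5
```

prints

```
wrote 154 shoeboxes over 15 shots to smoke.h5
edge shift: +2.001 eV (written to fit.json)
posterior edge shift: +1.545 +/- 0.849 eV (written to post.h5)
```

The simulator injected a +2.0 eV edge shift; the classical fit recovers
+2.001 eV (its 90% profile interval, stored in `fit.json`, is
[1.86, 2.21] eV), and the short P-VAE run returns a posterior mean of
+1.55 eV with a 0.85 eV standard deviation — consistent with the truth,
with honest-looking spread for only 15 shots and 40 epochs.  `smoke.h5`
holds only DIALS-style estimates (counts, boxes, Miller indices,
orientation/scale estimates); the ground truth goes to the
`smoke.h5.truth.h5` sidecar, which no inference stage reads.

The same pipeline is available as a library:

```python
from spread import EdgeShiftMLE, PVAECorrector, simulate_dataset

dataset, truth = simulate_dataset(n_shots=200, seed=0, edge_shift_ev=2.0)
mle = EdgeShiftMLE(interval_method="profile").fit(dataset)
print(mle.edge_shift_, mle.edge_shift_ci_)
```

`spread report --config cfg.yaml` runs simulate → fit → pvae end to end
and writes `report.json` plus curve/posterior plots; `spread kk` is a
stand-alone Kramers–Kronig utility for 3-column curve files.

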