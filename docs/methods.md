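# Methods

## The registration model

`gwdemons` performs intensity-driven non-rigid registration of 2-D
grayscale images. The estimated object is a dense displacement field
`u = (u_row, u_col)` in pixels, applied by backward warping with bilinear
interpolation: the registered image is `warped(p) = F(p + u(p))`, with
out-of-frame sample coordinates clamped to the border. The solver seeks to
minimize

```
E(u) = ||R − F ⊗ u||² + σ² ||u||²
```

in the classical demons fashion: an additive per-pixel force update
followed by Gaussian smoothing of the *accumulated* field,

```
u ← G(k1, k2, σ) ∗ (u + du).
```

Smoothing the accumulated field (a diffusion-like regularizer) rather than
the increment (a fluid-like one) is a deliberate choice; the energy above
penalizes the total field, which is what repeated smoothing of the
accumulated field approximates. No composition/diffeomorphic update is
provided.

### Forces

With `d = R − F⊗u` per pixel:

- **thirion** — `du = d ∇R / (‖∇R‖² + d²)`. Driven entirely by the fixed
  image's gradient; cheap, but blind where `∇R` vanishes.
- **wang** — the symmetric force adding the *current warped* moving image's
  gradient and a noise constant α (default 2.5, dimensionless) multiplying
  `d²` in each denominator: large α damps the force where the residual is
  large, stabilizing early iterations.
- **tang** — the symmetric force with the gradient-magnitude terms scaled
  by a balance coefficient `k²` and the force projected along the gradient
  unit vectors; algebraically `du = d ∇ / (k²‖∇‖² + α²d²)` per term, which
  reduces exactly to Wang's force at `k = 1`. `k` defaults to 1.0 because
  no canonical value exists.

Degenerate pixels (denominator below `eps = 1e-12`, i.e. flat *and*
matched) receive zero force — there the force is 0/0 and any value is
arbitrary; zero is the classical and the only stable choice.

Gradients are `numpy.gradient`: central differences in the interior,
one-sided at borders, which keeps the force defined up to the frame edge.

### Iteration policy

A fixed iteration count (default 120) with no early exit: correlation and
energy histories are recorded every iteration so callers can inspect
convergence, but the stopping rule stays trivial and reproducible.
Convergence is *not* monotone in general — the correlation history may dip —
so tests assert final-versus-initial improvement, never per-iteration
improvement.

### Regularizer numerics

The Gaussian kernel is a normalized, truncated window of size `(k1, k2)`
centered at `((k1−1)/2, (k2−1)/2)` (even sizes get a half-pixel-offset
center) with spread σ, applied with replicate border padding. It is
separable, so it runs as two 1-D correlations — numerically identical to
the 2-D kernel at a fraction of the cost, which is what makes
120-iteration runs with windows up to 100 px interactive. σ below 0.5 px
is narrower than the grid can represent and short-circuits to the identity.
Windows beyond 4× the image extent are rejected as configuration errors.

A consequence worth knowing: with replicate padding, regions that generate
no force (flat areas, the dark surround outside a fundus field of view) act
as sinks — each smoothing pass pulls neighboring displacement toward them.
Registration of images with large force-free areas therefore converges more
slowly than textured ones. This is a property of the model, not a bug; see
the phantom section below.

## Grey-wolf optimizer

`gwo_optimize` is maximization-native over a box with per-dimension
integer/continuous kinds. Per iteration, the control scalar is
`a = 2(1 − t/T)` (linear 2 → 0) and for each wolf `W` and each leader
`L ∈ {α, β, δ}`:

```
A = 2a·r1 − a,  C = 2·r2,  D = |C·L − W|,  W_L = L − A·D
```

with fresh `r1, r2 ~ U[0,1)` per use; the wolf moves to the mean of the
three leader-guided candidates, clamped to the box. Leaders update only on
*strict* fitness improvement (incumbents win ties). Integer dimensions
evolve continuously and are rounded only at evaluation/reporting time,
preserving the search dynamics on integer grids. Out-of-box positions are
clamped, not reflected. Everything is driven by one
`numpy.random.Generator(seed)`, so runs are bit-reproducible.

The optimizer registry (`make_optimizer`) exposes the same contract for
comparators; a standard global-best PSO with Clerc-style coefficients
(w = 0.72, c1 = c2 = 1.49) is included. GWO is the supported path.

## Hyperparameter tuning pipeline

`tune` searches `(k1, k2, k3)` — window rows, window cols, σ — over the box
k1, k2 ∈ [20, 100] (integers), k3 ∈ [0, 20] (continuous), fitness being the
Pearson correlation between the fixed image and the fully registered
result. Two policies matter:

- the conventional default triple (60, 60, 10) is injected into the initial
  population, so the reported optimum dominates the un-tuned baseline by
  construction and "optimized vs original" comparisons are meaningful;
- fitness values are memoized on the quantized parameter key
  (metaheuristics revisit integer triples constantly; registration is
  deterministic per triple, so the cache is semantically invisible).

The report re-registers at the best and default triples, computes all four
metrics for each, and derives per-metric improvement percentages as
`100·|after − before| / max(before, after)` with an Increase/Decrease
label; an unchanged metric (including the 0 → 0 MSE of an already-perfect
pair, where the ratio is undefined) reports 0.0 / "Unchanged".

## Metrics

Correlation is the Pearson coefficient over all pixels (undefined and an
error if an image is constant). MSE is on the normalized [0, 1] intensity
scale — an 8-bit pair differing by one grey level everywhere scores
(1/255)² ≈ 1.5e-5 — and the scale is part of the report. Joint entropy and
mutual information use an equal-width joint histogram on [0, 1]
(default 256 bins, one per 8-bit level; configurable) and are reported in
bits, marginals taken from the joint histogram's margins so
`MI = H(X) + H(Y) − H(X,Y)` is internally consistent. "MJE"/"NMI" field
names follow a naming convention common in the registration literature;
the quantities are plain joint entropy and plain mutual information.

## Phantoms: what they emulate and what they don't

`make_phantom` draws a fundus-like scene: a field-of-view disc inscribed in
the frame (radius fraction 1.0 of min(H,W)/2), mottled background texture
inside the disc (Gaussian-filtered noise, amplitude 0.06, correlation
length 3 px — standing in for the choroidal mottle visible through the
retina), bright random-walk vessel branches (default 8, widths 1.5–3.5 px)
started at the rim and steered inward, and additive pixel noise
(σ = 0.01). All of it is deterministic per seed.

The background texture is not cosmetic: an intensity-driven solver gets no
force from flat regions, and the regularizer then drains displacement
toward them, so a texture-free cartoon is *harder* than real tissue for
translation-scale recovery. The phantoms deliberately do not model
illumination gradients, the optic disc, pathology, or camera optics —
passing phantom tests demonstrates the registration machinery, not
photometric robustness on clinical data.

Synthetic warps (`translation`, `rotation_like`, `gaussian_bump`) come with
their analytic fields, and `make_phantom_pair` returns (warped, original,
field) with the *warped* image as the fixed target so the solver's
estimated field is directly comparable to the analytic one.
`recovery_error` is RMS endpoint error in pixels over an interior mask;
the default excludes a 16-px border band, and recovery checks at the stock
60-px window exclude a 30-px band (half the window), since the replicate
border condition makes the outermost band systematically unreliable.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script problems are phantom pairs of 96–128
px per side, 15–120 demons iterations, and optimizer budgets of 4–15 wolves
over 1–50 iterations; identity and translation checks run the full stock
configuration (60 × 60 window, σ = 10, 120 iterations). These sizes were
chosen to exercise every code path at interactive runtimes; the library
itself accepts arbitrary image sizes.

## Known limitations

- 2-D, mono-modal, intensity-based only; no rigid/affine pre-alignment, so
  very large displacements (beyond the regularizer's reach) will not be
  recovered.
- Additive demons only; the field is not guaranteed invertible or
  diffeomorphic.
- The correlation fitness is global: a tuning run can favor parameters that
  align dominant structures while leaving small features slightly off.
- GWO offers no optimality guarantee; the shipped defaults (population 15,
  iteration budgets in the tens) are adequate for the 3-D hyperparameter
  box, not for high-dimensional search.
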