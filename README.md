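# gwdemons

Grey-wolf-optimized demons registration for 2-D grayscale images, built for
retinal fundus photograph alignment but intensity-generic.

Non-rigid (deformable) registration aligns a moving image `F` onto a fixed
reference `R` through a dense per-pixel displacement field `u`. The demons
family estimates `u` iteratively by minimizing

```
E(u) = ||R − F ⊗ u||² + σ² ||u||²
```

where `⊗` is backward warping and the σ-term is realized by Gaussian
smoothing of the field after each additive update. The per-pixel "demon"
force comes in three flavors (with `d = R − F⊗u`):

- **Thirion**: `u = d ∇R / (‖∇R‖² + d²)`
- **Wang** (symmetric): `u = d [ ∇R/(‖∇R‖² + α²d²) + ∇F/(‖∇F‖² + α²d²) ]`
- **Tang** (balanced): the symmetric force with the gradient-magnitude terms
  scaled by a balance coefficient `k²`; identical to Wang at `k = 1`.

Registration quality is steered by the regularizer hyperparameters — the
Gaussian window `(k1, k2)` and spread `k3 = σ` — which are hard to pick by
hand. The package wraps the whole registration in a **grey-wolf optimizer**
(GWO): a population metaheuristic whose three best solutions (α, β, δ)
steer the rest of the pack through encircling-style updates, maximizing the
Pearson correlation between the fixed image and the registered result.
Similarity metrics (correlation, MSE, joint entropy, mutual information) and
a synthetic vessel-phantom generator with known ground-truth deformations
round out the toolkit, so everything is testable without external imaging
data.

## Worked example

```python
import gwdemons as g

# synthetic fundus-like pair: a vessel phantom displaced by 3 px
spec = g.PhantomSpec(size=(128, 128), seed=7)
warp = g.SyntheticWarp(kind="translation", magnitude=3.0, direction=(1.0, 0.0))
fixed, moving, truth = g.make_phantom_pair(spec, warp)

print(f"initial correlation {g.correlation(fixed, moving):.4f}")
result = g.register(fixed, moving, g.DemonsConfig(variant="wang"))
print(f"final correlation   {result.final_correlation:.4f}")
print(f"recovery error      {g.recovery_error(result.field, truth, border=30):.4f} px")
```

prints

```
initial correlation 0.5787
final correlation   1.0000
recovery error      0.0001 px
```

i.e. the solver starts from a clearly misaligned pair (correlation 0.58),
recovers the 3-px displacement essentially exactly, and the registered image
becomes indistinguishable from the reference. Tuning the regularizer instead
of trusting the defaults:

```python
problem = g.TuningProblem(fixed=fixed, moving=moving, n_iterations=40,
                          n_pop=6, n_iter=3, seed=11)
report = g.tune(problem)
print(report.best_params, round(report.best_fitness, 4))
# (20.0, 20.0, 18.298900371738224) 0.9768
```

Here the tuned window/σ triple beats the conventional defaults (60, 60, 10),
whose fitness under the same 40-iteration budget is 0.9596.
The report also carries metric tables for the default and tuned parameter
sets and per-metric improvement percentages.

A CLI mirrors the library: `gwdemons register`, `gwdemons optimize`,
`gwdemons metrics`, `gwdemons phantom` (see `--help` on each).

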