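# polwet

Object-based coastal wetland classification from polarimetric SAR (PolSAR)
coherency data, with feature-importance ranking and feature-set
optimization.

Coastal wetlands (tidal flats, salt marshes, paddies) are hard to map with
optical imagery because of persistent cloud cover; quad-polarized C-band SAR
sees through weather and distinguishes cover types by their backscattering
*mechanism*.  This package implements the full analysis chain used in that
setting, for a seven-class scheme (beach, *Suaeda salsa*, *Spartina
alterniflora*, road, water, irrigable land, rice paddy):

1. **Scene model / simulator** — per-pixel 3×3 Hermitian coherency matrices
   T₃ with multilook complex-Wishart speckle, built from convex mixtures of
   canonical scattering mechanisms (surface, double-bounce, volume, helix),
   with the volume term optionally following the Neumann particle-cloud
   model (anisotropy δ, orientation randomness τ).
2. **16 polarimetric features** per pixel:
   - Cloude–Pottier eigen-decomposition: entropy `H = −Σ pᵢ log₃ pᵢ`,
     anisotropy `A = (λ₂−λ₃)/(λ₂+λ₃)`, mean alpha angle
     `α = Σ pᵢ αᵢ`;
   - radar vegetation index `RVI = 4λ₃/(λ₁+λ₂+λ₃)`;
   - SERD/DERD, the single-/double-bounce eigenvalue relative differences
     from the co-polar eigenvalues under reflection symmetry;
   - Yamaguchi four-component powers (surface, double, volume, helix) with
     exact power conservation `p_s+p_d+p_v+p_h = Span = tr T₃`;
   - Shannon entropy `SE = ln(π³e³ |T₃|)`;
   - Neumann parameters |δ|, arg δ, τ, ψ.
3. **Multiresolution segmentation** of the Pauli RGB: bottom-up region
   merging under the fusion cost
   `f = (1−w_shape)·Δh_color + w_shape·Δh_shape`, merges admissible while
   `f < scale²` (defaults scale 28, shape 0.3, compactness 0.5).
4. **Random-forest permutation importance (MDA)** from per-tree out-of-bag
   samples: `MDA(f) = (1/N) Σᵢ (errOOB₂(i) − errOOB₁(i))`, overall and per
   class, and **sequential backward selection** of the feature subset that
   maximizes stratified 10-fold cross-validated accuracy.
5. **Evaluation** with confusion matrices (predicted on rows), overall
   accuracy, Cohen's kappa, user's and producer's accuracy.

A set of published seven-class confusion matrices from a GF-3 coastal
wetland experiment is bundled (`polwet.reference_confusion_matrices`) so the
accuracy arithmetic can be validated against printed values.

## Worked example

```python
import numpy as np
import polwet as pw

# a volume-scattering coherency matrix with Span = 3.2
t = 3.2 * np.diag([2.0, 1.0, 1.0]).astype(complex) / 4

h, a, alpha = pw.cloude_pottier(t)
ps, pd, pv, ph = pw.yamaguchi4(t)
dmod, dpha, tau, psi = pw.neumann(t)
print(f"H={h:.4f}  A={a:.1f}  alpha={alpha:.1f} deg")
print(f"Yamaguchi powers: odd={ps:.2f} dbl={pd:.2f} vol={pv:.2f} hlx={ph:.2f}")
print(f"Neumann: |delta|={dmod:.2f}  tau={tau:.2f}   "
      f"RVI={pw.rvi(t):.3f}  SE={pw.shannon_entropy(t):.3f}")

rep = pw.accuracy_report(pw.reference_confusion_matrices()["fs_rf"])
print(f"OA={rep.overall_accuracy:.2f}%  kappa={rep.kappa:.4f}")
```

prints

```
H=0.9464  A=0.0  alpha=45.0 deg
Yamaguchi powers: odd=0.00 dbl=0.00 vol=3.20 hlx=0.00
Neumann: |delta|=1.00  tau=1.00   RVI=1.000  SE=6.458
OA=92.85%  kappa=0.9139
```

The entropy 0.9464 and mean alpha of 45° identify fully developed volume
scattering (the eigenvalue spectrum is (½, ¼, ¼) of the Span), the whole
power budget lands in the Yamaguchi volume component, and τ = 1 marks a
completely random particle-orientation distribution.  The confusion-matrix
report reproduces the published overall accuracy (92.86%) and kappa (0.914)
of the optimized feature set to printing precision.

The end-to-end chain on a simulated scene:

```python
from polwet.workflow import run_synthetic_workflow

result = run_synthetic_workflow(seed=1)       # ~1 minute
print(result.reports["all"].overall_accuracy)  # object-based OA, percent
print(result.trace.selected)                   # optimized feature subset
print(result.importance.sort_values().tail(3)) # top MDA features
```

A command-line interface mirrors the stages:
`polwet simulate | preprocess | features | segment | select | evaluate`
(see `polwet --help`).

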