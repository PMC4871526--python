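# Methods

## Model and assumptions

`apseg` solves two-label seeded segmentation on a pixel lattice. For each
label `c ∈ {f, b}` it minimizes

    E(x^c) = Σ_{i∈𝒜} D(a_i, x_i^c, τ_i^c) + Σ_{e_ij} w_ij (x_i^c − x_j^c)²

over the unseeded pixels, with seeded pixels clamped to their indicators.
The smoothness term is the classical random-walker (RW) Dirichlet energy
with Gaussian-of-L1 weights `w_ij = exp(−β|g_i − g_j|) + ε_w`. The
attraction term pulls probabilities inside a shape-derived region 𝒜
toward per-pixel targets τ, weighted by how much each pixel resembles the
foreground seed (`a_i = exp(−|g_i − g_s|)`).

The solved systems are the method's operational definition (see the table
in the README). For the L2 variant the printed system is exactly the
stationarity condition of `E`, so its solution provably minimizes the
energy; this is verified variationally in the tests. For the Pearson and
inner-product variants the systems are taken as given: the inner-product
energy's formal gradient would put `−A_U τ` on the right-hand side, i.e.
the printed INN system *boosts* rather than penalizes in-region
probability, which is the intended behaviour of the algorithm. We
implement the systems, not the (inconsistent) energy expansions.

Key structural facts used in the implementation and asserted in tests:

- **RW reduction.** A zero attraction diagonal turns every variant's
  system into `L_U x = −Bᵀ m^c`. `prior=None`, `variant="rw"`, and a
  threshold matrix with empty support are all equivalent.
- **Conservation.** For RW and L2-AP, `x^f + x^b = 1` pixelwise and
  `x ∈ [0,1]`: the two right-hand sides sum to `(L_U + A_U)·1` by the
  Laplacian row-sum identity and `τ^f + τ^b = 1` on the region, and the
  system matrices are M-matrix-plus-nonnegative-diagonal. PEA and INN
  have no such guarantee; their probabilities are reported unclamped and
  only the argmax is used.
- **Single foreground seed.** The attraction region is the thresholded
  prior translated so its canvas centre (the calibrated centroid) lies on
  the foreground seed; the method therefore uses exactly one foreground
  seed whenever a prior is supplied.

## Shape prior

Training masks are binarized, centred on a common canvas by integer
translation of their rounded centroids (round-half-down; masks stay
binary, no interpolation), and averaged per cell: `SP = Fr/Ns`, values on
the grid `{0, 1/Ns, …, 1}`. Thresholding at Γ (inclusive) keeps the cells
covered by at least a fraction Γ of the training shapes. Supports nest
monotonically in Γ.

The Γ = 0.8 region is therefore approximately the 20th-percentile shape
of the training population — a *conservative core*. This matters: a
region cell that falls outside the true object is pinned toward τ^f by
the attraction term (the smoothness term cannot veto it when β is large),
seeding a false-positive bulge. The method's operating assumption is that
the placed region under-approximates the object; priors should be trained
on a corpus whose size spread brackets the objects being segmented from
*below* (see "Synthetic study conditions").

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `beta` | 310 | 1/intensity | contrast sensitivity of edge weights; 230–340 is the method's reported range on unit-scaled images. Large β makes weights collapse on noisy texture, increasing the relative strength of the attraction term |
| `gamma` | 0.8 | — | SP threshold; smaller values grow the attraction region (0.6 reported for INN) |
| `epsilon_w` | 1e-6 | — | weight floor; keeps the lattice connected and `L_U` SPD for any seed set |
| `epsilon_tau` | 1e-6 | — | floor on τ inside the region for the Pearson reciprocal; `τ^b = 0` occurs wherever `T = 1` |
| `connectivity` | 4 | — | 4-connectivity is the RW convention and keeps systems sparsest; 8 available |
| `margin_fraction` | 0.05 | fraction | distance of the background seed frame from the border |
| `sharpness` | 1.0 | — | optional multiplier in `a_i = exp(−s·|g_i−g_s|)`; on unit-range images the plain factors span only `[e^{−1}, 1]`, so a knob is exposed rather than hard-coding a steeper scale |

Intensities are always normalized to [0, 1] (min–max) before weighting;
the β range above is meaningless on raw 0–255 scales.

## Numerical choices

- One sparse direct factorization (SuperLU) per system; PEA needs one per
  label because its matrix contains `diag(1/τ^c)`. A conjugate-gradient
  fallback (rtol 1e-10, 10·|V_U| iterations) covers factorization
  failures on non-singular systems; an exactly singular system (possible
  only with `epsilon_w = 0` and an unseeded connected component) raises a
  solver error naming the component.
- Solves are rejected unless `‖Mx − b‖∞ ≤ 1e-8·(1 + ‖b‖∞)`.
- Ties `x^f = x^b` are assigned to foreground (favours recall, consistent
  with the method's emphasis on retrieving polyp pixels).
- Metrics with zero denominators are NaN ("undefined"), never silently 0;
  batch means skip them and report how many were skipped. Per-image
  averaging is the default; pixel-pooled summaries are available.

## Synthetic study conditions

The phantom generator emulates what makes OC frames hard: a roughly
convex bright blob on a textured background (smooth random field with
amplitude 2·σ plus i.i.d. Gaussian noise σ), radial vignetting, and
weak-boundary sectors. Defaults were chosen once as the study
conditions:

- **Evaluation population**: disks/ellipses, semi-axes 13–16 px,
  eccentricity 0.95–1.05, centred on a 128×128 field (object ≈ 23 % of
  the image width, comparable to the object/frame ratio of real OC
  frames), contrast 0.35, noise σ = 0.02, vignette 0.1. The centred
  placement mirrors the automatic acquisition mode in which the polyp is
  captured at a fixed position inside the viewfinder.
- **Training corpus**: the same shape family with the broader size range
  10–16 px and centre jitter ±8 px (exercising centroid calibration).
  With Γ = 0.8 this yields a region of effective radius ≈ 11.4 px —
  inside every evaluation object, as the model assumes.
- **Weak-boundary gap**: over a contiguous angular sector covering
  `gap_fraction` of the rim, the object's contrast fades linearly from
  its innermost point to zero at the boundary. The radial gradient
  (≈ 0.022/px at default contrast) stays below the noise scale, so no
  detectable edge exists anywhere in the sector — a genuine weak
  boundary rather than a displaced one. An alternative profile that
  zeroes contrast over an outer band was evaluated and rejected: it
  deletes object evidence outright, degrading every method alike instead
  of probing boundary weakness.

The field-of-view size matters for the RW baseline: if the background
frame sits close to the object, it geometrically caps how far the walker
can leak through a gap and masks the small-cut effect the weak-boundary
experiment probes; the 128 px field keeps the frame several object radii
away.

What passing these tests does **not** show: real OC images have specular
highlights, vessels, bubbles, colour, and priors trained on other
patients' polyps; the phantoms have none of these. The synthetic results
validate the mechanics (systems, prior, attraction geometry, metrics),
not clinical performance.

## Known limitations

- The inner-product variant is strongly β-sensitive: its system matrix is
  `L_U` alone, so its in-region solutions scale like `a τ / (graph
  degree)` and blow up when large β collapses the weights (on the
  synthetic phantoms at β = 310 it over-segments massively). This matches
  the variant's reported sensitivity; use PEA or L2 unless β is small.
- A single foreground seed and a single attraction region: no multi-polyp
  frames, no multi-label segmentation, no 3-D lattices.
- The prior is translated, never scaled or rotated, onto the seed; size
  mismatch between training corpus and target objects degrades precision
  (see "Shape prior").
- Masks of differing resolutions are calibrated on a common canvas
  without resampling.
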