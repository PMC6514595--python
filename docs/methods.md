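# Methods

## Model

Leaf/wood separation is treated as per-point binary classification driven
by local covariance geometry. For a point q and scale k, the neighborhood
is defined as {q} ∪ {its k exact nearest neighbors}, i.e. k+1 points; the
k-NN scale definition is used rather than a fixed-radius sphere because a
suitable radius varies between trees while k does not. The population
covariance of the neighborhood (divide by the point count) gives
eigenvalues λ₁ ≤ λ₂ ≤ λ₃, normalized to αᵢ = λᵢ/Σλ, and the eigen-entropy
E = −Σ αᵢ ln αᵢ (nats, bounded by [0, ln 3]).

Scale-selection strategies over an arithmetic candidate grid
(default k = 10..100 step 10):

* **optimal** — the single k minimizing E per point;
* **multi-optimal** — the m candidates with the m smallest entropies per
  point (the package's primary method);
* **multi-scale random** — one uniformly drawn size-m subset of the grid,
  shared by all points (the baseline band is its worst/mean/best over
  repeated draws).

At each selected scale 12 features are computed; the 2D features use the
*same* 3D neighborhood projected onto XY, not an independent planar
query. Linearity3D and Planarity3D are the normalized eigenvalues α₃ and
α₂ as such (so Linearity3D ≥ 1/3 by construction), not the classical
(λ₃−λ₂)/λ₃-style dimensionality contrasts. Density3D = (k+1)/((4/3)πr³)
and Density2D = (k+1)/(πr²) count the neighborhood points inside the
ball/disk of the neighborhood radius. Verticality3D is |n_z| of the
λ₁-eigenvector; the absolute value removes the arbitrary eigenvector
sign.

The classifier is a random forest on the stacked 12·m feature vector of a
random **core-point** subsample (default 10% of the cloud), trained on a
random ~10% of the core points; all other points inherit the label of
their Euclidean-nearest core point. Defaults ntree = 100,
max features per split = ⌊√(12·m)⌋, minimum leaf size 10 — chosen to
match the standard protocol for this task. Prediction uses the forest's
averaged class probability with exact 0.5 ties assigned to wood (an
arbitrary but fixed rule). Accuracy is (T_w+T_l)/(w+l) over the held-out
core points (the protocol's evaluation) and, separately, over the full
propagated cloud when reference labels exist.

## Numerical conventions and degenerate inputs

* 0·ln 0 = 0 in the entropy; eigenvalues are clipped at 0 to absorb
  eigensolver round-off.
* A neighborhood of coincident points (Σλ = 0) gets α = (1/3,1/3,1/3) and
  E = ln 3, so shape-free neighborhoods are never selected as "optimal";
  its normal is defined as (0,0,1), Anisotropy3D = 0, Density3D = 0,
  Density2D = 0, Linearity2D = 1/2.
* Entropy ties across scales break toward smaller k; selected scales are
  stored in ascending k so feature columns have one canonical layout.
* Neighbor-distance ties break toward the smaller point index
  (re-sorted after the kd-tree query), and exact search is mandatory —
  both for cross-platform determinism of the entropy minima.
* When λ₁ ≈ λ₂ (perfectly linear neighborhood, relative gap < 1e-9 of
  λ₃), the normal is the direction orthogonal to the λ₃ axis with maximal
  |z|, making Verticality3D deterministic.
* Nearest-core ties during propagation go to the smaller core index,
  re-checked among the 4 nearest cores; exact ties beyond that window are
  vanishingly unlikely for continuous coordinates.
* The mean of the random multi-scale accuracy band is clamped into
  [worst, best] to keep the order-statistics invariant exact under
  floating-point summation.
* Core-point and train-split sizes round half-away-from-zero with a floor
  of one point.

## Synthetic trees

The generator emulates the one property the method depends on: wood
points sampled on cylinder surfaces (quasi-1D/2D), leaf points uniform in
balls (isotropic 3D). The default tree is an 8 m × 0.12 m trunk, 25
branches (1–2.5 m × 0.025 m, attached on the upper 60% of the trunk,
inclination 20–70° from vertical so verticality stays informative), 30
foliage clusters of radius 0.3 m × 400 points, wood surface density
1200 points/m², and 5 mm radial Gaussian jitter emulating TLS range
noise — about 27,000 points at a roughly 55/45 wood/leaf split, a
desk-scale analogue of real single-tree scans (millions of points).
Jitter is applied along the local radial direction so the axis distance
stays radius + N(0, σ) exactly, which makes the generator's own noise
model directly testable. Point order is shuffled so class labels carry no
ordering signal into train/test splits.

What the generator does **not** emulate: occlusion and scan shadows,
registration artifacts between scan positions, foliage density gradients,
small twigs at or below the noise scale, and the leaf-size/point-spacing
interplay of real canopies. Passing tests therefore demonstrate that the
pipeline recovers the geometric contrast it is built on, not field-level
accuracy on real scans; on real TLS trees the same pipeline applies
unchanged but accuracy depends on scan quality and canopy structure.

## Experiment driver and problem sizes

`run_comparison` evaluates all strategies on one shared core sample and
one shared train/eval split with one forest seed, so differences isolate
scale selection. Feature blocks are computed once per candidate scale and
reused across all selections, which makes the 50-model random band cheap.
The package default for the random band is 50 models per m (the full
protocol); the test suite and the smaller structural checks use 5–10
models, since the assertable surface is the order statistics, not the
band's absolute width. Pipeline-level tests run on ~4.5k-point trees and
the separation-quality checks on ~27k-point trees; both finish in seconds
to a few minutes on one CPU.

Wall-clock timings are recorded per stage and the core-point speedup is
reported as a ratio (time without core subsampling / time with); it is
asserted only to exceed 1, never against any absolute figure, because it
is hardware-dependent.

## Design choices that were genuinely open

* Whether the query point belongs to its own PCA neighborhood is not
  settled in the optimal-scale literature; including it (k+1 points)
  keeps the Density3D numerator consistent and is adopted throughout.
* The core-point sample is simple random sampling, unstratified by class.
* The 50 random multi-scale models share one train/eval split rather than
  re-splitting per model; this isolates scale-subset variability.
* The training fraction is an exact parameter (default 0.1 of core
  points) rather than "about 10%".
* Parallel feature extraction is supported via the kd-tree's worker pool;
  results are bit-identical regardless of worker count because all
  reductions are order-independent.

## Known limitations

Binary classes only (no bark/twig/ground classes); no radiometric or
intensity features; no probability calibration; geometric-sequence scale
grids are expressible through the grid constructor but get no dedicated
machinery; LAS I/O is out of scope (ASCII XYZ and ascii-1.0 PLY only).
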