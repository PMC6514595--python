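# leafwood

Leaf/wood separation for terrestrial laser scanning (TLS) tree point
clouds: per-point **multi-optimal neighborhood scales**, covariance-
eigenvalue geometric features, and a random forest applied to a core-point
subsample with nearest-neighbor label propagation.

## The problem and the method

Dense TLS scans of individual trees mix two materials with very different
local geometry: wood (trunk, branches) lies on quasi-1D/2D manifolds,
while foliage forms 3D scatter. Classifying each point as leaf or wood is
the first step toward wood volume, above-ground biomass and leaf area
estimates.

For a point *q* and neighborhood size *k*, PCA of *q* and its *k* nearest
neighbors gives covariance eigenvalues λ₁ ≤ λ₂ ≤ λ₃ and normalized
eigenvalues αᵢ = λᵢ / Σλ. The **eigen-entropy**

> E(α) = −(α₁ ln α₁ + α₂ ln α₂ + α₃ ln α₃) ∈ [0, ln 3]

measures how ambiguous the local dimensionality is. Among a candidate
grid (default k = 10, 20, …, 100) each point's *optimal* scale is the k
minimizing E(α); its ***m* multi-optimal scales** are the m candidates
with the m smallest entropies — each point gets its own set. At each
selected scale, 12 geometric features are computed (Linearity3D,
Planarity3D, Omnivariance3D, Anisotropy3D, Verticality3D, Radius3D,
Density3D, Zdiff3D, StdZ3D and the projected Radius2D, Density2D,
Linearity2D) and stacked into a 12·m feature vector. A random forest
(100 trees, √#features per split, minimum leaf size 10) is trained on
~10% of a 10% *core-point* subsample; every remaining point inherits the
label of its nearest core point. Accuracy is (T_w + T_l)/(w + l), with
T_w/T_l the correctly identified wood/leaf points.

Baselines for comparison: the single optimal scale (m = 1) and the random
*multi-scale* strategy (one random size-m subset of the grid shared by
all points, refit many times to get its worst/mean/best band).

Because reference-labeled TLS trees are rarely deposited, the package
ships a synthetic-tree generator (cylinder wood + uniform-ball foliage)
that reproduces exactly the geometric contrast the method exploits.

## Worked example

```python
from leafwood import LeafWoodModel, SyntheticTreeSpec, generate_tree

cloud = generate_tree(SyntheticTreeSpec(seed=1))   # ~27k labeled points
res = LeafWoodModel(cloud, method="multi_optimal", m=5, seed=1).fit()
print(res.summary())
```

```
Leaf/wood separation results
============================================================
points:      27333    core points:     2733
method: multi_optimal (m=5), grid k=10..100 (10 scales)
forest: ntree=100, mleaf=10, n_train=273
------------------------------------------------------------
held-out core points:
  wood 1350/1367 correct, leaf 1047/1093 correct
  accuracy = (Tw+Tl)/(w+l) = 0.9744
full cloud (after nearest-core propagation):
  wood 15135/15333 correct, leaf 11172/12000 correct
  accuracy = 0.9625
------------------------------------------------------------
timings (s): core_sampling=0.00, scales_and_features=0.82, training=0.14, core_prediction=0.01, propagation=0.03
```

The held-out block scores the forest on the 90% of core points not used
for training; the full-cloud block scores every point after propagation
against the generator's reference labels. `res.labels` holds the
predicted class of all 27,333 points.

The same pipeline from the shell:

```sh
leafwood simulate --seed 1 --out tree.xyz
leafwood separate tree.xyz --out separated.xyz --method multi_optimal -m 5
leafwood compare tree.xyz --out-csv sweep.csv --m-values 2,3,4,5 --n-random-models 50
```

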