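# Methods

## The model

`gecon` reconstructs an undirected, signed gene co-expression network by
local pattern matching. The underlying assumption is that biologically
related genes share *local* similarity — matching rises and falls over
subsets of conditions — rather than global profile similarity, and that
both parallel (positive) and mirror-image (negative) behaviour count as
co-regulation.

Each profile of M conditions is reduced to M−1 edge descriptors: a
regulation sign (up/down step) and a degree of fluctuation, the angle
|atan2(next, prev)| in degrees, reflected to 180° − |·| on downward steps.
Note the angle is computed from the two *raw expression values*, not from
the step size: it is the direction of the point (prev, next) in the plane.
Two consequences matter in practice:

* the representation is invariant under multiplying a profile by a
  positive constant (atan2(βy, βx) = atan2(y, x)), so multiplicative
  ("scaled") co-regulation is captured exactly;
* additive ("shifted") co-regulation is captured only approximately: a
  constant offset rotates the direction of (prev, next), negligibly when
  both values are large relative to the offset, substantially near the
  origin. Shifted partners therefore match on most but not necessarily all
  edges.

Per-edge matching uses a tolerance τ: positive when signs agree and angles
differ by less than τ; negative when signs oppose and the two angles sum to
within τ of 180°. The sum rule encodes mirror-image geometry: an edge with
angle a and its reflection with angle 180 − a sum to exactly 180. Both
inequalities are strict. The two rules are mutually exclusive on any edge
pair because the sign conditions are disjoint.

Pair supports are the matched fractions of the M−1 edges, accumulated for
all unordered pairs in one pass over the transposed edge table into a
condensed triangular count structure of size N(N−1)/2 (the correlogram).
A pair is connected when pos + neg > θ (strict); the edge sign is +1 when
pos alone exceeds θ and −1 when neg does. When θ < 0.5 a pair can qualify
on combined support with neither component above θ; the sign of the larger
component is then used, ties +1 — a deterministic fallback that cannot
trigger at the recommended θ ≥ 0.5. Modules are connected components of
the nonzero adjacency, sign-agnostic, with a configurable minimum size
(default 2, i.e. only isolated genes are excluded).

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| τ (tau) | degrees | 20 | angle tolerance; useful range ≈ 15–25. Smaller is stricter on both match rules. |
| θ (theta) | fraction of M−1 edges | 0.5 | support threshold, strict. Below 0.5 the edge-sign fallback becomes reachable and spurious connections rise sharply. |
| β (beta) | – | 0.5 | F-score weight; β < 1 favours precision, appropriate when false edges are costlier than missed ones. |
| min_module_size | genes | 2 | drops singleton components only. |

## Evaluation

The method outputs a thresholded network, not a full ranking, so edges are
ranked by combined support (pos + neg) and all absent pairs share
confidence 0. Curves sweep the distinct confidence values descending, ties
entering together. The PR curve is anchored at (recall 0, precision of the
top threshold): with this convention a degenerate all-tied ranking
integrates to the positive prevalence, which is the natural floor. The ROC
curve is anchored at (0, 0). Both areas are trapezoidal. F_β is summarised
as both the maximum and the mean over sweep points; the maximum is the
headline number. Directed gold standards are symmetrised (a pair is
positive if either direction is) because the prediction is undirected;
self-pairs are excluded from the pair universe throughout. Edge signs are
not scored — gold standards label interaction, not polarity.

## The synthetic generator

`gecon.simulate` plants known co-regulation structure: each module derives
its members from an independent base profile by an additive offset
(drawn uniformly within ±alpha), a multiplicative factor (log-uniform in
[1/beta_scale, beta_scale]), reflection about the module's operating level,
or segment-wise mirroring (a persistent Markov on/off state with toggle
probability 0.25 per condition), plus i.i.d. Gaussian noise. The first
member of every module is the base itself. Ground truth is the
within-module clique, each pair signed by the product of its members'
orientations (−1 for reflected members). Placing the base in the module
matters for anti-correlated patterns: two reflections of the same base are
mutually *positively* similar, so a module of reflections without its base
would contain no negative edges at all.

Two geometric facts shaped the generator, and both are properties of the
angle representation rather than implementation choices:

* **Base profiles are mean-reverting random walks** (AR(1) with
  coefficient 0.3, innovation sd 150, consecutive values forced ≥ 15 units
  apart), zero-centred like log-ratio data. Strong mean reversion makes
  consecutive values nearly independent, so edge directions — and hence
  angles — spread broadly over [0°, 180°]. A drifting walk whose level is
  large relative to its steps produces angles piled up near 45°/135°, and
  unrelated genes then match on most edges by chance, drowning the planted
  structure in false positives.
* **Modules with reflected (inverted or mixed) members sit at an elevated
  positive operating level** (drawn uniformly in [500, 800]). Reflection
  about zero maps an edge onto one with the *same* angle
  (|atan2(−y, −x)| = 180 − |atan2(y, x)|, which the downward-step
  reflection maps back), so the angle-sum rule can essentially never fire
  for a profile negated about zero. Mirror geometry with
  aᵢ + aⱼ ≈ 180° requires a positive mirror axis, and reflection matching
  is approximate even then — exact only for edges whose two values
  straddle the axis symmetrically.

Default study conditions: 3 modules × 10 genes (shifted, scaled,
inverted), 15 conditions, noise sd 5 (about 3 % of the innovation sd,
i.e. low noise), 10 background genes. At τ = 20, θ = 0.5 these settings
yield mean edge precision ≈ 0.99 and recall ≈ 0.97 over 20 seeds with all
recovered signs correct; recovery degrades monotonically as noise grows
toward the step scale. All randomness derives from the single spec seed
through spawned `SeedSequence` children, so any individual profile is
reproducible in isolation.

What the generator does **not** emulate: transcription kinetics or any
mechanistic regulatory model (no ODE simulation à la GeneNetWeaver),
condition correlation structure, heteroskedastic or intensity-dependent
noise, missing values, or overlapping module membership. Passing the
recovery tests therefore demonstrates that the implementation detects the
pattern taxonomy it targets under controlled conditions — not that the
method attains any particular accuracy on real microarray data.

## Numerical choices and degenerate inputs

* Ties O_{k−1} = O_k take regulation +1 (ties are measure-zero in
  continuous data; a fixed choice keeps determinism).
* The (0, 0) edge takes angle 0 (the atan2 convention) with a warning.
* Angles are stored at full floating-point precision; whole-degree values
  appear only in display and documentation.
* Thresholds τ and θ are strict inequalities throughout.
* Module IDs order by decreasing size, then lexicographically smallest
  member; genes within a module sort lexicographically.
* F_β at precision = recall = 0 is defined as 0 with a warning.
* An expression matrix must be fully finite; a single gene is accepted
  (the transform is defined per profile) but pair counting requires at
  least two genes and two conditions.

## Problem sizes

The bundled tests and the acceptance script run on matrices up to 50 genes
× 20 conditions and synthetic datasets of 40 genes × 15 conditions
(20 replicate seeds), sizes at which brute-force oracles remain exact and
instant. The implementation itself is vectorised per edge column and
scales as O(N²·M) time with N(N−1)/2 memory; nothing in it is specific to
these sizes.

## Known limitations

* Shifted co-regulation is only approximately captured (see above); near
  zero-crossings an additive offset can rotate an edge beyond any
  reasonable τ.
* The negative-match rule is blind to anti-correlation about a zero
  baseline — a direct consequence of the published angle-sum formulation.
* Support counting weighs all conditions equally; a single module cannot
  be detected if its members co-vary under fewer than θ·(M−1) conditions.
* Edge confidence is the combined support, a step-like score with many
  ties; PR/ROC curves on small datasets are correspondingly coarse.
* Modules are plain connected components: one spurious bridge edge merges
  two otherwise distinct modules.
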