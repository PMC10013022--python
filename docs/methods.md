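# Methods

## The analysis chain

`boldvis` characterises a regional BOLD time series by the simplicial
structure of its natural visibility graph. The chain is: (optionally)
simulate a cohort of block-design series → average the cohort pointwise →
slice out one task condition (or keep the whole series) → build the natural
visibility graph → enumerate maximal cliques → report the f-vector of the
clique complex, q_max, and the classical network summary → contrast cells
of the population × region × condition grid.

Averaging always happens on the *series*, before graph construction —
never on graphs or f-vectors. This matches analyses that construct one
network per group from the group-average signal; the alternative
(per-subject networks, averaged descriptors) answers a different question
and is out of scope.

## Visibility graph

Nodes are the 0-based sample indices. Samples i < j are linked iff every
intermediate sample r lies strictly below the chord from (t_i, y_i) to
(t_j, y_j). Three numerical/semantic choices matter:

* **Collinear intermediates block by default.** With an intermediate point
  exactly on the chord, the strict inequality denies the link; this is the
  convention of the natural-visibility literature and avoids a straight
  ramp degenerating into a complete graph. The non-strict variant is
  exposed as `collinear_blocks=False` because the verbal "no point above
  the line" definition found in applied papers reads non-strict.
* **Cross-multiplied comparisons.** The chord test is evaluated as
  `(y_j - y_i)(t_r - t_i) > (y_r - y_i)(t_j - t_i)` (both time differences
  positive), so there is no division and no tolerance parameter; for
  integer or rational inputs the test is exact.
* **Times as indices.** The construction is invariant under positive affine
  maps of either axis (proved by the test suite on random series), so for
  uniformly sampled data the integer index is used as the time coordinate.

The implementation is an O(n²) sweep keeping, for each anchor i, the
running maximum slope to any intermediate sample; n = 240 makes anything
faster unnecessary. Equivalence with the O(n³) all-pairs/all-intermediates
brute force is part of the acceptance suite.

## Cliques and f-vectors

Maximal cliques come from the Bron–Kerbosch recursion with pivoting, with a
degeneracy-ordering outer loop — worst-case optimal, and effectively linear
on the sparse graphs visibility produces. Ties in the degeneracy order and
the pivot choice are broken deterministically, and output is canonically
ordered (size, then lexicographic), so runs are reproducible.

The f-vector is reported in two conventions, both always written:

* `all_faces` — f_q counts *every* clique on q+1 nodes (the classical
  f-vector of the clique complex). Obtained by expanding each maximal
  clique into all its subsets with deduplication; verified against
  exhaustive subset enumeration on small random graphs. Invariants
  f_0 = n, f_1 = |E| and the Euler characteristic (= 1 for any complete
  graph or path, as contractible complexes) serve as cross-checks.
* `maximal_only` — f_q counts only maximal cliques on q+1 nodes; entries
  sum to the number of maximal cliques.

q_max is identical under both. The default convention for contrasts is
`all_faces`, since "number of q-dimensional simplices" without a maximality
qualifier denotes the classical count; published per-dimension plots may
follow either convention, which is why both are persisted.

## Classical characterisers

D_avg = 2|E|/n; C_avg is the mean local clustering coefficient with
degree-0/1 nodes contributing 0 and **included** in the mean; L_avg is the
mean hop distance over unordered distinct pairs; diameter is the maximum.
The inclusion convention for low-degree nodes and the unordered-pair
averaging are stated prominently because published tables rarely say which
convention they used; comparisons across conventions can differ in the
second decimal. Disconnected input is rejected (with the component count)
rather than silently averaged per component.

## Synthetic generator

Each subject is `baseline + (boxcar * HRF) + AR(1) noise`:

* **Design**: 3 cycles × (word, rest, nonword, rest) × 20 samples at 3 s —
  240 samples, 12 min — matching the block paradigm the package emulates.
  All of it is configurable.
* **HRF**: canonical double-gamma, unit-dispersion gamma densities with
  shape = peak delay 6 s and undershoot delay 16 s, undershoot ratio 1/6,
  32 s support, normalised to unit peak so amplitudes are peak responses in
  BOLD units. Defaults `baseline=100`, task amplitude 2 (a ~2% signal
  change, typical for block designs); the low-activity region preset uses
  amplitude 0.4.
* **Noise**: stationary AR(1), x_t = φ·x_{t−1} + ε_t, initialised from the
  stationary distribution; added after convolution (measurement-noise
  model). φ controls smoothness, the property that drives visibility-clique
  dimension: smoother series have longer convex runs and hence larger
  cliques. Population presets: adults φ=0.4, σ=1.0; children φ=0.8, σ=0.6.
  These presets are a parameterisation that reproduces the *kind* of
  contrast of interest (children's averaged series yielding
  higher-dimensional simplices), not a generative claim about development.
* **Seeds**: per-subject seed = cohort seed + subject index; per-cell seeds
  in the pipeline are derived from the run seed by fixed offsets, with an
  optional per-population override. Seeds are mandatory in configs.

What the generator does *not* emulate: spatial structure, neurovascular
coupling dynamics, scanner drift, motion, physiological confounds, or any
resting-state correlation between regions. Passing tests therefore show
the chain is correct and well-behaved on signals with realistic timing,
response shape and autocorrelation — not that any particular empirical
q_max contrast in real populations is reproduced.

## Segmentation

`concatenated` (default) joins a condition's blocks end-to-end and
re-indexes 0..m−1 before building one graph; `per_block` builds one graph
per block. The default is concatenated because a single connected graph has
a well-defined path length and diameter, whereas a union of block graphs
does not; in `per_block` mode the reported f-vector is the sum over blocks
(simplex counts are additive over disjoint graphs) and the path-based
summary is omitted. Whether published condition networks were built one
way or the other is generally unstated; both modes are provided and the
choice is surfaced in the config. Note that concatenation creates spurious
visibility links across block boundaries; with three 20-sample blocks this
affects a small minority of pairs.

## Numerical and degenerate cases

* Series shorter than 2 samples are rejected everywhere.
* A 1-sample condition block is a valid (single-node) segment in
  `per_block` mode but cannot form a graph alone; concatenated mode
  absorbs it.
* f-vector of a 0-node graph is undefined and rejected; an edgeless graph
  has f = (n,), q_max = 0.
* AR(1) requires |φ| < 1; noise_sd = 0 short-circuits to an exactly
  deterministic series.
* Report JSON is written with sorted keys and no timestamps, so identical
  configs produce byte-identical reports; recomputing floats from re-read
  artifacts agrees to rounding (summation order), not necessarily
  bit-for-bit.

## Problem sizes

Default test and acceptance sizes: oracle equivalence on random series of
10–50 samples (100 series) and random graphs of 8–14 nodes (50 graphs,
exhaustive enumeration); generator recovery over 100 seeds of 240 samples;
the end-to-end grid at the full 240-sample, 5-subject scale. These sizes
make the exhaustive oracles exact and keep the whole suite to a few
seconds on one CPU.

## Known limitations

* The n-point correlation interpretation of q_max is heuristic; the package
  computes the topology, not an estimator of n-point correlations.
* No statistical inference across cohorts (no tests on f-vectors); the
  report gives raw counts and deltas. f-vectors of unequal-length series
  (60 vs 240 nodes) are not normalised before comparison — left to the
  user, since no principled normalisation is established.
* Horizontal/weighted/directed visibility variants, Betti numbers and
  persistent homology are out of scope.
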