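# Methods

## The question and the three spaces

Given a corpus of multi-herb formulas, per-compound descriptor tables and a
declared set of "incompatible" herb pairs, the package tests one directional
hypothesis per representation:

| space | construction | expected direction for incompatible pairs |
|---|---|---|
| network | herbs linked iff they share ≥ 1 formula | farther (longer shortest paths) |
| chemical | weight-center of molecular descriptors, PCA to 3D | farther (dissimilar chemistry) |
| metabolism | weight-center of CYP450 docking scores, PCA to 3D | closer (competition for the same enzymes) |

Each space produces the same statistic: the mean distance of the declared
pairs versus the global mean over all C(n, 2) unordered herb pairs, plus a
permutation p-value. The combined verdict is simply whether each space's
observed direction matches the expected one.

## Network model

- **Edges.** A formula's herb list is deduplicated before pairing, so a herb
  repeated in one prescription cannot create a self-loop or inflate an edge.
  Edges store the co-occurrence count, but all topology (shortest paths,
  clustering, degree) is computed on the unweighted graph: one shared
  formula already establishes the relationship, and the classical
  definitions of `D`, `L` and `C_i` are unweighted.
- **Average distance with disconnected graphs.** `L` averages over reachable
  unordered pairs only; the component count is always reported so users see
  when this restriction matters. A graph with no edges has no defined
  `D`/`L` and raises `DegenerateGraph`.
- **Clustering for degree < 2.** `C_i := 0` (the common convention), so the
  mean clustering is defined on all nodes.
- **Power-law fit.** Default estimator: OLS of `log10 P(k)` on `log10 k`
  over the support `{k > 0, P(k) > 0}`, requiring ≥ 3 distinct degrees;
  `γ` is minus the slope and the log-log `R²` is reported as a linearity
  diagnostic. This matches how such exponents are usually read off a log-log
  degree plot. A discrete maximum-likelihood mode (`method="mle"`,
  Hurwitz-zeta likelihood maximized numerically) is available; note it
  assumes an untruncated tail and is only meaningful for `γ > 1`, whereas
  dense co-occurrence networks often show `γ < 1`, where only the OLS
  reading makes sense.
- **Pair path distances.** Declared pairs in different components are
  reported as excluded ("unreachable") and left out of the pair-set mean;
  the permutation null likewise draws only from finite-distance pairs, so
  observed and null means stay exchangeable.

## Descriptor spaces

- **Weight-center treatment.** Herb centroid = mass-weighted mean of its
  compound descriptor vectors. Masses default to 1 (relative compound
  abundances in a herb are rarely known); a mass column is accepted for
  when they are. The operation is linear — pooling two groups gives the
  mass-weighted combination of their centroids — and this is tested to
  1e-12.
- **Standardization.** Descriptors are z-scored (ddof = 1) before PCA, i.e.
  the PCA is of the correlation structure. Descriptor units are wildly
  heterogeneous (molecular mass vs logP vs topological indices; docking
  scores per enzyme), which makes covariance PCA indefensible as a default;
  `scale=False` switches it off. Zero-variance descriptors are dropped with
  a warning before standardization (their z-score is undefined).
- **Missing values** are rejected by default; per-descriptor mean imputation
  exists behind an explicit `impute_missing=True` flag.
- **PCA.** Plain SVD of the standardized centroid matrix; explained-variance
  ratios are `s_i² / Σ s²`. Sign convention: each loading column's
  largest-magnitude entry is made positive, so coordinates reproduce across
  linear-algebra backends (distances are unaffected). A cumulative
  contribution rate below 80% triggers a warning — the conventional
  threshold for "three components carry the message" — never an error.
- **Distance.** The distance of record is the 3D Euclidean distance in the
  embedded coordinates, not the full-descriptor-space distance (which is
  available separately as a diagnostic via `centroid_distance_matrix`).
- **Global mean.** "The average distance of all herbs" is taken over all
  C(n, 2) unordered pairs of embedded herbs.

## Permutation test

The reference analyses this design descends from compare the two means with
no significance procedure; the permutation test is this package's addition.
Under the null, the declared pair set is an arbitrary k-subset of pairs:
each of `n_perm` replicates draws k distinct pairs uniformly without
replacement from the space's available pairs and records the mean distance.
The one-sided p-value uses +1 smoothing,
`p = (1 + #{null means at least as extreme}) / (n_perm + 1)`,
which cannot be zero and is super-uniform (slightly conservative) under the
null. Directions default to the per-space expectations above; a two-sided
mode (twice the smaller one-sided p, capped at 1) exists. `n_perm ≥ 99` is
enforced. For large pair counts the index draws are chunked so memory stays
bounded.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes, at
configurable scale, with one numpy `Generator` seeded from `StudyConfig.seed`
driving every draw (outputs are byte-identical across runs).

- **Formulas.** Each formula draws a size uniformly from
  `[formula_size_min, formula_size_max]` (default 4–10) and samples herbs
  without replacement with Zipf weights (`w_r ∝ r^−s`, default `s = 1`),
  reproducing the strong popularity skew of real prescription corpora. With
  `network_exclusion` on, any draw containing a planted pair is rejected and
  redrawn (bounded retries, then a loud `GenerationFailure`), so formula
  sizes stay as drawn and the exclusion constraint holds exactly. Herbs that
  end up in no formula are injected into a random compatible formula so the
  herb vocabulary and network node set coincide.
- **Descriptors.** Herb identity lives in a `latent_dim = 3` space: cluster
  means ~ N(0, cluster_spread² I) with `cluster_spread = 3`, herb offsets
  ~ N(0, herb_scatter² I) with `herb_scatter = 1`. Latent positions are
  mapped into descriptor space (p = 120 chemical, p = 15 metabolism) through
  a random orthonormal basis (isometric for the signal) plus a per-descriptor
  baseline, and each compound is its herb centroid plus isotropic noise with
  `within_herb_sd = 0.5`. The low-rank structure is deliberate: real
  descriptor and CYP-docking tables are reported to concentrate 80–90% of
  their variance in three principal components, and a full-rank isotropic
  cloud would hide any planted effect from the 3D embedding the distance
  formula prescribes.
- **Planted effects.** Pairs are drawn over disjoint herbs (each herb in at
  most one planted pair, so displacements are independent; the classical
  rule does reuse herbs — a simplification). Chemical mode pushes the two
  latent centroids apart by `chemical_separation` (default 5.0 descriptor
  units = 10 within-herb sd) along their separating direction; metabolism
  mode moves each endpoint up to `metabolism_attraction` (default 5.0)
  toward the pair midpoint. The network effect is the exclusion constraint
  itself.
- **The null world.** `StudyConfig.null()` sets both displacement effects to
  zero *and* turns `network_exclusion` off — the exclusion constraint *is*
  the network effect, so a calibration null must drop it too. (This switch
  is the one field added beyond the originally envisaged configuration.)
- **Scales.** Defaults are small and fast (50 herbs, 100 formulas, ~5
  compounds/herb). `StudyConfig.reference_scale()` is a preset at the reference
  corpora's scale (383 herbs, 362 formulas, ~8,514 compounds, 37 declared
  pairs); it runs end to end in seconds and incidentally lands near the
  reference network's density (average degree ≈ 32, clustering ≈ 0.7).

**What a green test does and does not establish.** The generator reproduces
popularity skew, co-occurrence density, low-rank descriptor structure and
controllable pair effects; it does not emulate chemically realistic
descriptor marginals, docking-score physics, correlated herb reuse across
declared pairs, or curation noise in historical corpora. Green recovery
tests therefore establish that the *pipeline* detects the stated structure
when present and stays calibrated when absent — not that any historical
claim about real herb pairs is true.

## Numerical and interface choices

- Node and herb iteration order is sorted-ID everywhere; every output is
  deterministic given inputs and seed, and fitted results serialize to
  byte-stable JSON.
- CSV writers emit floats via `repr` (shortest exact round trip) and the
  reader parses with `float_precision="round_trip"`, so write-then-read is
  lossless to the bit.
- The Pajek dialect is pinned: `*Vertices N`, 1-based indices, quoted
  labels, `*Edges i j w` with integer weights. Variants differ between
  tools; this one round-trips.
- The CLI refuses to overwrite outputs without `--force`; all tabular
  outputs carry `#` provenance comments (tool version, seed).
- Permutation seeds inside a model fit are three independent child streams
  spawned from the fit seed, so the three spaces' nulls are mutually
  independent.

## Known limitations and open points

- The corpora that motivated the design are proprietary and undeposited;
  the package's reference-scale numbers come from the synthetic preset, not
  from the historical data. (The published account of that data is itself
  internally inconsistent about its edge count — 5236 vs 5258 for the same
  network; this package always reports its own count.)
- Hub herbs (e.g. liquorice root, which appears in a large fraction of real
  formulas) shorten path distances for every pair; no hub-removal
  correction is implemented.
- The OLS power-law fit is a descriptive reading of the degree plot, not a
  rigorous tail estimate; use the MLE mode (γ > 1 regimes only) or external
  tooling for inferential claims about scale-freeness.
- Whether "the average distance of all herbs" should average all C(n, 2)
  pairs or some curated subset is a design choice; all-pairs is implemented
  and documented.
- Per-pair reference values for individual classical pairs are not encoded;
  only set-level comparisons are made.
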