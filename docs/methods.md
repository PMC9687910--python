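# Methods

## The occupancy statistic

A class reconstruction is a 3D density map on an absolute gray scale
(unsharpened output of 3D refinement), with a reference atomic model
rigid-body fitted into it. For a structural feature *f* — an r-protein
chain, an rRNA helix, or an rRNA domain — the occupancy is the
fraction of *f*'s heavy (non-hydrogen) atoms whose interpolated map
value strictly exceeds a threshold τ:

O(f) = |{a ∈ f : ρ(x_a) > τ}| / |f|.

Choices fixed by this definition:

- **Interpolation** is trilinear on the 8 surrounding voxels, after
  converting Å coordinates to fractional voxel coordinates using the
  map origin (position of the center of voxel (0,0,0)) and voxel size.
  Points outside the hull spanned by voxel centers return exactly 0:
  an atom outside the reconstructed box is not supported by density,
  and it stays in the denominator.
- **Strict inequality** at the threshold. The choice is immaterial at
  float granularity but must be fixed for exact tests.
- **Low-pass first.** Maps are filtered to 5 Å before scoring so that
  sub-voxel misalignments between map and model do not desert
  well-ordered features. The filter is a Fourier radial mask passing
  |k| < 1/resolution with a raised-cosine roll-off (default width
  2 Fourier pixels). The edge avoids ringing while keeping the filter
  close to idempotent outside the roll-off band; the DC term is
  untouched, so the mean density is preserved. Whether a soft edge was
  part of the original protocol is not documented, so the edge width
  is an exposed parameter rather than a constant.
- **Defaults** τ = 0.05 and 5 Å, appropriate for unsharpened
  reconstructions on an absolute gray scale. The statistic is
  covariant under a common rescaling of map and threshold, which the
  tests assert.

Empty feature selections (a chain legitimately absent from a
salt-washed model) score 0 with a logged flag rather than NaN, because
downstream clustering needs complete matrices.

## Normalization

Raw occupancies of feature *f* across classes are divided by
D(f) = max(max_c O(f,c), M), with M the median over all matrix
entries. Features whose best observed occupancy exceeds the global
median therefore reach 1.0 somewhere; features never seen above the
median are scaled by M instead, so their noise floor is not inflated
to full scale. The published description of this rule is grammatically
ambiguous between "median of all entries" and "median of per-feature
medians"; the former (most literal) reading is the default and the
latter is available as `median_mode="per_feature"` for sensitivity
analysis. An all-zero matrix normalizes to all-zero with a warning.

## Manual categories

Visual quality calls for helix density — near-native, slightly
distorted, highly distorted, disordered — encode as 0.1, 0.085, 0.045,
0. These values sit on the same scale as raw occupancies of strong
features at τ = 0.05, so encoded and automated cells can be clustered
together. When a manual table is supplied, encoded values **replace**
the automated values for the listed (feature, class) cells before
normalization; replacement rather than averaging is this package's
decision, made so that a manual call is authoritative for its cell.

## Clustering

Classes (columns) and features (rows) of the normalized matrix are
clustered agglomeratively: Euclidean metric, complete linkage
(inter-cluster distance = maximum member pair distance). The
agglomerator is implemented directly so that its tie-breaking is part
of the contract — merge the minimum-distance pair, ties resolved to
the lexicographically smallest (left, right) node-index pair — because
library implementations leave tie order unspecified and the pipeline
promises byte-identical reruns. scipy's `linkage(..., "complete")`
serves as an independent cross-check in the tests (merge heights and
cophenetic matrices agree to 1e-9 on random instances), never as the
implementation.

Trees export as ultrametric Newick with each leaf at depth
root_height/2, so the patristic distance between two leaves equals
their merge height (the cophenetic distance). Cutting the tree into k
groups removes the k−1 highest merges, which is deterministic because
complete linkage is monotone.

Feature-row clustering is known to be sensitive to upstream parameters
(threshold, filtering, normalization, model choice); the pipeline
records every effective parameter in its report precisely so such
sensitivity can be audited.

## Disassembly ordering

A feature is *present* in a class when its normalized occupancy is at
least the presence threshold (default 0.5). Classes are ordered by
inclusion of their present-feature sets: A precedes B when at most
`slack` (default 0) of A's features are missing from B and B's set is
strictly larger. The strict size increase keeps the relation acyclic
for any slack; at slack 0 it is exact strict inclusion, a genuine
partial order. The transitive reduction (Hasse diagram) keeps covering
relations only, each edge annotated with the features gained, and the
maximal chains of the diagram — enumerated depth-first, returned in
lexicographic order, with a 10⁴-chain guard — are the candidate
disassembly paths. Classes with identical feature sets are
incomparable by construction.

This is a deliberate formalization of orderings that are usually drawn
by expert judgment. It replaces two qualitative judgments with
parameters (presence threshold, slack) and makes no claim to reproduce
any manually curated figure; whether a conformationally misfolded
feature should count as present is a flag for the caller, not a
decision this package can make.

## Solvent mask

The mask recipe: zero density outside a centered sphere (default
155 Å), low-pass to 15 Å, binarize above 0.012, binary-dilate by
5 voxels (Euclidean ball, via distance transform), and append a cosine
soft edge falling 1 → 0 over 5 voxels of Euclidean distance. The
sphere is centered on the geometric center of the box (reconstructions
are box-centered). The output is 1 on the dilated binary set, 0 beyond
the soft shell, and monotone in between.

## Pixel-size calibration

The nominal pixel size of a map can be off by a percent or two; the
scan recovers the calibrated value by maximizing the real-space
map–model correlation. For each candidate scale the model coordinates
are rescaled about the box center, rasterized as Gaussian atoms
(σ = resolution/π at the working low-pass, the standard
resolution-to-width heuristic), and correlated with the map over the
model region (voxels above 5 % of the rasterization's maximum). The
optimum of a uniform scan is refined by parabolic interpolation
through the best three samples; calibrated voxel size =
nominal / best scale. A maximum on the scan boundary or a best
correlation below 0.2 flags the result unconverged (a pure-noise map
triggers this).

## Synthetic data

The generator emulates the regime the pipeline is built for: one
shared model whose features appear per class at full, partial,
shifted, or zero occupancy, on nested (or two-branch) present-feature
sets, with additive Gaussian noise on an absolute-like gray scale.

- **Toy model geometry.** Features are compact clusters of heavy atoms
  (4-atom pseudo-residues; helices share one rRNA-like chain, proteins
  get their own chains). Atoms sit on a jittered sub-lattice
  (pitch 5.5 Å, jitter ±0.5 Å) inside a ball, giving ≥ ~4.5 Å
  intra-feature spacing; cluster centers sit on a lattice spaced so
  the nearest atoms of distinct features are ≥ 8 Å apart (verified by
  brute force). The spacing is what makes the statistic *calibrated*:
  after the 5-Å low-pass, a deleted atom's position genuinely drops
  below threshold instead of riding on its neighbors' density, and an
  absent feature feels nothing from its neighbors.
- **States.** full rasterizes all atoms; partial(α) retains a seeded
  random subset of round(α·n) atoms — deletion rather than density
  scaling, so the expected recovered occupancy equals the retained
  fraction wherever the threshold sits between the noise floor and
  the working density; shifted(δ) rigidly translates the feature
  (used to emulate distorted elements; its occupancy depends on δ
  versus resolution and is deliberately not asserted); absent
  contributes nothing.
- **Amplitude calibration.** The volume is scaled so a fully occupied
  feature's atom-center values average `peak_density` (default 0.12)
  *after* low-pass filtering to the working resolution — the scale on
  which the 0.05 threshold operates. Gaussian atoms use σ = 3.5/π Å
  (a nominal 3.5-Å detail level). Noise default is σ = 0.01, placing
  truth comfortably off the decision boundary (0.12 vs 0.05 vs
  ~0.02 residual at deleted positions).
- **Series layout.** The linear series plants nested feature sets
  whose sizes fall in three blocks separated by ≥ 4 features with ≤ 1
  feature variation inside a block — the planted small/medium/large
  partition that a k = 3 complete-linkage cut must recover exactly.
  Each class's newest feature is planted at α = 0.7 so matrices
  exercise non-binary values. The branching series grows a 3-feature
  core along two disjoint feature pools that reunite in a top class: a
  diamond-shaped inclusion order with exactly two maximal chains.
  Default problem sizes (6–8 classes, 13–19 features, 12–20 atoms per
  feature, ~80³-voxel maps at 1.1 Å) keep a full simulated series
  around a second of compute while leaving every recovery margin
  wide.
- **Manifests** record seed, states, expected occupancies, present
  sets, planted groups, Hasse edges, maximal chains, and the peak
  density of every written map. Identical seeds reproduce maps
  bitwise.

What the generator does **not** emulate: CTF effects, projection and
reconstruction artifacts, orientation-dependent resolution
anisotropy, correlated (non-white) noise, partial *density* (as
opposed to partial atom sets), and real rRNA helix geometry. Passing
recovery tests therefore demonstrates the correctness and calibration
of the statistics and graph algorithms — not robustness to every
failure mode of experimental reconstructions.

## Hairpin detection

The detector asks a narrow question: can a strand segment form a
single contiguous stem-loop? Pairs are Watson–Crick (AU, GC) plus, by
default, GU wobble; the stem extends inward from a candidate closing
pair until the first mismatch or until the loop would drop below
`min_loop` (default 3 nt); stems shorter than 2 bp are not hairpins.
Ties prefer the smaller loop, then the 5′-most stem. This is
deliberately not minimum-free-energy folding — the question is
existence of a competing local stem, not the full structure ensemble.
One caveat: stem length is invariant under reverse-complementation
only for pure Watson–Crick pairing (a GU pair maps to AC under
reverse-complement), so that invariance is only asserted with wobble
disabled.

## File formats and determinism

Maps are MRC/CCP4 2014, written mode 2 (32-bit float), voxel size in
CELLA/mx and the Å origin in the ORIGIN words; reading prefers ORIGIN
over nstart when both are present and permutes any axis order to
canonical x, y, z. Round trips are bitwise on data. Models are PDB or
mmCIF via gemmi (highest-occupancy altloc kept, waters dropped).
Segmentations and matrices are TSV; trees are Newick; graphs are JSON
and Graphviz DOT. All randomness flows from explicit integer seeds,
and `run_profile` writes byte-identical artifacts for identical
inputs and configuration.

## Known limitations

- The pipeline does not fit the model to each map; it consumes
  pre-aligned models (optionally one transform per class) and the
  pixel-size scan assumes the model is already roughly aligned.
- Occupancy conflates disorder with displacement: a feature shifted
  by more than the low-pass resolution scores low even though its
  density exists elsewhere. The shifted synthetic state exists
  precisely to probe this.
- The manual-category encoding maps an ordinal scale onto occupancy
  values; distances that mix encoded and automated cells inherit that
  arbitrariness.
- The inclusion order depends on the presence threshold; near-0.5
  normalized occupancies can flip edges. The slack parameter trades
  robustness against the strictness of the partial order.
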