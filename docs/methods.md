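# Methods

## Model and procedure

A DRM list is characterized by a *theme location* — the centroid of its
studied items in the input vector space — and by how the remaining items
are arranged around it. All proximity is cosine distance
d(u, v) = 1 − cos∠(u, v) ∈ [0, 2]; rankings are computed in double
precision, compared exactly, and ties broken lexicographically by label so
every run is reproducible across platforms. Centroids are raw arithmetic
means, never renormalized: cosine distance is invariant to the scale of
the reference, so renormalization could not change any ranking and the raw
mean is the simpler contract.

Generation proceeds in four stages (seeding → close-space construction →
lure selection → target sampling); the README sketches them, this note
records the decisions underneath.

### Seeding

k-means runs on unit-normalized vectors with Euclidean metric (on the unit
sphere this orders item pairs identically to cosine), k-means++
initialization, 10 restarts, 300-iteration cap. k is drawn uniformly from
{N_L, …, N_L + 3} (capped at the vocabulary size) and the first N_L
centroids in the clustering's output order are retained — the surplus
centroids and arbitrary output order are deliberate sources of between-run
variability in which regions become lists. If two retained centroids map
to the same nearest item, the later one takes its next-nearest item so
seeds stay distinct.

### Close-space construction

The loop re-derives the close space from the current center, resamples the
full studied set each iteration, recenters on the sample centroid, and
accepts only when (i) the farthest studied item is the rank-N_CS neighbor
of the final centroid among eligible items and (ii) under classical
selection the rank-1 neighbor is unstudied. Acceptance is a stochastic
event (per-iteration probability a few percent in realistic geometries),
hence the 500-iteration budget per start item. Start items are attempted
in neighbor order of the originating cluster centroid; after 50 exhausted
candidates the list fails with a diagnosable error rather than spinning.

### Lure selection

*Random:* uniform draws from the non-studied close space (critical) and
from the globally eligible far pool (unrelated). The far pool excludes the
close spaces of **all** lists and every already-selected item, and is
additionally filtered to strict distance > close_radius of the current
list — redundant except under exact distance ties at the boundary, where
the strict "farther than every studied item" guarantee must win.

*Distributed:* the non-studied close-space candidates are sorted by
distance; their occupied range [d_nearest, close_radius] is tiled by N_CL
contiguous bins and the far range (close_radius, d_max] by N_UL further
bins, all widths forming one geometric progression w, wr, wr², …. The
ratio satisfies

    r^N_CL (r^N_UL − 1) / (r^N_CL − 1) = far_span / close_span,

whose left side is continuous and strictly increasing in r on (0, ∞), so
the root is unique; it is found by Brent bisection with the r = 1
(uniform) limit handled analytically and r < 1 admitted when the far span
is proportionally narrower. One lure is drawn uniformly per bin; under
classical selection the rank-1 neighbor occupies its containing bin. Bins
are anchored at the nearest *candidate*, not at distance zero: in high
dimension no item can lie arbitrarily close to a 15-item centroid (the
nearest candidate typically sits at 50–60 % of the close radius), so bins
anchored at zero would be structurally empty and the method could never
terminate. Anchoring at the occupied range preserves every stated
property: a single ratio across the close–far boundary, one lure per bin,
and exact degeneration to the random method at N_CL = N_UL = 1.

An empty bin triggers a resample of that list's study set (fresh
close-space construction) up to 20 times before the configuration is
declared infeasible, mirroring the restart philosophy of the close-space
loop.

### Orchestration and exclusivity

The far pool depends on *every* list's close space, so generation is
two-phase: all study sets are built sequentially under a growing used-item
exclusion set (with each list's forced critical lure reserved at build
time so no later list can consume it), then lures are selected per list
against the union of all close spaces. Each list records the exclusion set
it was built under (`build_excluded`), which makes every geometric claim —
"farthest studied at rank N_CS", "rank-1 neighbor is a critical lure" —
re-derivable from the space alone; those claims are stated relative to the
items eligible at build time, since items consumed by other lists are by
definition unavailable as this list's lures. When a distributed-bin
resample rebuilds a list's study set, its own prior selections are rolled
back but other lists are untouched; an unrelated lure chosen earlier may
then fall inside the rebuilt list's close *radius* (never its close-space
item set) — a deliberate trade against cascading rollbacks.

### Randomness

One master seed expands into independent named substreams (clustering,
study sampling, lure draws, target draws) via seed-sequence spawning; the
feasibility simulation runs on a fifth, separate stream, so checking
feasibility can never perturb a subsequent real run. Identical
configuration + seed ⇒ byte-identical output files.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| N_L (`n_lists`) | lists to generate | — (required) | experiment-specific |
| N_CS (`close_space_size`) | items forming each close space | 50 | the validated classical configuration; must be ≥ N_S + N_CL |
| N_S (`n_studied`) | studied items per list | 15 | classical DRM list length |
| N_T (`n_targets`) | studied items re-shown at recognition | 6 | ≤ N_S |
| N_CL (`n_critical`) | critical lures per list | 1 | classical design; 3 for continuous-similarity designs |
| N_UL (`n_unrelated`) | unrelated lures per list | 5 | false-alarm baseline |
| `method` | random / distributed | random | random suits small spaces; distributed needs room in every bin |
| `classical_critical_lure` | force the centroid's first neighbor as a lure | on | classical DRM semantics |
| `seed` | master seed | 0 | reproducibility |

Screening threshold: A′ < 0.7 excludes (strict, so exactly 0.7 is kept);
distances print with six decimals; vector files are written with six
decimal places, bounding round-trip error by 5 × 10⁻⁷ per value.

## The synthetic space

`make_synthetic_space` emulates the neighborhood structure of a
distributional semantic model: unit-length cluster directions plus
isotropic Gaussian noise of scale `within_spread`, renormalized. Defaults
(12 clusters × 500 items, 50 dimensions, spread 0.15) give well-separated
clusters in which seeding, close-space construction and lure selection all
operate as they would on a real embedding lexicon. The large demonstration
space uses 34 × 229 = 7,786 items (a realistic dominant-lemma vocabulary
size) at spread 0.35.

What it does **not** emulate: real embedding spaces are anisotropic, have
hubness, frequency-correlated norms and uneven cluster sizes. One concrete
consequence: at 300 dimensions isotropic clusters concentrate so sharply
that a 15-item sample's centroid is strictly closer to its own sample than
to any other item, making the rank-N_CS acceptance criterion unreachable —
which is why synthetic demonstrations run at 50 dimensions. Real
high-dimensional embeddings do not exhibit this failure because their
local density varies. Passing tests therefore establish the correctness of
the selection geometry and its invariants, not distributional claims about
any particular embedding model.

## Numerical choices and degenerate inputs

- Zero-norm vectors are rejected at load time (cosine undefined); labels
  must be non-empty, whitespace-free and unique; tab-containing labels are
  rejected for TSV safety at the parsing layer (whitespace rule).
- Distance clipping to [−1, 1] cosine guards accumulated rounding.
- `N_CS = N_S` (no classical flag) is a legal degenerate call of the
  study-set builder: the close space is exactly the studied set.
- `N_UL = 0` is allowed; the distributed method then tiles only the close
  region uniformly.
- The bin-ratio root is polished to ~1e-15 relative tolerance; bin edges
  are constructed from (w, r) so consecutive width ratios are exact to
  machine precision, and the region boundaries are pinned exactly to
  close_radius and d_max.

## Known limitations

- The close-space loop's acceptance probability degrades as dimensionality
  grows or local density flattens; the restart ladder makes failure
  explicit but cannot manufacture geometry that is not there.
- Feasibility checking is a bounded simulation: "feasible" means one
  capped trial succeeded, not a proof; "infeasible" reports the first
  binding constraint encountered.
- Lists are matched only on similarity geometry — psycholinguistic
  covariates (frequency, length, concreteness) are out of scope and should
  be controlled at the vector-space or post-selection stage.
- Only the closed-form statistics (A′, evidence ratios) are implemented;
  mixed-model estimation belongs to a statistics environment.
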