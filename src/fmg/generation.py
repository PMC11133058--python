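"""The list-generation routine.

For every requested list the routine grows a *close space* around a seed
item: the ``N_CS`` items nearest a working center.  ``N_S`` studied items
are sampled from it, their centroid becomes the new center, and the loop
repeats until the farthest studied item sits at neighbor rank exactly
``N_CS`` of the final centroid (so the close space is exactly the region
spanned by the studied set) and, when classical critical-lure selection is
on, the centroid's first neighbor is not itself studied.  After 500
unsuccessful iterations the whole selection restarts from the next-nearest
item to the original cluster center.

Critical lures are then drawn from the close space and unrelated lures
from the far space (everything outside every list's close space), either
uniformly (*random* method) or stratified over geometrically-widening
distance bins tiling both regions with a single common ratio
(*distributed* method).  A global exclusion set guarantees that no item
appears in two lists in any role.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError, GenerationError, InfeasibleError
from .geometry import _distances_to, _ranked_indices
from .seeding import find_list_seeds
from .space import VectorSpace

__all__ = [
    "GenerationConfig",
    "DRMList",
    "FeasibilityReport",
    "build_study_set",
    "select_lures_random",
    "select_lures_distributed",
    "generate_lists",
    "check_feasibility",
]

#: iterations of the close-space loop before moving to the next start item
MAX_ITERATIONS = 500
#: start items attempted (in neighbor order of the cluster center) before failure
MAX_STARTS = 50
#: study-set resamples allowed when a distributed bin comes up empty
MAX_BIN_RESAMPLES = 20

METHODS = ("random", "distributed")

# config-file / UI parameter names, used in validation messages
_PARAM_NAMES = {
    "n_lists": "Number of Lists",
    "close_space_size": "Close Space Items",
    "n_studied": "Studied Items",
    "n_targets": "Target Items",
    "n_critical": "Critical Lures",
    "n_unrelated": "Unrelated Lures",
}


@dataclass(frozen=True)
class GenerationConfig:
    """All user parameters of a generation run.

    Validation is explicit (:meth:`validate`), not performed at
    construction, so feasibility checking can report structural problems
    instead of raising.
    """

    n_lists: int
    close_space_size: int = 50
    n_studied: int = 15
    n_targets: int = 6
    n_critical: int = 1
    n_unrelated: int = 5
    method: str = "random"
    classical_critical_lure: bool = True
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`~fmg.errors.ConfigError` naming any violated constraint."""
        for f in ("n_lists", "close_space_size", "n_studied", "n_targets",
                  "n_critical"):
            if getattr(self, f) < 1:
                raise ConfigError(f"{_PARAM_NAMES[f]} ({f}) must be >= 1")
        if self.n_unrelated < 0:
            raise ConfigError("Unrelated Lures (n_unrelated) must be >= 0")
        if self.close_space_size < self.n_studied + self.n_critical:
            raise ConfigError(
                "Close Space Items (close_space_size) must be greater than or "
                "equal to the sum of Studied Items and Critical Lures"
            )
        if self.n_targets > self.n_studied:
            raise ConfigError(
                "Target Items (n_targets) cannot exceed the number chosen for "
                "the Studied Items (n_studied)"
            )
        if self.method not in METHODS:
            raise ConfigError(f"selection method must be one of {METHODS}")

    def replace(self, **kw) -> "GenerationConfig":
        return _dc_replace(self, **kw)


@dataclass
class DRMList:
    """One generated stimulus list.

    ``studied`` is ordered by descending similarity to the centroid
    (ascending cosine distance); ``targets`` is the studied subset shown
    again at recognition; ``close_space`` holds the ``N_CS`` labels nearest
    the centroid among items eligible when the list was built
    (``build_excluded`` records the ineligible labels so every geometric
    claim can be re-derived from the space alone).
    """

    list_id: int
    seed_item: str
    studied: list[str]
    centroid: np.ndarray
    close_radius: float
    close_space: list[str]
    nearest_neighbor: str
    build_excluded: frozenset
    restarts: int = 0
    targets: list[str] = field(default_factory=list)
    critical_lures: list[str] = field(default_factory=list)
    unrelated_lures: list[str] = field(default_factory=list)
    bin_edges: np.ndarray | None = None  # distributed method only
    bin_ratio: float | None = None

    def distance(self, space: VectorSpace, label: str) -> float:
        """Cosine distance of one item to this list's studied-set centroid."""
        return float(_distances_to(space, self.centroid)[space.index(label)])


@dataclass
class FeasibilityReport:
    """Verdict of the preliminary simulation for one selection method."""

    method: str
    feasible: bool
    limiting_constraint: str | None = None
    suggested_edits: dict = field(default_factory=dict)


def _streams(root: np.random.SeedSequence) -> dict[str, np.random.Generator]:
    keys = ("clustering", "study", "lures", "targets")
    return {k: np.random.default_rng(c) for k, c in zip(keys, root.spawn(len(keys)))}


def build_study_set(
    space: VectorSpace,
    seed_item: str,
    config: GenerationConfig,
    rng: np.random.Generator,
    excluded=frozenset(),
    center: np.ndarray | None = None,
    list_id: int = 1,
    max_starts: int = MAX_STARTS,
) -> DRMList:
    """Grow a study set and its close space around a seed item.

    ``center`` is the originating cluster centroid used to order restart
    candidates; it defaults to the seed item's own vector (the seed is the
    item nearest that centroid).  Returns a partial :class:`DRMList`
    (lures and targets unfilled).  Deterministic per ``rng`` state.
    """
    n_cs, n_s = config.close_space_size, config.n_studied
    excluded = frozenset(excluded)
    if seed_item in excluded:
        raise GenerationError(f"seed item {seed_item!r} is excluded")
    mask = np.ones(len(space), dtype=bool)
    for l in excluded:
        mask[space.index(l)] = False
    n_eligible = int(mask.sum())
    if n_eligible < n_cs:
        raise InfeasibleError(
            f"list {list_id}: only {n_eligible} eligible items but the close "
            f"space needs {n_cs}"
        )

    center_vec = np.asarray(
        center if center is not None else space.vector(seed_item), dtype=np.float64
    )
    start_order, _ = _ranked_indices(space, center_vec, mask)
    ranks = np.empty(len(space), dtype=np.int64)

    for restart, start_idx in enumerate(start_order[:max_starts]):
        cur = space.vectors[start_idx]
        for _ in range(MAX_ITERATIONS):
            order, _ = _ranked_indices(space, cur, mask)
            pick = rng.choice(n_cs, size=n_s, replace=False)
            studied_idx = order[:n_cs][pick]
            cen = space.vectors[studied_idx].mean(axis=0)

            order2, dists2 = _ranked_indices(space, cen, mask)
            ranks[order2] = np.arange(1, len(order2) + 1)
            max_rank = int(ranks[studied_idx].max())
            ok = max_rank == n_cs
            if ok and config.classical_critical_lure:
                ok = int(order2[0]) not in set(int(i) for i in studied_idx)
            if ok:
                studied_sorted = studied_idx[np.argsort(ranks[studied_idx])]
                return DRMList(
                    list_id=list_id,
                    seed_item=seed_item,
                    studied=[space.labels[int(i)] for i in studied_sorted],
                    centroid=cen,
                    close_radius=float(dists2[n_cs - 1]),
                    close_space=[space.labels[int(i)] for i in order2[:n_cs]],
                    nearest_neighbor=space.labels[int(order2[0])],
                    build_excluded=excluded,
                    restarts=restart,
                )
            cur = cen
    criterion = (
        "close-space size and classical critical-lure"
        if config.classical_critical_lure
        else "close-space size"
    )
    raise GenerationError(
        f"list {list_id}: no start item among the {max_starts} nearest to the "
        f"cluster center satisfied the {criterion} criteria"
    )


def _far_pool(
    space: VectorSpace,
    plist: DRMList,
    used: set,
    close_space_union: set,
) -> tuple[list[str], np.ndarray]:
    """Eligible far-space labels for one list, with distances to its centroid.

    Far items lie outside every list's close space, are unused in any role,
    and are strictly farther from this list's centroid than its farthest
    studied item.  Sorted ascending by (distance, label).
    """
    dists = _distances_to(space, plist.centroid)
    cands = [
        (float(dists[space.index(l)]), l)
        for l in space.labels
        if l not in close_space_union and l not in used
    ]
    cands = [(d, l) for d, l in cands if d > plist.close_radius]
    cands.sort()
    return [l for _, l in cands], np.array([d for d, _ in cands])


def _close_candidates(plist: DRMList, globally_excluded: set) -> list[str]:
    studied = set(plist.studied)
    return [
        l
        for l in plist.close_space  # already ascending distance
        if l not in studied and l not in globally_excluded
    ]


def select_lures_random(
    space: VectorSpace,
    plist: DRMList,
    config: GenerationConfig,
    rng: np.random.Generator,
    globally_excluded=frozenset(),
    close_space_union: set | None = None,
) -> tuple[list[str], list[str]]:
    """Uniform lure selection.

    Critical lures are drawn without replacement from the non-studied
    close-space items (the centroid's first neighbor is forced in when
    classical selection is on); unrelated lures from the far pool — items
    outside every list's close space and unused in any role.
    """
    if close_space_union is None:
        close_space_union = set(plist.close_space)
    globally_excluded = set(globally_excluded)

    cands = _close_candidates(plist, globally_excluded)
    crit: list[str] = []
    if config.classical_critical_lure:
        if plist.nearest_neighbor not in cands:
            raise InfeasibleError(
                f"list {plist.list_id}: forced critical lure "
                f"{plist.nearest_neighbor!r} is no longer available"
            )
        crit.append(plist.nearest_neighbor)
        cands = [l for l in cands if l != plist.nearest_neighbor]
    n_more = config.n_critical - len(crit)
    if len(cands) < n_more:
        raise InfeasibleError(
            f"list {plist.list_id}: close space has {len(cands)} free items "
            f"but {n_more} more critical lures are needed"
        )
    if n_more:
        crit += [cands[int(i)] for i in rng.choice(len(cands), n_more, replace=False)]

    far_labels, _ = _far_pool(
        space, plist, globally_excluded | set(crit), close_space_union
    )
    if len(far_labels) < config.n_unrelated:
        raise InfeasibleError(
            f"list {plist.list_id}: far space has {len(far_labels)} free items "
            f"but {config.n_unrelated} unrelated lures are needed"
        )
    unrel = (
        [far_labels[int(i)]
         for i in rng.choice(len(far_labels), config.n_unrelated, replace=False)]
        if config.n_unrelated
        else []
    )
    return crit, unrel


def solve_bin_ratio(close_span: float, far_span: float,
                    n_close: int, n_far: int) -> float:
    """Common ratio of the geometric bin widths tiling both regions.

    The close span is tiled by ``n_close`` bins of widths w, w*r, ...,
    and the far span by ``n_far`` further bins continuing the same
    progression.  Eliminating w leaves a single monotone equation in r,

        r**n_close * (r**n_far - 1) / (r**n_close - 1) = far_span / close_span,

    solved by bisection (Brent).  r = 1 (uniform widths) is the exact
    solution when the spans are in the ratio n_far : n_close; r < 1 occurs
    when the far span is proportionally narrower.
    """
    if close_span <= 0 or far_span <= 0:
        raise InfeasibleError("empty close or far span: cannot place bins")
    target = far_span / close_span
    balanced = n_far / n_close
    if abs(target - balanced) <= 1e-12 * balanced:
        return 1.0

    def f(r: float) -> float:
        return r ** n_close * (r ** n_far - 1.0) / (r ** n_close - 1.0) - target

    if target > balanced:
        lo, hi = 1.0 + 1e-12, 2.0
        while f(hi) < 0:
            hi *= 2.0
            if hi > 1e12:
                raise GenerationError("bin-ratio bracket expansion failed")
    else:
        lo, hi = 0.5, 1.0 - 1e-12
        while f(lo) > 0:
            lo *= 0.5
            if lo < 1e-12:
                raise GenerationError("bin-ratio bracket expansion failed")
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-15))


def _bin_edges(close_lo: float, close_radius: float, d_max: float,
               n_close: int, n_far: int) -> tuple[np.ndarray, float]:
    """Edges of the n_close + n_far geometric bins over [close_lo, d_max].

    ``close_lo`` is the distance of the nearest eligible close-space
    candidate: bins tile the occupied candidate range, not the empty
    region around the centroid (which, in high dimension, no item can
    reach).  The first ``n_close`` bins end exactly at ``close_radius``;
    the remaining ``n_far`` bins continue the same width progression up to
    ``d_max``.
    """
    close_span = close_radius - close_lo
    r = solve_bin_ratio(close_span, d_max - close_radius, n_close, n_far)
    n = n_close + n_far
    if r == 1.0:
        w = close_span / n_close
        edges = close_lo + np.concatenate(([0.0], w * np.arange(1, n + 1)))
    else:
        w = close_span * (r - 1.0) / (r ** n_close - 1.0)
        i = np.arange(1, n + 1)
        edges = close_lo + np.concatenate(([0.0], w * (r ** i - 1.0) / (r - 1.0)))
    edges[n_close] = close_radius  # exact region boundary
    edges[-1] = d_max
    return edges, r


def _draw_from_bins(
    labels: list[str],
    dists: np.ndarray,
    edges: np.ndarray,
    rng: np.random.Generator,
    forced: dict[int, str],
    what: str,
    list_id: int,
) -> list[str]:
    """One uniform draw per bin; ``forced`` maps bin index -> mandatory item."""
    chosen: list[str] = []
    for b in range(len(edges) - 1):
        lo, hi = edges[b], edges[b + 1]
        if b in forced:
            chosen.append(forced[b])
            continue
        in_bin = [
            l
            for l, d in zip(labels, dists)
            if (lo < d <= hi or (b == 0 and d <= hi)) and l not in chosen
        ]
        in_bin = [l for l in in_bin if l not in forced.values()]
        if not in_bin:
            raise InfeasibleError(
                f"list {list_id}: empty {what} bin over distance interval "
                f"({lo:.6f}, {hi:.6f}]"
            )
        chosen.append(in_bin[int(rng.integers(len(in_bin)))])
    return chosen


def select_lures_distributed(
    space: VectorSpace,
    plist: DRMList,
    config: GenerationConfig,
    rng: np.random.Generator,
    globally_excluded=frozenset(),
    close_space_union: set | None = None,
) -> tuple[list[str], list[str], np.ndarray, float]:
    """Distance-stratified lure selection.

    The occupied close region [d_nearest_candidate, close_radius] is tiled
    by ``N_CL`` contiguous bins whose widths form a geometric sequence,
    and the far region (close_radius, d_max] by ``N_UL`` further bins
    continuing the same progression; one lure is drawn uniformly from each
    bin.  Returns (critical_lures, unrelated_lures, bin_edges, ratio).
    """
    if close_space_union is None:
        close_space_union = set(plist.close_space)
    globally_excluded = set(globally_excluded)

    close_cands = _close_candidates(plist, globally_excluded)
    if len(close_cands) < config.n_critical:
        raise InfeasibleError(
            f"list {plist.list_id}: close space has {len(close_cands)} free "
            f"items but {config.n_critical} critical lures are needed"
        )
    far_labels, far_dists = _far_pool(
        space, plist, globally_excluded, close_space_union
    )
    if len(far_labels) < config.n_unrelated:
        raise InfeasibleError(
            f"list {plist.list_id}: far space has {len(far_labels)} free items "
            f"but {config.n_unrelated} unrelated lures are needed"
        )
    close_dists = np.array([plist.distance(space, l) for l in close_cands])
    close_lo = float(close_dists.min())
    if close_lo >= plist.close_radius:
        raise InfeasibleError(
            f"list {plist.list_id}: close-space candidates span no distance "
            f"range (all at the boundary)"
        )
    d_max = float(far_dists[-1]) if len(far_dists) else plist.close_radius
    if config.n_unrelated == 0:
        # degenerate: only the close region is binned (uniform tiling)
        w = (plist.close_radius - close_lo) / config.n_critical
        edges = close_lo + np.concatenate(
            ([0.0], w * np.arange(1, config.n_critical + 1))
        )
        edges[-1] = plist.close_radius
        ratio = 1.0
    else:
        edges, ratio = _bin_edges(
            close_lo, plist.close_radius, d_max,
            config.n_critical, config.n_unrelated,
        )

    close_edges = edges[: config.n_critical + 1]
    forced: dict[int, str] = {}
    if config.classical_critical_lure:
        nn = plist.nearest_neighbor
        if nn not in close_cands:
            raise InfeasibleError(
                f"list {plist.list_id}: forced critical lure {nn!r} is no "
                f"longer available"
            )
        d_nn = plist.distance(space, nn)
        b = int(np.searchsorted(close_edges[1:], d_nn, side="left"))
        forced[min(b, config.n_critical - 1)] = nn
    crit = _draw_from_bins(
        close_cands, close_dists, close_edges, rng, forced,
        "close-space", plist.list_id,
    )

    if config.n_unrelated:
        far_edges = edges[config.n_critical:]
        unrel = _draw_from_bins(
            far_labels, far_dists, far_edges, rng, {}, "far-space",
            plist.list_id,
        )
    else:
        unrel = []
    return crit, unrel, edges, ratio


def _own_labels(plist: DRMList, config: GenerationConfig) -> set:
    own = set(plist.studied)
    if config.classical_critical_lure:
        own.add(plist.nearest_neighbor)
    own |= set(plist.critical_lures) | set(plist.unrelated_lures)
    return own


def generate_lists(
    space: VectorSpace,
    config: GenerationConfig,
    _root: np.random.SeedSequence | None = None,
    max_starts: int = MAX_STARTS,
    stats: dict | None = None,
) -> list[DRMList]:
    """Run the full routine: seeds, study sets, lures, targets.

    A single master seed expands into independent named substreams
    (clustering, study sampling, lure draws, target draws), and a global
    exclusion set guarantees that no item appears in two lists in any role.
    Deterministic per ``config.seed``.
    """
    config.validate()
    if len(space) < config.n_lists * config.close_space_size:
        raise InfeasibleError(
            f"space has {len(space)} items; {config.n_lists} lists x "
            f"{config.close_space_size} close-space items need at least "
            f"{config.n_lists * config.close_space_size}"
        )
    root = _root if _root is not None else np.random.SeedSequence(config.seed)
    streams = _streams(root)

    seeds = find_list_seeds(space, config.n_lists, streams["clustering"])
    if stats is not None:
        stats["k_used"] = seeds.k_used
    used: set = set()
    lists: list[DRMList] = []

    def _build(list_id: int) -> DRMList:
        center = seeds.centers[list_id - 1]
        label = seeds.labels[list_id - 1]
        if label in used:  # seed consumed by an earlier list: take nearest free
            mask = np.array([l not in used for l in space.labels])
            order, _ = _ranked_indices(space, center, mask)
            label = space.labels[int(order[0])]
        p = build_study_set(
            space, label, config, streams["study"], excluded=frozenset(used),
            center=center, list_id=list_id, max_starts=max_starts,
        )
        used.update(p.studied)
        if config.classical_critical_lure:
            used.add(p.nearest_neighbor)  # reserve the forced critical lure
        return p

    for i in range(1, config.n_lists + 1):
        lists.append(_build(i))

    close_union = set().union(*(set(p.close_space) for p in lists))

    for i, p in enumerate(lists):
        for attempt in range(MAX_BIN_RESAMPLES):
            other_used = used - _own_labels(p, config)
            try:
                if config.method == "random":
                    crit, unrel = select_lures_random(
                        space, p, config, streams["lures"], other_used,
                        close_union,
                    )
                else:
                    crit, unrel, edges, ratio = select_lures_distributed(
                        space, p, config, streams["lures"], other_used,
                        close_union,
                    )
                    p.bin_edges, p.bin_ratio = edges, ratio
                break
            except InfeasibleError as exc:
                if config.method == "random" or attempt == MAX_BIN_RESAMPLES - 1:
                    raise InfeasibleError(
                        f"lure selection failed ({config.method} method): {exc}"
                    ) from exc
                # empty distributed bin: resample this list's study set
                used.difference_update(_own_labels(p, config))
                p = _build(p.list_id)
                lists[i] = p
                close_union = set().union(*(set(q.close_space) for q in lists))
        p.critical_lures, p.unrelated_lures = crit, unrel
        used.update(crit)
        used.update(unrel)
        pick = streams["targets"].choice(
            config.n_studied, size=config.n_targets, replace=False
        )
        p.targets = [p.studied[int(j)] for j in sorted(pick)]
    return lists


_EDIT_KEYS = {
    "n_lists": "number_of_lists",
    "close_space_size": "close_space_items",
    "n_targets": "target_items",
}


def check_feasibility(
    space: VectorSpace, config: GenerationConfig
) -> dict[str, FeasibilityReport]:
    """Preliminary simulation: can each selection method fill this config?

    Structural violations are reported (not raised), an obvious counting
    shortfall is caught without simulation, and otherwise a capped trial
    generation is attempted on an rng stream independent of any subsequent
    real run.  Infeasible verdicts carry the binding constraint and
    suggested parameter edits.
    """
    reports: dict[str, FeasibilityReport] = {}
    for method in METHODS:
        cfg = config.replace(method=method)
        try:
            cfg.validate()
        except ConfigError as exc:
            edits: dict = {}
            if cfg.close_space_size < cfg.n_studied + cfg.n_critical:
                edits["close_space_items"] = cfg.n_studied + cfg.n_critical
            if cfg.n_targets > cfg.n_studied:
                edits["target_items"] = cfg.n_studied
            if not edits:
                edits["close_space_items"] = max(
                    cfg.close_space_size, cfg.n_studied + cfg.n_critical
                )
            reports[method] = FeasibilityReport(
                method=method, feasible=False,
                limiting_constraint=str(exc), suggested_edits=edits,
            )
            continue
        need = cfg.n_lists * cfg.close_space_size
        if len(space) < need:
            reports[method] = FeasibilityReport(
                method=method, feasible=False,
                limiting_constraint=(
                    f"vocabulary size: the space has {len(space)} items but "
                    f"{cfg.n_lists} lists x {cfg.close_space_size} close-space "
                    f"items need at least {need}"
                ),
                suggested_edits={
                    "number_of_lists": max(1, len(space) // cfg.close_space_size),
                    "close_space_items": max(
                        cfg.n_studied + cfg.n_critical,
                        len(space) // cfg.n_lists,
                    ),
                },
            )
            continue
        trial_root = np.random.SeedSequence(cfg.seed).spawn(5)[4]
        try:
            generate_lists(space, cfg, _root=trial_root, max_starts=10)
        except (GenerationError, InfeasibleError) as exc:
            reports[method] = FeasibilityReport(
                method=method, feasible=False,
                limiting_constraint=str(exc),
                suggested_edits={
                    "number_of_lists": max(1, cfg.n_lists - 1),
                    "close_space_items": max(
                        cfg.n_studied + cfg.n_critical, cfg.close_space_size // 2
                    ),
                },
            )
        else:
            reports[method] = FeasibilityReport(method=method, feasible=True)
    return reports
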