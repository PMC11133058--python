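"""Generate classical DRM lists (one forced critical lure per list).

Builds a small clustered synthetic space, generates three lists with the
random selection method, and prints each list's items sorted by cosine
distance to the studied-set centroid.
"""

from fmg import GenerationConfig, generate_lists, make_synthetic_space

space = make_synthetic_space(
    n_clusters=8, items_per_cluster=150, dim=50, within_spread=0.15, seed=4
).space

config = GenerationConfig(
    n_lists=3, close_space_size=50, n_studied=15, n_targets=6,
    n_critical=1, n_unrelated=5, method="random",
    classical_critical_lure=True, seed=20,
)
lists = generate_lists(space, config)

for p in lists:
    print(f"\nList {p.list_id}  (close radius {p.close_radius:.4f})")
    rows = [(p.distance(space, l), l, "Studied" + (" +Target" if l in p.targets else ""))
            for l in p.studied]
    rows += [(p.distance(space, l), l, "Critical Lure") for l in p.critical_lures]
    rows += [(p.distance(space, l), l, "Unrelated Lure") for l in p.unrelated_lures]
    for d, label, role in sorted(rows):
        print(f"  {d:.4f}  {label:12s}  {role}")

# The critical lure is the item closest to the studied-set centroid (it was
# forced by the classical flag); every unrelated lure lies beyond the close
# radius, i.e. farther out than every studied item.
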