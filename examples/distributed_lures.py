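"""Distance-stratified lure selection with the distributed method.

Generates one list with three critical and three unrelated lures drawn
from geometrically widening distance bins, and prints the bin edges, the
common width ratio and where each lure landed.
"""

import numpy as np

from fmg import GenerationConfig, generate_lists, make_synthetic_space

space = make_synthetic_space(
    n_clusters=8, items_per_cluster=150, dim=50, within_spread=0.15, seed=4
).space

config = GenerationConfig(
    n_lists=1, close_space_size=50, n_studied=15, n_targets=6,
    n_critical=3, n_unrelated=3, method="distributed",
    classical_critical_lure=True, seed=33,
)
(p,) = generate_lists(space, config)

widths = np.diff(p.bin_edges)
print(f"bin ratio r = {p.bin_ratio:.4f}")
print("bin edges:", np.round(p.bin_edges, 4))
print("bin widths:", np.round(widths, 4), "(each width = previous x r)")
print(f"close radius = {p.close_radius:.4f} (bin 3 ends exactly there)")

for role, items in (("critical", p.critical_lures),
                    ("unrelated", p.unrelated_lures)):
    for l in items:
        d = p.distance(space, l)
        b = int(np.searchsorted(p.bin_edges[1:], d, side="left"))
        print(f"{role:9s} {l:12s} distance {d:.4f} -> bin {b + 1}")

# One lure per bin: the three critical lures are spread across the close
# space instead of clumping at its densest shell, and the unrelated lures
# continue the same geometric progression into the far space, giving the
# recognition phase a continuous gradient of similarity to the list theme.
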