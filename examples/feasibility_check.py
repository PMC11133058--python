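"""Preliminary feasibility simulation before committing to a configuration.

Asks for more lists than a small space can support and prints the per-
method verdicts with the suggested parameter edits.
"""

from fmg import GenerationConfig, check_feasibility, make_synthetic_space

space = make_synthetic_space(
    n_clusters=4, items_per_cluster=60, dim=20, within_spread=0.15, seed=9
).space
print(f"space: {len(space)} items")

config = GenerationConfig(n_lists=10, close_space_size=50, seed=5)
for method, report in check_feasibility(space, config).items():
    print(f"\n{method}: {'feasible' if report.feasible else 'infeasible'}")
    if not report.feasible:
        print("  constraint:", report.limiting_constraint)
        for key, value in report.suggested_edits.items():
            print(f"  suggest {key} = {value}")

# 10 lists x 50 close-space items need 500 items but only 240 exist; the
# report names the binding constraint and proposes counts that would fit.
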