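# fmg — data-driven DRM false-memory list generation

In the Deese–Roediger–McDermott (DRM) paradigm, participants study word
lists built around an unpresented *critical lure* (bed, rest, awake, … for
the lure *sleep*) and later falsely recognize that lure as "old".
Traditionally such lists are built from human free-association norms, which
exist for few languages, cover limited vocabularies, and cannot be extended
to non-verbal material. `fmg` replaces the norms with geometry: given **any
vector space** — word embeddings, visual features, sensorimotor ratings — it
selects Studied Items, Targets, Critical Lures and Unrelated Lures purely
from cosine similarity, for researchers in memory and psycholinguistics who
need controlled false-memory stimuli in arbitrary languages or modalities.

## The method

With cosine distance d(u, v) = 1 − u·v ⁄ (‖u‖‖v‖):

1. **Seeding.** k-means (k drawn from {N_L, …, N_L + 3}) partitions the
   space; the first N_L cluster centroids are kept and each is mapped to
   its nearest item, giving mutually dissimilar list seeds.
2. **Close space.** Around each seed, the N_CS nearest items form a
   candidate *close space*; N_S studied items are sampled from it and
   their centroid **c** becomes the new center. The loop repeats until the
   farthest studied item is exactly the rank-N_CS neighbor of **c** (the
   close space is precisely the region the studied set spans) and — with
   classical critical-lure selection — the rank-1 neighbor of **c** is not
   itself studied. After 500 failed iterations the process restarts from
   the next-nearest item to the original cluster center.
3. **Lures.** *Random method:* N_CL critical lures are drawn uniformly from
   the non-studied close space (the rank-1 neighbor forced in when the
   classical flag is on) and N_UL unrelated lures uniformly from the far
   space (outside every list's close space). *Distributed method:* the
   occupied close region and the far region are tiled by N_CL + N_UL
   contiguous distance bins whose widths form a single geometric
   progression (width_{i+1} = r · width_i, with r solved exactly from the
   two spans); one lure is drawn per bin, spreading the recognition items
   over the whole similarity range.
4. **Exclusivity.** A global exclusion set guarantees no item appears in
   two lists in any role; N_T targets are sampled from each studied set for
   the recognition phase.

The companion statistics implement the nonparametric discriminability
index A′ (participant screening at A′ < 0.7) and the AIC evidence ratio
exp(ΔAIC ⁄ 2) for comparing categorical vs. continuous models of false
recognition.

## Worked example

```python
from fmg import GenerationConfig, generate_lists, make_synthetic_space

space = make_synthetic_space(n_clusters=8, items_per_cluster=150,
                             dim=50, within_spread=0.15, seed=4).space
config = GenerationConfig(n_lists=3, close_space_size=50, n_studied=15,
                          n_targets=6, n_critical=1, n_unrelated=5,
                          method="random", classical_critical_lure=True,
                          seed=20)
for p in generate_lists(space, config):
    print(p.list_id, p.critical_lures, round(p.close_radius, 4))
```

Running `python examples/generate_classical_lists.py` prints each list
sorted by distance to its centroid, e.g. for list 1:

```
List 1  (close radius 0.2805)
  0.2091  c07_i0064     Critical Lure
  0.2132  c07_i0049     Studied +Target
  0.2191  c07_i0125     Studied
  ...
```

The critical lure (distance 0.2091) is the item *closest* to the studied
set's centroid — the strongest false-memory candidate — while every
unrelated lure lies beyond the close radius 0.2805, i.e. farther out than
every studied item. Other example scripts cover the distributed method's
geometric bins, the feasibility simulation with suggested parameter edits,
and A′-based participant screening.

A thin CLI wraps the same library:

```
fmg synth --out space.txt --seed 1
fmg check --space space.txt --n-lists 12 --seed 1
fmg generate --space space.txt --n-lists 12 --seed 1 --out run1
```

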