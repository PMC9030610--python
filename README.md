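# herbvec

Multi-assay bioactivity profiling of herbal drugs: vector-magnitude
scoring, k-means clustering with an exact small-panel solver, and
association of activity clusters with Traditional Chinese Medicine (TCM)
characters.

## The problem

Screening panels for natural products report, per extract, the percent of
control activity remaining in several assay endpoints — here three
antioxidant models (non-enzymatic and enzymatic lipid peroxidation, LNE
and LE; xanthine oxidase, XO) and three eicosanoid-pathway models (5-LOX,
COX-1, 12-LOX). The scale is inverted: 0 = maximal inhibition, 100 = no
effect, and values above 100 mark enhancement (e.g. pro-oxidant
behaviour). The question such a panel can answer is whether extracts with
similar *quantitative* activity profiles share *qualitative* traditional
characters — nature (cold … hot), flavor (bitter, sweet, …), actions
("clear heat", "expel wind").

`herbvec` condenses each herb's profile into vector magnitudes

- α = ‖(LNE, LE)‖ — combined lipid-peroxidation (antioxidant) activity,
- β = ‖(5-LOX, COX-1)‖ — combined eicosanoid inhibition,
- χ = ‖(5-LOX, COX-1, 12-LOX)‖ — the wider eicosanoid space,

(Euclidean norms, rounded to integers; low score = high activity), then
partitions the herbs by k-means in the (α, β) and (α, χ) planes and tests
whether characters are non-randomly distributed over the clusters (Fisher
exact tests, Benjamini–Hochberg adjusted — a quantitative extension of
the traditionally qualitative overlay). A synthetic-panel generator with
known cluster structure and trait coupling supports parameter-recovery
experiments.

For small panels the k-means solution is found *exactly* by
branch-and-bound over all set partitions, so cluster memberships are
never initialization artifacts; a seeded k-means++/Lloyd solver with
restarts handles larger panels and is verified against the exact solver.

The package ships the 15-herb screening panel and its character table as
fixtures (`herbvec.load_fixture_activity()` / `load_fixture_traits()`).

## Worked example

```python
import herbvec as hv

table = hv.score_panel(hv.load_fixture_activity())
result = hv.kmeans_exact(table.coordinates("alpha", "beta"), hv.ClusterConfig(k=3))
for label in result.labels:
    cx, cy = result.centroids[label]
    print(label, f"({cx:.1f}, {cy:.1f})", result.members(label))
```

prints

```
1 (38.0, 28.5) ('c_chinensis', 'f_suspensa', 'p_amurense', 's_baicalensis')
2 (133.0, 30.7) ('a_membranaceus', 'a_sinensis', 'p_cocos')
3 (128.9, 105.4) ('a_dahurica', 'a_macrocephala', 'a_pubescens', 'c_aromatica', 'c_pilosula', 'l_edodes', 'p_lactiflora', 'r_glutinosa')
```

Cluster 1 (smallest centroid norm = strongest combined inhibition) is the
four "cleansing" herbs, all bitter and cold; cluster 2 inhibits
eicosanoid synthesis strongly but is a weak antioxidant and is uniformly
sweet; cluster 3 is the diffuse low-activity remainder. The
`examples/` directory has one short script per capability (scoring,
clustering, trait enrichment, synthetic recovery, full pipeline), and the
`herbvec` CLI runs the whole pipeline from a YAML config:

```sh
herbvec run --config config.yaml --seed 0 --out results/
```

## Notes on the inverted scale

Throughout, 0 means maximal inhibition. Cluster 1 is therefore always the
most *active* cluster, and scatterplots place the strongest herbs near
the origin. See `docs/methods.md` for the model, parameter defaults, and
known data inconsistencies (including one printed α value that follows a
different endpoint definition than the rest of its column).
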