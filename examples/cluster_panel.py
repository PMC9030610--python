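"""Cluster the herbs in the (alpha, beta) activity plane.

Uses the exact solver (globally optimal partition for small panels) with
k=3 and canonical labels: cluster 1 has the smallest-norm centroid, i.e.
the strongest combined inhibition. The result splits the panel into a
highly active cleansing-herb cluster, an eicosanoid-selective cluster,
and a diffuse low-activity cluster.
"""

import herbvec as hv

table = hv.score_panel(hv.load_fixture_activity())
points = table.coordinates("alpha", "beta")
result = hv.kmeans_exact(points, hv.ClusterConfig(k=3))

print(f"algorithm={result.algorithm}  wss={result.wss:.1f}")
for label in result.labels:
    cx, cy = result.centroids[label]
    members = ", ".join(result.members(label))
    print(f"cluster {label}: centroid=({cx:.1f}, {cy:.1f})  members: {members}")
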