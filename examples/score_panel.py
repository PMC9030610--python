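"""Score the packaged 15-herb panel: alpha/beta/chi vector magnitudes.

Each herb's assay readings (percent of control: 0 = maximal inhibition,
100 = no effect) define vectors in the antioxidant plane (LNE, LE) and
the eicosanoid spaces (5-LOX, COX-1) and (5-LOX, COX-1, 12-LOX); the
rounded Euclidean norms are the alpha, beta and chi scores. Low score =
high combined inhibitory activity. '-' marks herbs missing an endpoint.
"""

import herbvec as hv

profiles = hv.load_fixture_activity()
table = hv.score_panel(profiles)
print(table.frame[["display_name", "alpha", "beta", "chi"]].to_string())
print()
print("Most active overall (smallest alpha+beta):",
      (table.frame["alpha"] + table.frame["beta"]).idxmin())
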