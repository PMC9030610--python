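"""Synthetic herb panels with known cluster structure and trait coupling.

Panels are drawn from a Gaussian mixture in activity (percent-of-control)
space: each cluster has a centroid per endpoint and an isotropic spread,
values are clipped at zero (the scale has no negative side; values above
100 — enhancers — are representable). Cluster memberships are assigned
round-robin so small panels cannot lose a cluster by sampling chance.
Each cluster designates a signature flavor; a herb carries its cluster's
signature with probability ``trait_purity`` and otherwise a uniformly
chosen other signature, which makes trait-enrichment recovery a tunable
target. Endpoint values are independently masked with ``missing_rate``.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .tables import (
    ActivityProfile,
    ActivityValue,
    MISSING,
    TraitProfile,
    write_activity_table,
    AssayEndpoint,
)

__all__ = [
    "SyntheticPanelSpec",
    "SyntheticPanel",
    "PAPER_LIKE_CENTROIDS",
    "generate_panel",
    "adjusted_rand_index",
    "write_panel",
]

#: Cluster means of the real 15-herb panel in the (alpha-driving,
#: beta-driving) endpoint plane: a compact highly active cluster, a
#: mid-activity/eicosanoid-selective cluster, and a diffuse low-activity
#: cluster.
PAPER_LIKE_CENTROIDS: tuple[tuple[float, float], ...] = (
    (38.0, 28.5),
    (133.0, 30.7),
    (128.9, 105.4),
)

_SIGNATURE_FLAVORS = ("bitter", "sweet", "pungent", "sour", "bland")
_SIGNATURE_NATURES = ("cold", "neutral", "warm", "slightly_cold", "slightly_warm")


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Parameters of one synthetic panel draw."""

    n_herbs: int = 15
    n_clusters: int = 3
    centroids: tuple[tuple[float, ...], ...] = PAPER_LIKE_CENTROIDS
    spread: float = 10.0
    trait_purity: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    endpoint_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_herbs < self.n_clusters:
            raise ValueError("need n_herbs >= n_clusters >= 1")
        if len(self.centroids) != self.n_clusters:
            raise ValueError("one centroid per cluster required")
        dims = {len(c) for c in self.centroids}
        if len(dims) != 1:
            raise ValueError("centroids must share dimensionality")
        if any(not (0 <= v <= 200) for c in self.centroids for v in c):
            raise ValueError("centroids must lie in [0, 200] percent-of-control")
        if not (self.spread > 0):
            raise ValueError("spread must be positive")
        if not (0 <= self.trait_purity <= 1):
            raise ValueError("trait_purity must be in [0, 1]")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must be in [0, 1]")

    @property
    def n_endpoints(self) -> int:
        return len(self.centroids[0])

    @property
    def endpoints(self) -> tuple[str, ...]:
        if self.endpoint_ids:
            return self.endpoint_ids
        return tuple(f"E{j + 1}" for j in range(self.n_endpoints))


@dataclass(frozen=True)
class SyntheticPanel:
    profiles: tuple[ActivityProfile, ...]
    traits: tuple[TraitProfile, ...]
    true_labels: Mapping[str, int]
    signature_traits: tuple[str, ...]

    @property
    def points(self) -> list[tuple[str, tuple[float, ...]]]:
        """Herbs with fully observed endpoint vectors, as clustering input."""
        out = []
        for p in self.profiles:
            vals = [p.numeric(e) for e in _panel_order(p)]
            if all(v is not None for v in vals):
                out.append((p.herb_id, tuple(vals)))
        return out


def _panel_order(profile: ActivityProfile) -> list[str]:
    # endpoint ids are E1..Em for synthetic panels; preserve numeric order
    return sorted(profile.values, key=lambda e: (len(e), e))


def generate_panel(spec: SyntheticPanelSpec) -> SyntheticPanel:
    """Draw one reproducible panel from the spec."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_clusters
    if k > len(_SIGNATURE_FLAVORS):
        raise ValueError("at most 5 clusters supported (one signature flavor each)")
    signatures = _SIGNATURE_FLAVORS[:k]
    natures = _SIGNATURE_NATURES[:k]
    endpoints = spec.endpoints
    width = len(str(spec.n_herbs))

    profiles: list[ActivityProfile] = []
    traits: list[TraitProfile] = []
    true_labels: dict[str, int] = {}
    for i in range(spec.n_herbs):
        c = i % k  # round-robin membership
        herb = f"H{i + 1:0{width}d}"
        true_labels[herb] = c + 1
        raw = rng.normal(loc=spec.centroids[c], scale=spec.spread)
        raw = np.clip(raw, 0.0, None)
        observed = rng.random(len(endpoints)) >= spec.missing_rate
        values = {
            e: (ActivityValue(float(v)) if ok else MISSING)
            for e, v, ok in zip(endpoints, raw, observed)
        }
        if rng.random() < spec.trait_purity or k == 1:
            flavor = signatures[c]
        else:
            others = [s for s in signatures if s != signatures[c]]
            flavor = others[rng.integers(len(others))]
        profiles.append(ActivityProfile(herb, herb, values))
        traits.append(
            TraitProfile(
                herb_id=herb,
                nature=natures[signatures.index(flavor)],
                flavors=frozenset({flavor}),
                display_name=herb,
            )
        )
    return SyntheticPanel(
        profiles=tuple(profiles),
        traits=tuple(traits),
        true_labels=true_labels,
        signature_traits=signatures,
    )


def adjusted_rand_index(
    labels_a: Mapping[str, int], labels_b: Mapping[str, int]
) -> float:
    """Chance-corrected pair-counting agreement between two herb partitions."""
    if set(labels_a) != set(labels_b):
        raise ValueError("partitions must label the same herb set")
    herbs = sorted(labels_a)
    return float(
        adjusted_rand_score([labels_a[h] for h in herbs], [labels_b[h] for h in herbs])
    )


def write_panel(panel: SyntheticPanel, outdir: str | Path) -> None:
    """Write activity, trait and true-label tables in the standard TSV formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    endpoints = _panel_order(panel.profiles[0])
    schema = tuple(
        AssayEndpoint(e, e, "antioxidant") for e in endpoints
    )
    write_activity_table(panel.profiles, outdir / "activity.tsv", panel=schema)
    lines = ["herb_id\tdisplay_name\tnature\tflavors\tmeridians\tactions"]
    for t in panel.traits:
        lines.append(
            "\t".join(
                [t.herb_id, t.display_name, t.nature, ", ".join(sorted(t.flavors)),
                 ", ".join(sorted(t.meridians)), ", ".join(sorted(t.actions))]
            )
        )
    (outdir / "traits.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    lab_lines = ["herb_id\tcluster"] + [
        f"{h}\t{c}" for h, c in sorted(panel.true_labels.items())
    ]
    (outdir / "true_labels.tsv").write_text("\n".join(lab_lines) + "\n", encoding="utf-8")
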