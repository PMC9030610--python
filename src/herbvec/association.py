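"""Cluster x traditional-character association statistics.

The source analysis overlays TCM characters on the activity clusters
qualitatively ("all members of the most active cluster are bitter and
cold"). This module quantifies that overlay — it is an engineering
extension of the original, qualitative comparison, and its outputs are
labelled as such.

Traits are binary herb attributes: a collapsed nature level (cold /
neutral / warm), a flavor, or an action token (with a small synonym map
so that e.g. "invigorate qi" counts as "tonify qi"). For each trait a
2 x k contingency table of carriers across clusters is built and tested
exactly (Fisher for k=2; complete enumeration of tables with fixed
margins under probability ordering for larger k when feasible, otherwise
a seeded Monte-Carlo permutation of cluster labels). Per trait x cluster
pairs a 2 x 2 Fisher test with a continuity-corrected odds ratio is
reported, Benjamini-Hochberg adjusted across the whole family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import TraitProfile, collapse_nature

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "ACTION_SYNONYMS",
    "DEFAULT_ACTION_TRAITS",
    "herb_carries_trait",
    "build_contingency",
    "exact_association_test",
    "bh_adjust",
    "enrichment_scan",
    "overlay_report",
]

#: Action-phrase synonyms folded onto the tokens singled out in the
#: cluster discussion (wind-expelling, qi-tonifying, heat-clearing,
#: toxicity-removing actions).
ACTION_SYNONYMS: dict[str, str] = {
    "dispel_wind_damp": "expel_wind",
    "invigorate_qi": "tonify_qi",
    "move_qi": "tonify_qi",
    "regulate_qi": "tonify_qi",
    "tonify_spleen_qi": "tonify_qi",
    "invigorate_lung_qi": "tonify_qi",
    "relieve_toxicity": "remove_toxicity",
    "dispel_toxin": "remove_toxicity",
}

DEFAULT_ACTION_TRAITS: tuple[str, ...] = (
    "expel_wind",
    "tonify_qi",
    "clear_heat",
    "remove_toxicity",
)

_COLLAPSED_NATURES = ("cold", "neutral", "warm")


def herb_carries_trait(trait_profile: TraitProfile, trait: str) -> bool:
    """Whether a herb carries a binary trait token.

    Natures are matched on the collapsed 3-level scale, flavors literally,
    actions through the synonym map.
    """
    if trait in _COLLAPSED_NATURES:
        return collapse_nature(trait_profile.nature) == trait
    if trait in trait_profile.flavors:
        return True
    actions = {ACTION_SYNONYMS.get(a, a) for a in trait_profile.actions}
    return trait in actions


@dataclass(frozen=True)
class ContingencyTable:
    """2 x k table of trait carriers (row 0) vs non-carriers (row 1)."""

    trait: str
    cluster_labels: tuple[int, ...]
    counts: tuple[tuple[int, ...], tuple[int, ...]]

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    def column(self, label: int) -> tuple[int, int]:
        j = self.cluster_labels.index(label)
        return self.counts[0][j], self.counts[1][j]


def build_contingency(
    assignments: Mapping[str, int],
    traits: Sequence[TraitProfile],
    trait: str,
) -> ContingencyTable:
    """Count trait carriers per cluster among herbs with known characters.

    Herbs in the clustering that lack a trait profile are excluded.
    """
    by_id = {t.herb_id: t for t in traits}
    labels = tuple(sorted(set(assignments.values())))
    has = [0] * len(labels)
    lacks = [0] * len(labels)
    carriers = 0
    for herb, lab in assignments.items():
        tp = by_id.get(herb)
        if tp is None:
            continue
        j = labels.index(lab)
        if herb_carries_trait(tp, trait):
            has[j] += 1
            carriers += 1
        else:
            lacks[j] += 1
    if carriers == 0:
        raise ValueError(f"trait {trait!r} absent from every clustered herb")
    return ContingencyTable(trait, labels, (tuple(has), tuple(lacks)))


def _table_log_prob(row0: Sequence[int], col_totals: Sequence[int], m: int) -> float:
    """Log multivariate-hypergeometric probability of a 2 x k table given margins."""
    n = sum(col_totals)
    lp = -math.lgamma(n + 1) + math.lgamma(m + 1) + math.lgamma(n - m + 1)
    for a, nj in zip(row0, col_totals):
        lp += math.lgamma(nj + 1) - math.lgamma(a + 1) - math.lgamma(nj - a + 1)
    return lp


def _enumerate_count(col_totals: Sequence[int], m: int) -> int:
    """Number of 2 x k tables with the given margins (for the feasibility guard)."""
    count = [0] * (m + 1)
    count[0] = 1
    for nj in col_totals:
        new = [0] * (m + 1)
        for s in range(m + 1):
            if count[s]:
                for a in range(0, min(nj, m - s) + 1):
                    new[s + a] += count[s]
        count = new
    return count[m]


def exact_association_test(
    table: ContingencyTable,
    seed: int = 0,
    max_tables: int = 1_000_000,
    n_permutations: int = 100_000,
) -> float:
    """Two-sided exact p-value for trait x cluster association.

    k=2 columns: Fisher's exact test. k>2: complete enumeration of the
    conditional table distribution under probability ordering when at most
    ``max_tables`` tables exist, else Monte-Carlo permutation of cluster
    labels with a fixed seed (add-one correction keeps p > 0). Degenerate
    margins (an empty row or column) give p = 1.
    """
    arr = table.array
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        return 1.0
    if arr.shape[1] == 2:
        return float(stats.fisher_exact(arr, alternative="two-sided")[1])
    col_totals = arr.sum(axis=0)
    m = int(arr[0].sum())
    obs_lp = _table_log_prob(arr[0], col_totals, m)
    tol = 1e-9
    if _enumerate_count(col_totals, m) <= max_tables:
        total = 0.0
        ranges = [range(min(nj, m) + 1) for nj in col_totals[:-1]]
        for head in itertools.product(*ranges):
            rest = m - sum(head)
            if 0 <= rest <= col_totals[-1]:
                lp = _table_log_prob(list(head) + [rest], col_totals, m)
                if lp <= obs_lp + tol:
                    total += math.exp(lp)
        return float(min(total, 1.0))
    # permutation: shuffle cluster labels, keep margins, count tables at
    # least as extreme under the same probability ordering
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(arr.shape[1]), col_totals)
    carrier = np.zeros(labels.size, dtype=bool)
    carrier[:m] = True
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(carrier)
        row0 = np.bincount(labels[carrier], minlength=arr.shape[1])
        if _table_log_prob(row0, col_totals, m) <= obs_lp + tol:
            hits += 1
    return float((hits + 1) / (n_permutations + 1))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    if len(p_values) == 0:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


@dataclass(frozen=True)
class EnrichmentResult:
    trait: str
    cluster: int
    count_in: int
    total_in: int
    count_out: int
    total_out: int
    odds_ratio: float
    p_value: float
    q_value: float


def enrichment_scan(
    assignments: Mapping[str, int],
    traits: Sequence[TraitProfile],
    trait_tokens: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """Per trait x cluster 2 x 2 Fisher tests, BH-adjusted as one family.

    The default trait family is the collapsed natures, the flavors present
    in the panel, and the four discussion-highlighted action tokens.
    """
    by_id = {t.herb_id: t for t in traits}
    present = [t for h, t in ((h, by_id.get(h)) for h in assignments) if t is not None]
    if trait_tokens is None:
        flavors = sorted({f for t in present for f in t.flavors})
        trait_tokens = list(_COLLAPSED_NATURES) + flavors + list(DEFAULT_ACTION_TRAITS)
    labels = sorted(set(assignments.values()))

    rows: list[EnrichmentResult] = []
    pvals: list[float] = []
    for trait in trait_tokens:
        carriers = {
            t.herb_id for t in present if herb_carries_trait(t, trait)
        }
        if not carriers:
            continue
        for lab in labels:
            in_ids = [h for h, c in assignments.items() if c == lab and h in by_id]
            out_ids = [h for h, c in assignments.items() if c != lab and h in by_id]
            a = sum(1 for h in in_ids if h in carriers)
            b = len(in_ids) - a
            c = sum(1 for h in out_ids if h in carriers)
            d = len(out_ids) - c
            p = float(stats.fisher_exact([[a, b], [c, d]])[1])
            cells = (a, b, c, d)
            if 0 in cells:
                a_, b_, c_, d_ = (x + 0.5 for x in cells)
            else:
                a_, b_, c_, d_ = cells
            rows.append(
                EnrichmentResult(
                    trait=trait, cluster=lab,
                    count_in=a, total_in=len(in_ids),
                    count_out=c, total_out=len(out_ids),
                    odds_ratio=(a_ * d_) / (b_ * c_),
                    p_value=p, q_value=math.nan,
                )
            )
            pvals.append(p)
    qvals = bh_adjust(pvals)
    return [
        EnrichmentResult(**{**r.__dict__, "q_value": q})
        for r, q in zip(rows, qvals)
    ]


def overlay_report(
    assignments: Mapping[str, int], traits: Sequence[TraitProfile]
) -> str:
    """Qualitative per-cluster character composition, mirroring the way the
    original analysis narrates its clusters (counts of natures, flavors and
    highlighted actions per cluster)."""
    by_id = {t.herb_id: t for t in traits}
    lines = [
        "Cluster character overlay (quantified extension of the qualitative analysis)",
        "Scale reminder: 0 = maximal inhibition, so cluster 1 is the most active.",
        "",
    ]
    for lab in sorted(set(assignments.values())):
        members = sorted(h for h, c in assignments.items() if c == lab)
        lines.append(f"Cluster {lab} ({len(members)} herbs): {', '.join(members)}")
        profs = [by_id[h] for h in members if h in by_id]
        n = len(profs)
        for title, getter in (
            ("natures", lambda t: {collapse_nature(t.nature)}),
            ("flavors", lambda t: t.flavors),
            ("actions", lambda t: {ACTION_SYNONYMS.get(a, a) for a in t.actions}
                                  & set(DEFAULT_ACTION_TRAITS)),
        ):
            counts: dict[str, int] = {}
            for t in profs:
                for tok in getter(t):
                    counts[tok] = counts.get(tok, 0) + 1
            desc = ", ".join(
                f"{tok} {c}/{n}" for tok, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            )
            lines.append(f"  {title}: {desc if desc else '(none)'}")
        lines.append("")
    return "\n".join(lines)
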