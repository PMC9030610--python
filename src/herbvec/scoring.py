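"""Percent-of-control normalization and activity-vector magnitude scores.

Each herb's assay readings define vectors in named endpoint subspaces and
the Euclidean norm of each vector is a single activity score:

* ``alpha`` — lipid-peroxidation (antioxidant) endpoints, default (LNE, LE);
* ``beta``  — the 2D eicosanoid space (5-LOX, COX-1);
* ``chi``   — the 3D eicosanoid space (5-LOX, COX-1, 12-LOX).

Because the percent scale is inverted (0 = maximal inhibition, 100 = no
effect), a *small* magnitude means a *highly active* herb.

The text definition of alpha spans all three antioxidant endpoints
(LNE, LE, XO), but the magnitudes in the source data table are consistent
with the two-component (LNE, LE) norm for all herbs except A. dahurica,
whose value matches the three-component norm. The default is therefore
(LNE, LE), with ``ALPHA3_SPEC`` available as the three-component variant;
see docs/methods.md for the full account of the inconsistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .tables import ActivityProfile

__all__ = [
    "VectorSpaceSpec",
    "ScoreTable",
    "ALPHA_SPEC",
    "ALPHA3_SPEC",
    "BETA_SPEC",
    "CHI_SPEC",
    "DEFAULT_SPECS",
    "inhibition_to_remaining",
    "raw_to_percent_of_control",
    "vector_magnitude",
    "round_half_away",
    "score_panel",
]


@dataclass(frozen=True)
class VectorSpaceSpec:
    """A named subset of endpoints defining one magnitude score.

    ``missing_policy`` controls behaviour when a herb lacks an endpoint:
    ``drop_herb`` (default) yields a MISSING score, ``available_case``
    computes the norm over whatever endpoints are present.
    """

    name: str
    endpoint_ids: tuple[str, ...]
    missing_policy: str = "drop_herb"

    def __post_init__(self) -> None:
        if not self.endpoint_ids:
            raise ValueError("endpoint_ids must be non-empty")
        if len(set(self.endpoint_ids)) != len(self.endpoint_ids):
            raise ValueError("endpoint_ids must not repeat")
        if self.missing_policy not in ("drop_herb", "available_case"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


ALPHA_SPEC = VectorSpaceSpec("alpha", ("LNE", "LE"))
ALPHA3_SPEC = VectorSpaceSpec("alpha", ("LNE", "LE", "XO"))
BETA_SPEC = VectorSpaceSpec("beta", ("L5", "COX1"))
CHI_SPEC = VectorSpaceSpec("chi", ("L5", "COX1", "L12"))
DEFAULT_SPECS: tuple[VectorSpaceSpec, ...] = (ALPHA_SPEC, BETA_SPEC, CHI_SPEC)


def inhibition_to_remaining(pct_inhibition: float) -> float:
    """Convert percent inhibition (100 = complete) to percent of control.

    Enhancement reported as negative inhibition maps above 100, e.g. a 49%
    enhancement (-49) becomes 149 on the percent-of-control scale.
    """
    if not math.isfinite(pct_inhibition):
        raise ValueError("percent inhibition must be finite")
    return 100.0 - pct_inhibition


def raw_to_percent_of_control(treated: float, control: float) -> float:
    """Normalize a raw endpoint reading against its vehicle control."""
    if not (control > 0):
        raise ValueError("control reading must be positive")
    return 100.0 * treated / control


def vector_magnitude(
    profile: ActivityProfile, spec: VectorSpaceSpec
) -> tuple[float | None, tuple[str, ...]]:
    """Euclidean norm of a herb's activity vector in the spec's subspace.

    Returns ``(magnitude, endpoints_used)``; magnitude is None when the
    herb fails the spec's missing policy (any endpoint absent under
    ``drop_herb``, all absent under ``available_case``).
    """
    present = [
        (e, profile.numeric(e)) for e in spec.endpoint_ids
        if profile.numeric(e) is not None
    ]
    if spec.missing_policy == "drop_herb" and len(present) < len(spec.endpoint_ids):
        return None, ()
    if not present:
        return None, ()
    used = tuple(e for e, _ in present)
    return math.sqrt(sum(v * v for _, v in present)), used


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ScoreTable:
    """Per-herb rounded magnitude scores with the endpoints actually used.

    ``frame`` has one row per herb (index ``herb_id``) and, per score name,
    a nullable-integer score column plus an ``endpoints_used_<name>``
    column. MISSING scores are pandas NA.
    """

    frame: pd.DataFrame
    specs: tuple[VectorSpaceSpec, ...]

    @property
    def score_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def coordinates(self, x: str, y: str) -> list[tuple[str, tuple[float, float]]]:
        """(herb_id, (x, y)) points for herbs with both scores present."""
        pts = []
        for herb_id, row in self.frame.iterrows():
            if pd.notna(row[x]) and pd.notna(row[y]):
                pts.append((str(herb_id), (float(row[x]), float(row[y]))))
        return pts

    def write_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        for name in self.score_names:
            out[name] = out[name].map(lambda v: "-" if pd.isna(v) else str(int(v)))
        out.to_csv(path, sep="\t")


def score_panel(
    profiles: Sequence[ActivityProfile],
    specs: Iterable[VectorSpaceSpec] = DEFAULT_SPECS,
    rounding=round_half_away,
) -> ScoreTable:
    """Compute the rounded magnitude scores for every herb in the panel."""
    specs = tuple(specs)
    records = {}
    for p in profiles:
        row: dict[str, object] = {"display_name": p.display_name}
        for spec in specs:
            mag, used = vector_magnitude(p, spec)
            row[spec.name] = pd.NA if mag is None else rounding(mag)
            row[f"endpoints_used_{spec.name}"] = ",".join(used)
        records[p.herb_id] = row
    frame = pd.DataFrame.from_dict(records, orient="index")
    frame.index.name = "herb_id"
    for spec in specs:
        frame[spec.name] = frame[spec.name].astype("Int64")
    return ScoreTable(frame=frame, specs=specs)
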