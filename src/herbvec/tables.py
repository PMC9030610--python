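"""Reading, validation and writing of herb activity and character tables.

The activity table holds percent-of-control values on an inverted
inhibition scale: 0 means maximal inhibition of the assay endpoint, 100
means no effect, and values above 100 indicate enhancement (for example
pro-oxidant behaviour in the enzymatic lipid-peroxidation model). Missing
cells are written as ``-``. Individual cells may carry a provenance suffix
``value[lit:tag]`` marking a literature substitution rather than an
in-house measurement.

The character table holds the traditional characters of each herbal drug:
its nature (cold ... hot), flavors, the meridians it enters, and its
action phrases, either pre-tokenized in separate columns or as a free-text
``properties`` string that is tokenized on read.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AssayEndpoint",
    "ActivityValue",
    "ActivityProfile",
    "TraitProfile",
    "JoinedPanel",
    "MISSING",
    "DEFAULT_PANEL",
    "NATURE_LEVELS",
    "FLAVOR_VOCABULARY",
    "SchemaError",
    "ValidationError",
    "collapse_nature",
    "read_activity_table",
    "write_activity_table",
    "read_trait_table",
    "parse_properties",
    "join_panel",
    "mask_literature",
    "load_fixture_activity",
    "load_fixture_traits",
    "fixture_path",
]


class SchemaError(ValueError):
    """A table's header does not match the expected panel schema."""


class ValidationError(ValueError):
    """A table's contents violate an invariant (negative value, duplicate id...)."""


@dataclass(frozen=True)
class AssayEndpoint:
    """One assay endpoint of the panel.

    ``group`` separates the antioxidant endpoints (lipid peroxidation,
    xanthine oxidase) from the eicosanoid-pathway endpoints (5-LOX, COX-1,
    12-LOX).
    """

    id: str
    label: str
    group: str  # "antioxidant" | "eicosanoid"

    def __post_init__(self) -> None:
        if self.group not in ("antioxidant", "eicosanoid"):
            raise ValueError(f"unknown endpoint group {self.group!r}")


#: The six endpoints of the in-house screening panel.
DEFAULT_PANEL: tuple[AssayEndpoint, ...] = (
    AssayEndpoint("LNE", "Lipid non-enzymatic peroxidation", "antioxidant"),
    AssayEndpoint("LE", "Lipid enzymatic peroxidation", "antioxidant"),
    AssayEndpoint("XO", "Xanthine oxidase / superoxide", "antioxidant"),
    AssayEndpoint("L5", "5-lipoxygenase (5-HETE/LTB4)", "eicosanoid"),
    AssayEndpoint("COX1", "Cyclooxygenase-1 (12-HHTrE)", "eicosanoid"),
    AssayEndpoint("L12", "12-lipoxygenase (12-HETE)", "eicosanoid"),
)


@dataclass(frozen=True)
class ActivityValue:
    """A single percent-of-control reading with its provenance.

    ``value`` is None exactly when ``provenance == "missing"``. Literature
    substitutions carry a citation tag.
    """

    value: float | None
    provenance: str = "measured"  # "measured" | "literature" | "missing"
    citation: str | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("measured", "literature", "missing"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if (self.value is None) != (self.provenance == "missing"):
            raise ValueError("value is None iff provenance is 'missing'")
        if self.value is not None and self.value < 0:
            raise ValidationError(f"negative percent-of-control value {self.value}")

    @property
    def is_missing(self) -> bool:
        return self.value is None

    @property
    def is_enhancer(self) -> bool:
        """True for values above 100 (enhancement / pro-oxidant)."""
        return self.value is not None and self.value > 100


MISSING = ActivityValue(None, "missing")


@dataclass(frozen=True)
class ActivityProfile:
    """One herb's percent-of-control values across the panel endpoints."""

    herb_id: str
    display_name: str
    values: Mapping[str, ActivityValue]

    def value(self, endpoint_id: str) -> ActivityValue:
        return self.values.get(endpoint_id, MISSING)

    def numeric(self, endpoint_id: str) -> float | None:
        return self.value(endpoint_id).value


#: Ordinal nature scale, coldest to hottest.
NATURE_LEVELS: tuple[str, ...] = (
    "cold",
    "slightly_cold",
    "neutral",
    "slightly_warm",
    "warm",
    "hot",
)

FLAVOR_VOCABULARY: frozenset[str] = frozenset(
    {"bitter", "sweet", "pungent", "sour", "bland"}
)

#: 3-level collapse used for plotting and enrichment: cold-ish vs neutral vs
#: warm-ish, matching the figure legend (blue/grey/red).
_NATURE_COLLAPSE = {
    "cold": "cold",
    "slightly_cold": "cold",
    "neutral": "neutral",
    "slightly_warm": "warm",
    "warm": "warm",
    "hot": "warm",
}


def collapse_nature(nature: str) -> str:
    """Collapse the 6-level nature scale to cold / neutral / warm."""
    return _NATURE_COLLAPSE[nature]


@dataclass(frozen=True)
class TraitProfile:
    """Traditional characters of one herbal drug."""

    herb_id: str
    nature: str
    flavors: frozenset[str]
    meridians: frozenset[str] = frozenset()
    actions: frozenset[str] = frozenset()
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.nature not in NATURE_LEVELS:
            raise ValidationError(f"unknown nature {self.nature!r}")
        if not self.flavors:
            raise ValidationError(f"{self.herb_id}: flavors must be non-empty")


_CELL_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*(?:\[lit:([^\]]+)\])?\s*$")
_MISSING_CODES = {"-", "", "NA", "na", "nan"}


def _parse_cell(text: str, *, herb: str, endpoint: str) -> ActivityValue:
    if text.strip() in _MISSING_CODES:
        return MISSING
    m = _CELL_RE.match(text)
    if m is None:
        raise ValidationError(f"{herb}/{endpoint}: cannot parse cell {text!r}")
    value = float(m.group(1))
    if value < 0:
        raise ValidationError(
            f"{herb}/{endpoint}: negative percent-of-control value {value}"
        )
    if m.group(2) is not None:
        return ActivityValue(value, "literature", m.group(2))
    return ActivityValue(value, "measured")


def _sniff_rows(path: str | Path) -> list[list[str]]:
    text = Path(path).read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows = [row for row in csv.reader(text.splitlines(), delimiter=delimiter)]
    return [[c.strip() for c in row] for row in rows if any(c.strip() for c in row)]


def read_activity_table(
    path: str | Path,
    panel: Sequence[AssayEndpoint] = DEFAULT_PANEL,
) -> list[ActivityProfile]:
    """Read a herb x endpoint activity table (TSV default, CSV accepted).

    The header must name only known endpoint ids after the ``herb_id`` and
    optional ``display_name`` columns. Missing cells are ``-``, empty or
    ``NA``; literature-substituted cells use the ``value[lit:tag]`` suffix.
    """
    rows = _sniff_rows(path)
    if not rows:
        raise SchemaError(f"{path}: empty file, header row required")
    header = rows[0]
    if not header or header[0] != "herb_id":
        raise SchemaError(f"{path}: first column must be 'herb_id'")
    has_name = len(header) > 1 and header[1] == "display_name"
    endpoint_cols = header[2:] if has_name else header[1:]
    known = {e.id for e in panel}
    unknown = [c for c in endpoint_cols if c not in known]
    if unknown:
        raise SchemaError(f"{path}: unknown endpoint column(s) {unknown}")

    profiles: list[ActivityProfile] = []
    seen: set[str] = set()
    for row in rows[1:]:
        herb_id = row[0]
        if herb_id in seen:
            raise ValidationError(f"duplicate herb_id {herb_id!r}")
        seen.add(herb_id)
        display = row[1] if has_name else herb_id
        cells = row[2:] if has_name else row[1:]
        values = {e.id: MISSING for e in panel}
        for endpoint, cell in zip(endpoint_cols, cells):
            values[endpoint] = _parse_cell(cell, herb=herb_id, endpoint=endpoint)
        profiles.append(ActivityProfile(herb_id, display, values))
    return profiles


def write_activity_table(
    profiles: Iterable[ActivityProfile],
    path: str | Path,
    panel: Sequence[AssayEndpoint] = DEFAULT_PANEL,
) -> None:
    """Write profiles back to TSV, preserving missingness and provenance."""
    lines = ["\t".join(["herb_id", "display_name"] + [e.id for e in panel])]
    for p in profiles:
        cells = []
        for e in panel:
            v = p.value(e.id)
            if v.is_missing:
                cells.append("-")
            else:
                num = f"{v.value:g}"
                if v.provenance == "literature":
                    tag = v.citation or "unknown"
                    num += f"[lit:{tag}]"
                cells.append(num)
        lines.append("\t".join([p.herb_id, p.display_name] + cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_NATURE_TOKEN_RE = re.compile(
    r"slightly\s+cold|slightly\s+warm|cold|cool|neutral|warm|hot", re.IGNORECASE
)


def parse_properties(text: str) -> tuple[str, frozenset[str]]:
    """Tokenize a free-text property string like ``"Bitter, slightly pungent, cold."``.

    Returns (nature, flavors). The nature token is the last recognized
    thermal word; flavor words are matched against the controlled
    vocabulary, with qualifiers such as "slightly" stripped. Unknown tokens
    trigger a warning but are not fatal; a missing nature token is.
    """
    nat_matches = _NATURE_TOKEN_RE.findall(text)
    if not nat_matches:
        raise ValidationError(f"no nature token found in {text!r}")
    nature = nat_matches[-1].lower().replace(" ", "_").replace("cool", "cold")
    flavors: set[str] = set()
    for raw in re.split(r"[,.;]", text):
        token = raw.strip().lower().removeprefix("slightly ").strip()
        if not token or _NATURE_TOKEN_RE.fullmatch(token):
            continue
        if token in FLAVOR_VOCABULARY:
            flavors.add(token)
        else:
            warnings.warn(f"unknown flavor token {token!r}", stacklevel=2)
    return nature, frozenset(flavors)


def _tokenize_set(cell: str) -> frozenset[str]:
    return frozenset(
        t.strip().lower().replace(" ", "_")
        for t in cell.split(",")
        if t.strip()
    )


def read_trait_table(path: str | Path) -> list[TraitProfile]:
    """Read a herb x character table.

    Accepts either pre-tokenized ``nature``/``flavors``/``meridians``/
    ``actions`` columns or a free-text ``properties`` column which is
    tokenized with :func:`parse_properties`.
    """
    rows = _sniff_rows(path)
    if not rows:
        raise SchemaError(f"{path}: empty file, header row required")
    header = rows[0]
    col = {name: i for i, name in enumerate(header)}
    if "herb_id" not in col:
        raise SchemaError(f"{path}: 'herb_id' column required")

    out: list[TraitProfile] = []
    for row in rows[1:]:
        def cell(name: str) -> str:
            i = col.get(name)
            return row[i] if i is not None and i < len(row) else ""

        herb_id = cell("herb_id")
        if "properties" in col:
            nature, flavors = parse_properties(cell("properties"))
            meridians = _tokenize_set(cell("meridians"))
        else:
            nature = cell("nature").strip().lower().replace(" ", "_")
            flavors = frozenset(
                f for f in _tokenize_set(cell("flavors"))
            )
            unknown = flavors - FLAVOR_VOCABULARY
            if unknown:
                warnings.warn(
                    f"{herb_id}: unknown flavor token(s) {sorted(unknown)}",
                    stacklevel=2,
                )
            meridians = _tokenize_set(cell("meridians"))
        out.append(
            TraitProfile(
                herb_id=herb_id,
                nature=nature,
                flavors=flavors,
                meridians=meridians,
                actions=_tokenize_set(cell("actions")),
                display_name=cell("display_name") or herb_id,
            )
        )
    return out


@dataclass(frozen=True)
class JoinedPanel:
    """Inner join of activity and trait tables on herb_id, plus orphans."""

    records: tuple[tuple[ActivityProfile, TraitProfile], ...]
    orphan_activity: tuple[str, ...]
    orphan_traits: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.records)


def join_panel(
    profiles: Sequence[ActivityProfile], traits: Sequence[TraitProfile]
) -> JoinedPanel:
    """Inner-join the two tables; herbs present in only one are reported."""
    by_trait = {t.herb_id: t for t in traits}
    act_ids = [p.herb_id for p in profiles]
    shared = [p for p in profiles if p.herb_id in by_trait]
    if not shared:
        raise ValidationError("no herb_id shared between activity and trait tables")
    return JoinedPanel(
        records=tuple((p, by_trait[p.herb_id]) for p in shared),
        orphan_activity=tuple(h for h in act_ids if h not in by_trait),
        orphan_traits=tuple(
            t.herb_id for t in traits if t.herb_id not in set(act_ids)
        ),
    )


def mask_literature(profiles: Sequence[ActivityProfile]) -> list[ActivityProfile]:
    """Replace literature-substituted cells with MISSING (measured-only view)."""
    out = []
    for p in profiles:
        values = {
            k: (MISSING if v.provenance == "literature" else v)
            for k, v in p.values.items()
        }
        out.append(replace(p, values=values))
    return out


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture table (``table1_traits.tsv`` or ``table2_activity.tsv``)."""
    return Path(str(resources.files("herbvec.data") / name))


def load_fixture_activity() -> list[ActivityProfile]:
    """The 15-herb, 6-endpoint screening panel shipped with the package."""
    return read_activity_table(fixture_path("table2_activity.tsv"))


def load_fixture_traits() -> list[TraitProfile]:
    """The traditional-character table for the 15 fixture herbs."""
    return read_trait_table(fixture_path("table1_traits.tsv"))
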