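"""Single-command pipeline: score -> cluster -> associate -> report.

Given an activity table and a character table, the pipeline computes the
alpha/beta/chi magnitude scores, clusters the herbs in the (alpha, beta)
plane and — for herbs with a chi score — in the (alpha, chi) plane,
quantifies the cluster x character association, and writes tables,
scatterplots (SVG + PNG, with a plotted-coordinate manifest for
deterministic comparison) and a machine-readable run manifest.

All outputs are deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .association import enrichment_scan, overlay_report
from .cluster import ClusterConfig, ClusterResult, cluster_points
from .scoring import (
    ALPHA3_SPEC,
    ALPHA_SPEC,
    BETA_SPEC,
    CHI_SPEC,
    ScoreTable,
    VectorSpaceSpec,
    score_panel,
)
from .tables import (
    TraitProfile,
    collapse_nature,
    join_panel,
    mask_literature,
    read_activity_table,
    read_trait_table,
)

__all__ = ["PipelineConfig", "RunSummary", "run_pipeline", "render_scatter"]

log = logging.getLogger("herbvec")

CONFIG_SCHEMA_VERSION = 1

#: Figure-legend colors for collapsed natures.
NATURE_COLORS = {"cold": "tab:blue", "warm": "tab:red", "neutral": "tab:grey"}
FALLBACK_COLOR = "0.55"


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable configuration of one pipeline run."""

    activity_table: str
    trait_table: str | None = None
    outdir: str = "herbvec_out"
    seed: int = 0
    alpha_endpoints: tuple[str, ...] = ALPHA_SPEC.endpoint_ids
    beta_endpoints: tuple[str, ...] = BETA_SPEC.endpoint_ids
    chi_endpoints: tuple[str, ...] = CHI_SPEC.endpoint_ids
    missing_policy: str = "drop_herb"
    k: int = 3
    algorithm: str = "auto"
    restarts: int = 100
    scaling: str = "none"
    measured_only: bool = False
    associate: bool = True
    schema_version: int = CONFIG_SCHEMA_VERSION

    def specs(self) -> tuple[VectorSpaceSpec, ...]:
        return (
            VectorSpaceSpec("alpha", tuple(self.alpha_endpoints), self.missing_policy),
            VectorSpaceSpec("beta", tuple(self.beta_endpoints), self.missing_policy),
            VectorSpaceSpec("chi", tuple(self.chi_endpoints), self.missing_policy),
        )

    def cluster_config(self) -> ClusterConfig:
        return ClusterConfig(
            k=self.k, algorithm=self.algorithm, restarts=self.restarts,
            seed=self.seed, scaling=self.scaling,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if data.get("schema_version", CONFIG_SCHEMA_VERSION) != CONFIG_SCHEMA_VERSION:
            raise ValueError("unsupported config schema version")
        for key in ("alpha_endpoints", "beta_endpoints", "chi_endpoints"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("alpha_endpoints", "beta_endpoints", "chi_endpoints"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


@dataclass(frozen=True)
class RunSummary:
    outdir: Path
    n_herbs: int
    cluster_results: dict[str, ClusterResult]
    score_table: ScoreTable
    manifest: dict


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_cluster_tables(
    outdir: Path, space: str, result: ClusterResult, score_table: ScoreTable,
    x: str, y: str,
) -> None:
    rows = ["herb_id\t%s\t%s\tcluster" % (x, y)]
    frame = score_table.frame
    for herb in sorted(result.assignments):
        rows.append(
            f"{herb}\t{int(frame.loc[herb, x])}\t{int(frame.loc[herb, y])}"
            f"\t{result.assignments[herb]}"
        )
    (outdir / f"clusters_{space}.tsv").write_text("\n".join(rows) + "\n", "utf-8")
    crows = ["cluster\t%s\t%s\tsize" % (x, y)]
    for lab in result.labels:
        cx, cy = result.centroids[lab]
        crows.append(f"{lab}\t{cx:.4f}\t{cy:.4f}\t{len(result.members(lab))}")
    (outdir / f"centroids_{space}.tsv").write_text("\n".join(crows) + "\n", "utf-8")


def render_scatter(
    score_table: ScoreTable,
    result: ClusterResult,
    traits: Sequence[TraitProfile],
    space: str,
    outdir: str | Path,
    numbering: Sequence[str] | None = None,
) -> list[Path]:
    """Scatter the herbs in a score plane, colored by collapsed nature.

    ``space`` is ``"alpha-beta"`` or ``"alpha-chi"``. Points are labelled
    by their position in ``numbering`` (input table order) when given,
    else by herb id. Writes SVG, PNG and a TSV manifest of the plotted
    coordinates; returns the written paths.
    """
    x, y = space.split("-")
    pts = [
        (h, xy) for h, xy in score_table.coordinates(x, y)
        if h in result.assignments
    ]
    if len(pts) < 2:
        raise ValueError("need at least two plottable herbs")
    by_id = {t.herb_id: t for t in traits}
    if traits and not any(h in by_id for h, _ in pts):
        log.warning("no herb in the trait table; using fallback color")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    manifest_rows = ["herb_id\tlabel\t%s\t%s\tcluster\tnature" % (x, y)]
    for herb, (px, py) in pts:
        tp = by_id.get(herb)
        nature = collapse_nature(tp.nature) if tp else ""
        color = NATURE_COLORS.get(nature, FALLBACK_COLOR)
        label = str(numbering.index(herb) + 1) if numbering and herb in numbering else herb
        ax.scatter([px], [py], c=color, s=45, edgecolors="k", linewidths=0.4, zorder=3)
        ax.annotate(label, (px, py), xytext=(4, 4), textcoords="offset points",
                    fontsize=8)
        manifest_rows.append(
            f"{herb}\t{label}\t{px:g}\t{py:g}\t{result.assignments[herb]}\t{nature}"
        )
    ax.set_xlabel(f"{x} (0 = maximal inhibition)")
    ax.set_ylabel(f"{y} (0 = maximal inhibition)")
    ax.set_title(f"Herb activity clusters in the ({x}, {y}) plane")
    fig.tight_layout()
    paths = []
    for ext in ("svg", "png"):
        p = outdir / f"scatter_{space}.{ext}"
        fig.savefig(p, dpi=150)
        paths.append(p)
    plt.close(fig)
    mpath = outdir / f"scatter_{space}_coords.tsv"
    mpath.write_text("\n".join(manifest_rows) + "\n", "utf-8")
    paths.append(mpath)
    return paths


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute score -> cluster -> associate -> report; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_stages(config, outdir, written)
    except Exception:
        for p in written:
            if p.exists():
                p.unlink()
        raise


def _run_stages(config: PipelineConfig, outdir: Path, written: list[Path]) -> RunSummary:
    if config.associate and not config.trait_table:
        raise ValueError("[config] association enabled but no trait table given")

    try:
        profiles = read_activity_table(config.activity_table)
    except Exception as exc:
        raise RuntimeError(f"[read] {exc}") from exc
    input_order = [p.herb_id for p in profiles]
    if config.measured_only:
        profiles = mask_literature(profiles)
    log.info("read: %d activity profiles", len(profiles))

    traits: list[TraitProfile] = []
    if config.trait_table:
        traits = read_trait_table(config.trait_table)
        joined = join_panel(profiles, traits)
        log.info("join: %d matched, %d/%d orphans",
                 len(joined), len(joined.orphan_activity), len(joined.orphan_traits))

    score_table = score_panel(profiles, config.specs())
    spath = outdir / "scores.tsv"
    score_table.write_tsv(spath)
    written.append(spath)
    log.info("score: %d rows", len(score_table.frame))

    cluster_results: dict[str, ClusterResult] = {}
    manifest_stages = {}
    for space in ("alpha-beta", "alpha-chi"):
        x, y = space.split("-")
        pts = score_table.coordinates(x, y)
        if len(pts) < config.k:
            raise RuntimeError(f"[cluster] fewer than k={config.k} points in {space}")
        result = cluster_points(pts, config.cluster_config())
        cluster_results[space] = result
        _write_cluster_tables(outdir, space, result, score_table, x, y)
        written += [outdir / f"clusters_{space}.tsv", outdir / f"centroids_{space}.tsv"]
        written += render_scatter(score_table, result, traits, space, outdir,
                                  numbering=input_order)
        log.info("cluster %s: n=%d wss=%.2f sizes=%s",
                 space, len(pts), result.wss, result.sizes())
        manifest_stages[space] = {
            "n_points": len(pts),
            "wss": result.wss,
            "algorithm": result.algorithm,
            "sizes": {str(k): v for k, v in result.sizes().items()},
        }
        if config.associate:
            results = enrichment_scan(result.assignments, traits)
            erows = ["trait\tcluster\tcount_in\ttotal_in\tcount_out\ttotal_out"
                     "\todds_ratio\tp_value\tq_value"]
            for r in results:
                erows.append(
                    f"{r.trait}\t{r.cluster}\t{r.count_in}\t{r.total_in}"
                    f"\t{r.count_out}\t{r.total_out}\t{r.odds_ratio:.4f}"
                    f"\t{r.p_value:.6g}\t{r.q_value:.6g}"
                )
            epath = outdir / f"enrichment_{space}.tsv"
            epath.write_text("\n".join(erows) + "\n", "utf-8")
            opath = outdir / f"overlay_{space}.txt"
            opath.write_text(overlay_report(result.assignments, traits), "utf-8")
            written += [epath, opath]
            log.info("associate %s: %d trait x cluster tests", space, len(results))

    manifest = {
        "herbvec_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {
            "activity_table": _sha256(config.activity_table),
            **({"trait_table": _sha256(config.trait_table)} if config.trait_table else {}),
        },
        "stages": manifest_stages,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", "utf-8")
    written.append(mpath)
    return RunSummary(
        outdir=outdir,
        n_herbs=len(profiles),
        cluster_results=cluster_results,
        score_table=score_table,
        manifest=manifest,
    )
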