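"""End-to-end orchestration: literature stage, gene shortlist, network stage.

The pipeline mirrors the published workflow: map disease concepts, build
genetic concept profiles, cluster and test cohesion, project to a plane,
shortlist the genes contributing more than a cutoff (default 0.1%) to any
significant cluster, and validate the shortlist as seeds on a referenced
protein-interaction background (reference cap 4, path length 2, z cutoff
2.5 — the published settings are the defaults throughout).
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__
from .models import ConceptClustering, SeedNetworkAnalysis, read_seed_list
from .network import intermediate_zscore
from .table4 import Table4Row, load_table4

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline parameters; the defaults are the published settings."""

    occurrences: str
    thesaurus: str
    edge_lists: list[str] = field(default_factory=list)
    concept_names: list[str] | None = None
    seeds_file: str | None = None  # overrides the stage-1 shortlist if set
    weight_method: str = "uncertainty"
    linkage: str = "average"
    iterations: int = 200
    rng_seed: int = 17
    contribution_cutoff_pct: float = 0.1
    p_threshold: float = 0.05
    max_links_per_reference: int = 4
    max_path_length: int = 2
    z_cutoff: float = 2.5
    permutation_universe: str = "all"
    include_intermediate_edges: bool = True
    output_dir: str = "gcpnet_out"

    def validate(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.max_links_per_reference < 1:
            raise ValueError("max_links_per_reference must be >= 1")
        if self.max_path_length not in (1, 2):
            raise ValueError("max_path_length must be 1 or 2")
        if not 0.0 <= self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in [0, 1]")
        if self.contribution_cutoff_pct < 0:
            raise ValueError("contribution_cutoff_pct must be >= 0")
        if not Path(self.occurrences).exists():
            raise ValueError(f"occurrence file not found: {self.occurrences}")
        if not Path(self.thesaurus).exists():
            raise ValueError(f"thesaurus file not found: {self.thesaurus}")
        for p in self.edge_lists:
            if not Path(p).exists():
                raise ValueError(f"edge list not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a YAML config; unknown keys are rejected."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def echo(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class RunReport:
    """Per-stage record of a pipeline run."""

    parameters: dict[str, Any]
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = __version__

    def log_stage(self, name: str, **counts: Any) -> None:
        if name in self.stages:
            raise ValueError(f"stage {name!r} logged twice")
        self.stages[name] = counts

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "version": self.version,
                    "parameters": self.parameters,
                    "stages": self.stages,
                    "warnings": self.warnings,
                },
                sort_keys=False,
            )
        )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run both stages end to end and write all artifacts.

    Any stage failure aborts with the stage name; partial outputs under the
    run's output directory are removed.
    """
    config.validate()
    outdir = Path(config.output_dir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=config.echo())
    written: list[Path] = []
    try:
        stage = "profiles"
        model = ConceptClustering.from_files(
            config.occurrences,
            config.thesaurus,
            concept_names=config.concept_names,
            weight_method=config.weight_method,
            permutation_universe=config.permutation_universe,
        )
        report.log_stage(
            stage,
            documents=model.corpus.n_documents,
            concepts=len(model.concepts),
            gene_vocabulary=len(model.thesaurus.gene_vocabulary),
        )

        stage = "clustering"
        results = model.fit(
            iterations=config.iterations,
            linkage=config.linkage,
            seed=config.rng_seed,
        )
        written.extend(results.save(outdir).values())
        report.warnings.extend(
            f"degenerate profile excluded: {c}" for c in results.dropped_concepts
        )
        report.log_stage(
            stage,
            clusters=len(results.cohesion),
            significant=len(results.significant_clusters(config.p_threshold)),
            universe=results.universe_size,
        )

        stage = "shortlist"
        if config.seeds_file:
            seeds = read_seed_list(config.seeds_file)
        else:
            seeds = results.gene_shortlist(
                config.contribution_cutoff_pct, config.p_threshold
            )
        (outdir / "gene_shortlist.txt").write_text("".join(f"{g}\n" for g in seeds))
        written.append(outdir / "gene_shortlist.txt")
        report.log_stage(stage, genes=len(seeds))

        if config.edge_lists:
            stage = "network"
            net = SeedNetworkAnalysis.from_files(
                config.edge_lists,
                outdir / "gene_shortlist.txt",
                max_links_per_reference=config.max_links_per_reference,
                max_path_length=config.max_path_length,
                include_intermediate_edges=config.include_intermediate_edges,
            )
            net_results = net.fit(z_cutoff=config.z_cutoff)
            written.extend(net_results.save(outdir).values())
            report.warnings.extend(
                f"seed absent from background: {s}"
                for s in net_results.subnetwork.missing_seeds
            )
            report.log_stage(
                stage,
                background_links=net_results.N,
                subnetwork_links=net_results.K,
                seeds_found=len(net_results.subnetwork.seeds),
                intermediates=len(net_results.scores),
                significant=len(net_results.significant),
            )
        report.to_yaml(outdir / "run_report.yaml")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return report


@dataclass
class Table4Verification:
    """Recomputation of the published intermediate z-score benchmark."""

    rows: list[Table4Row]
    recomputed_z: list[float]
    max_abs_deviation: float
    significant_count: int
    order_matches: bool

    def summary(self) -> str:
        lines = [
            "Published z-score benchmark verification",
            "----------------------------------------",
            f"rows:               {len(self.rows)}",
            f"max |z - printed|:  {self.max_abs_deviation:.4f}",
            f"significant:        {self.significant_count} of {len(self.rows)}",
            f"descending z order: {'matches' if self.order_matches else 'DIFFERS from'} the printed order",
        ]
        return "\n".join(lines)


def verify_table4(cutoff: float = 2.5) -> Table4Verification:
    """Recompute z for every benchmark row and compare with the printed values."""
    rows = load_table4()
    z = [intermediate_zscore(r.n, r.k, r.K, r.N) for r in rows]
    deviations = [abs(zi - r.z_printed) for zi, r in zip(z, rows)]
    order = sorted(range(len(rows)), key=lambda i: (-z[i], rows[i].gene))
    return Table4Verification(
        rows=rows,
        recomputed_z=z,
        max_abs_deviation=max(deviations),
        significant_count=sum(zi > cutoff for zi in z),
        order_matches=order == list(range(len(rows))),
    )
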