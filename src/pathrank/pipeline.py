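"""End-to-end pipeline driver and the simulate command.

Stage order mirrors the analysis chain: preprocess (log2, quantile
normalization, probe averaging) -> differential expression (moderated t,
BH) -> gene-set enrichment (rank-sum + overlap pruning) -> network analysis
(pathway subnetworks, edge costs, dual-scope betweenness).  Every stage
writes its TSV/GraphML artifacts into the run directory, and a JSON
manifest records the configuration echo, seed, and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .preprocess import (
    InputError,
    preprocess_pipeline,
    read_annotation,
    read_expression,
    write_annotation,
    write_expression,
    write_groups,
)
from . import diffexp as de_mod
from . import gsea as gsea_mod
from . import network as net_mod
from . import synthetic_data as sim_mod

logger = logging.getLogger("pathrank.pipeline")

STAGES = ("preprocess", "diffexp", "gsea", "network")
DEFAULT_DE_THRESHOLDS = [0.05, 0.01, 0.001]


def setup_logging(run_dir: Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr and, when a run directory is given, to run.log inside it."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if run_dir is not None:
        handlers.append(logging.FileHandler(run_dir / "run.log"))
    root = logging.getLogger("pathrank")
    root.setLevel(level)
    root.handlers = handlers
    for h in handlers:
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for one pipeline run."""

    expression: str
    groups: str
    gmt_files: dict[str, str]  # database tag -> GMT path
    interactome: str
    out_dir: str
    annotation: str | None = None
    alpha_gsea: float = 0.05
    de_count_thresholds: list[float] = field(
        default_factory=lambda: list(DEFAULT_DE_THRESHOLDS)
    )
    string_cutoff: int = net_mod.DEFAULT_SCORE_CUTOFF
    cost_transform: str = "gm"
    tie_rel_tol: float = net_mod.TIE_REL_TOL
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_gsea < 1.0):
            raise InputError(f"alpha_gsea must lie in (0, 1), got {self.alpha_gsea}")
        if self.cost_transform not in net_mod.COST_TRANSFORMS:
            raise InputError(f"unknown cost transform {self.cost_transform!r}")
        if self.string_cutoff < 0:
            raise InputError("string_cutoff must be >= 0")

    def validate_paths(self) -> None:
        required = [self.expression, self.groups, self.interactome, *self.gmt_files.values()]
        if self.annotation:
            required.append(self.annotation)
        missing = [p for p in required if not Path(p).is_file()]
        if missing:
            raise InputError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all four stages; returns the run directory.

    Any stage failure propagates after logging the stage name; partial
    outputs written so far are retained.
    """
    config.validate_paths()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(run_dir)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    stage = "preprocess"
    try:
        matrix = read_expression(config.expression, config.groups)
        annotation = read_annotation(config.annotation) if config.annotation else None
        normalized = preprocess_pipeline(matrix, annotation)
        write_expression(normalized, run_dir / "expression.normalized.tsv")
        manifest["stages"]["preprocess"] = {
            "n_input_rows": len(matrix.row_ids),
            "n_genes": len(normalized.row_ids),
            "n_samples": len(normalized.sample_ids),
        }
        logger.info("preprocess: %d rows -> %d genes", len(matrix.row_ids), len(normalized.row_ids))

        stage = "diffexp"
        de_table, prior = de_mod.run_diffexp(normalized)
        de_mod.write_de_table(de_table, run_dir / "de_table.tsv")
        counts = de_mod.count_de(de_table, config.de_count_thresholds)
        counts.to_csv(run_dir / "de_counts.tsv", sep="\t", index=False, float_format="%.10g")
        de_mod.volcano_table(de_table).to_csv(
            run_dir / "volcano.tsv", sep="\t", index=False, float_format="%.10g"
        )
        de_mod.cumulative_p_table(de_table, config.de_count_thresholds).to_csv(
            run_dir / "cumulative_p.tsv", sep="\t", index=False, float_format="%.10g"
        )
        manifest["stages"]["diffexp"] = {
            "n_genes": len(de_table),
            "prior_d0": prior.d0 if prior.d0 != float("inf") else "inf",
            "prior_s0sq": prior.s0sq,
        }

        stage = "gsea"
        collections = [
            gsea_mod.GeneSetCollection.from_gmt(path, database)
            for database, path in sorted(config.gmt_files.items())
        ]
        set_results = gsea_mod.run_gsea(de_table, collections, alpha=config.alpha_gsea)
        gsea_mod.write_set_results(set_results, run_dir / "set_results.tsv")
        merged = collections[0]
        for extra in collections[1:]:
            merged = merged.merge(extra)
        gsea_mod.membership_table(set_results, merged, de_table, config.alpha_gsea).to_csv(
            run_dir / "set_membership.tsv", sep="\t", index=False, float_format="%.10g"
        )
        manifest["stages"]["gsea"] = {
            "n_sets_tested": len(set_results),
            "n_retained_significant": int(
                (
                    (set_results["status"] == "retained")
                    & (set_results["p_set_adj"] <= config.alpha_gsea)
                ).sum()
            ),
            "n_discarded": int((set_results["status"] == "discarded").sum()),
        }

        stage = "network"
        interactome = net_mod.load_interactome(config.interactome, config.string_cutoff)
        significant = set_results[
            (set_results["status"] == "retained")
            & (set_results["p_set_adj"] <= config.alpha_gsea)
        ]
        pathway_nets = [
            net_mod.extract_subnetwork(interactome, merged.sets[sid].members, sid)
            for sid in significant["set_id"]
        ]
        net_mod.dual_scope_annotate(
            interactome, pathway_nets, de_table, config.cost_transform
        )
        for pn in pathway_nets:
            net_mod.export_network(pn, run_dir, f"network.{pn.parent_set}")
        net_mod.global_betweenness_table(interactome).to_csv(
            run_dir / "interactome.betweenness.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        manifest["stages"]["network"] = {
            "n_interactome_nodes": interactome.number_of_nodes(),
            "n_interactome_edges": interactome.number_of_edges(),
            "n_pathway_networks": len(pathway_nets),
        }
    except Exception:
        logger.exception("stage %s failed", stage)
        manifest["failed_stage"] = stage
        _write_manifest(manifest, run_dir)
        raise

    _write_manifest(manifest, run_dir)
    logger.info("pipeline complete: %s", run_dir)
    return run_dir


def _write_manifest(manifest: dict, run_dir: Path) -> None:
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Simulation bundle
# ---------------------------------------------------------------------------

def simulate_bundle(
    config: sim_mod.SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write a complete synthetic fixture bundle consumable by run_pipeline.

    Produces expression.tsv, groups.tsv, annotation.tsv, sets.gmt,
    interactome.tsv and truth.json in ``out_dir``; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, annotation, truth = sim_mod.generate_expression(config)
    collection = sim_mod.generate_genesets(config, truth)
    interactome = sim_mod.generate_interactome(config, truth)

    paths = {
        "expression": out / "expression.tsv",
        "groups": out / "groups.tsv",
        "annotation": out / "annotation.tsv",
        "gmt": out / "sets.gmt",
        "interactome": out / "interactome.tsv",
        "truth": out / "truth.json",
    }
    write_expression(matrix, paths["expression"])
    write_groups(matrix, paths["groups"])
    write_annotation(annotation, paths["annotation"])
    collection.write_gmt(paths["gmt"])
    sim_mod.write_interactome(interactome, paths["interactome"])
    truth.to_json(paths["truth"])
    logger.info("synthetic bundle written to %s", out)
    return paths


def pipeline_config_for_bundle(
    bundle: dict[str, Path], out_dir: str | Path, seed: int = 0, **overrides
) -> PipelineConfig:
    """Pipeline configuration pointing at a simulated bundle."""
    return PipelineConfig(
        expression=str(bundle["expression"]),
        groups=str(bundle["groups"]),
        annotation=str(bundle["annotation"]),
        gmt_files={"synthetic": str(bundle["gmt"])},
        interactome=str(bundle["interactome"]),
        out_dir=str(out_dir),
        seed=seed,
        **overrides,
    )
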