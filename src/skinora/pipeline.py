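"""End-to-end orchestration: preprocessing → fold change → DEGs → enrichment.

A run is driven by a :class:`RunConfig` (loadable from YAML), processes
each treatment arm independently, and writes deterministic TSV outputs
plus a JSON manifest with a SHA-256 hash per file, so reruns are
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError, DataError, SkinoraError
from .diffexp import (
    MODE_AGGREGATE,
    MODE_PER_SAMPLE,
    call_degs,
    degs_to_tsv,
    fold_change_aggregate,
    fold_change_per_sample,
    sensitivity_analysis,
)
from .enrichment import EnrichmentSummary, enrich_all, results_to_tsv
from .knowledge_base import KnowledgeBase, load_gene_sets, load_interactions
from .overlay import export_overlay, overlay
from .preprocessing import (
    StudyDesign,
    collapse_probes,
    filter_by_detection,
    median_normalize,
    read_expression_matrix,
    read_probe_gene_map,
)

logger = logging.getLogger(__name__)


def analyze_cohort(cohort, arm: str, cutoff: float = 1.0, alpha: float = 0.05,
                   detection_threshold: float = 0.70, tail: str = "greater") -> EnrichmentSummary:
    """Run the standard per-sample analysis on an in-memory cohort bundle.

    Convenience wrapper used by the simulation-based calibration and power
    estimators; the staged file-based entry point is :func:`run`.
    """
    m = median_normalize(cohort.expression)
    m = filter_by_detection(m, cohort.design, threshold=detection_threshold, arm=arm)
    g = collapse_probes(m, cohort.mapping)
    fc = fold_change_per_sample(g, cohort.design, arm)
    deg_sets = call_degs(fc, cutoff)
    return enrich_all(deg_sets, cohort.kb, alpha=alpha, tail=tail)


@dataclass
class RunConfig:
    """Inputs, analysis settings and output location for one pipeline run.

    Defaults are the conventional settings of this analysis style: DEG
    cutoff 1.0 log2 (two-fold), detection threshold 0.70, alpha 0.05 and
    sensitivity cutoffs (0.5, 1.0, 1.5).
    """

    matrix: str = ""
    calls: str | None = None
    mapping: str = ""
    design: str = ""
    gene_sets: str = ""
    edges: str | None = None
    arms: list[str] | None = None  # None → every arm in the design
    mode: str = MODE_PER_SAMPLE
    cutoff: float = 1.0
    sensitivity_cutoffs: tuple[float, ...] = (0.5, 1.0, 1.5)
    alpha: float = 0.05
    detection_threshold: float = 0.70
    universe: str = "kb"  # or "kb-intersect-measured"
    tail: str = "greater"
    bh: bool = False
    out_dir: str = "skinora_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (MODE_PER_SAMPLE, MODE_AGGREGATE):
            raise ConfigError(f"mode must be {MODE_PER_SAMPLE!r} or {MODE_AGGREGATE!r}")
        if self.universe not in ("kb", "kb-intersect-measured"):
            raise ConfigError(f"unknown universe policy {self.universe!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: run config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        if "sensitivity_cutoffs" in raw:
            raw["sensitivity_cutoffs"] = tuple(raw["sensitivity_cutoffs"])
        return cls(**raw)


@dataclass
class RunArtifacts:
    """Outputs of a run: file paths plus the content-hash manifest."""

    out_dir: str
    files: dict[str, str]
    manifest_path: str


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context manager labelling failures with the stage they occurred in."""

    def __init__(self, name: str, state: dict):
        self.name = name
        self.state = state

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        self.state["stage"] = self.name
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, SkinoraError):
            raise DataError(f"stage {self.name!r} failed: {exc}") from exc
        if isinstance(exc, SkinoraError):
            exc.args = (f"stage {self.name!r}: {exc}",)
        return False


def run(cfg: RunConfig) -> RunArtifacts:
    """Execute the full pipeline per the config; each arm independently.

    Writes, per arm: fold-change TSV, DEG TSV, per-test enrichment TSV,
    cross-sample summary TSV, sensitivity TSV and one overlay export per
    enriched pathway; plus a run log and a manifest of SHA-256 hashes.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    state: dict = {"stage": None}
    files: dict[str, str] = {}
    log_path = os.path.join(cfg.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("skinora")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    try:
        logger.info("run config: %s", json.dumps(asdict(cfg), default=list, sort_keys=True))
        with _Stage("design", state):
            if not os.path.exists(cfg.design):
                raise DataError(f"design file not found: {cfg.design!r}")
            design = StudyDesign.from_tsv(cfg.design)
        with _Stage("knowledge_base", state):
            kb = load_gene_sets(cfg.gene_sets)
            if cfg.edges:
                kb = load_interactions(cfg.edges, kb)
        with _Stage("matrix", state):
            m = read_expression_matrix(cfg.matrix, cfg.calls)
        with _Stage("mapping", state):
            mapping = read_probe_gene_map(cfg.mapping)
        with _Stage("normalize", state):
            m = median_normalize(m)
        arms = cfg.arms or design.arms
        for arm in arms:
            prefix = os.path.join(cfg.out_dir, arm)
            with _Stage(f"filter[{arm}]", state):
                m_arm = filter_by_detection(
                    m, design, threshold=cfg.detection_threshold, arm=arm
                )
            with _Stage(f"collapse[{arm}]", state):
                g = collapse_probes(m_arm, mapping)
            with _Stage(f"fold_change[{arm}]", state):
                if cfg.mode == MODE_PER_SAMPLE:
                    fc = fold_change_per_sample(g, design, arm)
                else:
                    fc = fold_change_aggregate(g, design, arm)
                fc.to_tsv(f"{prefix}_fold_changes.tsv")
                files[f"{arm}:fold_changes"] = f"{prefix}_fold_changes.tsv"
            with _Stage(f"degs[{arm}]", state):
                deg_sets = call_degs(fc, cfg.cutoff)
                degs_to_tsv(deg_sets, f"{prefix}_degs.tsv")
                files[f"{arm}:degs"] = f"{prefix}_degs.tsv"
            universe = None
            if cfg.universe == "kb-intersect-measured":
                universe = kb.universe & frozenset(g.gene_symbols)
            with _Stage(f"enrichment[{arm}]", state):
                summary = enrich_all(
                    deg_sets, kb, alpha=cfg.alpha, tail=cfg.tail,
                    universe=universe, bh=cfg.bh,
                )
                results_to_tsv(summary.results, f"{prefix}_enrichment.tsv")
                summary.to_tsv(f"{prefix}_summary.tsv")
                files[f"{arm}:enrichment"] = f"{prefix}_enrichment.tsv"
                files[f"{arm}:summary"] = f"{prefix}_summary.tsv"
            with _Stage(f"sensitivity[{arm}]", state):
                report = sensitivity_analysis(
                    fc, kb, cutoffs=cfg.sensitivity_cutoffs, alpha=cfg.alpha, tail=cfg.tail
                )
                report.to_tsv(f"{prefix}_sensitivity.tsv")
                files[f"{arm}:sensitivity"] = f"{prefix}_sensitivity.tsv"
            with _Stage(f"overlay[{arm}]", state):
                enriched = [nm for nm in kb.pathway_names if summary.counts[nm] > 0]
                for nm in enriched:
                    paths = export_overlay(
                        overlay(nm, kb, fc, cutoff=cfg.cutoff),
                        os.path.join(cfg.out_dir, f"overlays_{arm}"),
                    )
                    for kind, p in paths.items():
                        files[f"{arm}:overlay:{nm}:{kind}"] = p
        manifest = {
            "status": "complete",
            "files": {key: _sha256(path) for key, path in sorted(files.items())},
        }
        with open(manifest_path, "wt", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        files["manifest"] = manifest_path
        return RunArtifacts(out_dir=cfg.out_dir, files=files, manifest_path=manifest_path)
    except Exception:
        manifest = {
            "status": "aborted",
            "failed_stage": state["stage"],
            "files": {key: _sha256(path) for key, path in sorted(files.items())
                      if os.path.exists(path)},
        }
        with open(manifest_path, "wt", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
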