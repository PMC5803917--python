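"""Fold-change based differential expression and cutoff sensitivity.

Differential expression is defined purely by a log2 fold-change threshold
against the pre-treatment baseline — there is no gene-level statistical
test in this design; significance enters only at the pathway level.  Two
modes are provided:

* per-sample: each treated sample is compared with its own patient's
  baseline, giving one fold-change column per treated sample and
  preserving inter-patient variability;
* aggregate: the median over treated samples is compared with the median
  over baseline samples, giving a single column (the input classic
  single-list enrichment tools expect).

A DEG call at cutoff ``c`` (default 1.0, i.e. two-fold) is inclusive at
the boundary: up-regulated means log2FC >= +c, down-regulated means
log2FC <= -c.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .knowledge_base import KnowledgeBase
from .preprocessing import COND_BASELINE, COND_TREATED, GeneMatrix, StudyDesign

logger = logging.getLogger(__name__)

#: pseudo-value added on the linear scale before taking log2, guarding log2(0)
EPSILON = 1e-6

MODE_PER_SAMPLE = "per_sample"
MODE_AGGREGATE = "aggregate"
AGGREGATE_COLUMN = "aggregate"


@dataclass
class FoldChangeTable:
    """Gene × column log2 fold changes versus baseline.

    Columns are treated sample ids (per-sample mode) or the single column
    ``"aggregate"``.  All values are finite.
    """

    values: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        if self.values.shape[1] < 1:
            raise ConfigError("fold-change table needs at least one column")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ConfigError("fold-change table contains non-finite values")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.rename_axis("gene").to_csv(path, sep="\t")


@dataclass(frozen=True)
class DEGSet:
    """Up/down regulated gene sets for one column at one cutoff."""

    column_id: str
    cutoff: float
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ConfigError("up and down DEG sets overlap")

    @property
    def all(self) -> frozenset[str]:
        """Pooled DEG set (direction ignored)."""
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def _drop_all_zero_genes(frame: pd.DataFrame) -> pd.DataFrame:
    dead = (frame == 0).all(axis=1)
    n_dead = int(dead.sum())
    if n_dead:
        logger.info("fold change: excluded %d genes with all-zero intensities", n_dead)
        frame = frame.loc[~dead]
    return frame


def fold_change_per_sample(
    g: GeneMatrix,
    design: StudyDesign,
    arm: str,
    epsilon: float = EPSILON,
    baseline: str = "paired",
) -> FoldChangeTable:
    """Per-treated-sample log2 fold change versus baseline.

    With ``baseline="paired"`` (default) each treated sample is compared
    with its own patient's baseline sample; ``baseline="pooled"`` compares
    every treated sample with the median over all baseline samples of the
    arm.  Genes with zero intensity in every sample of the arm are
    excluded (count logged); elsewhere the pseudo-value ``epsilon`` keeps
    all log ratios finite.
    """
    if baseline not in ("paired", "pooled"):
        raise ConfigError(f"baseline must be 'paired' or 'pooled', got {baseline!r}")
    pairs = design.pairs(arm)
    if not pairs:
        raise DesignError(f"arm {arm!r} has no treated samples")
    needed = {s for pair in pairs for s in pair}
    missing = sorted(needed - set(g.values.columns))
    if missing:
        raise DesignError(f"samples missing from gene matrix: {missing}")
    sub = _drop_all_zero_genes(g.values[sorted(needed)])
    if baseline == "pooled":
        base_col = sub[[b for b, _ in pairs]].median(axis=1)
    cols = {}
    for base_id, treat_id in pairs:
        base = base_col if baseline == "pooled" else sub[base_id]
        cols[treat_id] = np.log2(sub[treat_id] + epsilon) - np.log2(base + epsilon)
    return FoldChangeTable(values=pd.DataFrame(cols), mode=MODE_PER_SAMPLE)


def fold_change_aggregate(
    g: GeneMatrix,
    design: StudyDesign,
    arm: str,
    epsilon: float = EPSILON,
    method: str = "median_of_groups",
) -> FoldChangeTable:
    """One log2 fold change per gene from group medians.

    Default: log2(median over treated + eps) - log2(median over baseline
    + eps).  ``method="median_of_fcs"`` instead takes the median of the
    paired per-sample fold changes.
    """
    if method not in ("median_of_groups", "median_of_fcs"):
        raise ConfigError(f"unknown aggregate method {method!r}")
    if method == "median_of_fcs":
        per_sample = fold_change_per_sample(g, design, arm, epsilon=epsilon)
        agg = per_sample.values.median(axis=1)
        return FoldChangeTable(
            values=agg.to_frame(AGGREGATE_COLUMN), mode=MODE_AGGREGATE
        )
    base_ids = design.samples(arm=arm, condition=COND_BASELINE)
    treat_ids = design.samples(arm=arm, condition=COND_TREATED)
    if not base_ids or not treat_ids:
        raise DesignError(f"arm {arm!r} needs at least one baseline and one treated sample")
    missing = sorted((set(base_ids) | set(treat_ids)) - set(g.values.columns))
    if missing:
        raise DesignError(f"samples missing from gene matrix: {missing}")
    sub = _drop_all_zero_genes(g.values[base_ids + treat_ids])
    fc = np.log2(sub[treat_ids].median(axis=1) + epsilon) - np.log2(
        sub[base_ids].median(axis=1) + epsilon
    )
    return FoldChangeTable(values=fc.to_frame(AGGREGATE_COLUMN), mode=MODE_AGGREGATE)


def call_degs(fc: FoldChangeTable, cutoff: float = 1.0) -> list[DEGSet]:
    """Threshold each column into up/down DEG sets (boundary inclusive)."""
    if not cutoff > 0:
        raise ConfigError(f"DEG cutoff must be > 0, got {cutoff}")
    out = []
    for col in fc.values.columns:
        series = fc.values[col]
        out.append(
            DEGSet(
                column_id=col,
                cutoff=cutoff,
                up=frozenset(series.index[series >= cutoff]),
                down=frozenset(series.index[series <= -cutoff]),
            )
        )
    return out


def degs_to_tsv(deg_sets: list[DEGSet], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene\tcolumn\tdirection\tcutoff\n")
        for ds in deg_sets:
            for gene in sorted(ds.up):
                fh.write(f"{gene}\t{ds.column_id}\tup\t{ds.cutoff}\n")
            for gene in sorted(ds.down):
                fh.write(f"{gene}\t{ds.column_id}\tdown\t{ds.cutoff}\n")


@dataclass
class SensitivityReport:
    """Robustness of enrichment conclusions to the fold-change cutoff.

    ``deg_counts`` has one row per (cutoff, column) with up/down counts;
    ``membership`` is a pathway × cutoff boolean table (enriched in at
    least one column at that cutoff); ``core_pathways`` are enriched at
    every cutoff.
    """

    cutoffs: tuple[float, ...]
    deg_counts: pd.DataFrame
    membership: pd.DataFrame
    alpha: float

    @property
    def enriched_at(self) -> dict[float, frozenset[str]]:
        return {
            c: frozenset(self.membership.index[self.membership[c]])
            for c in self.cutoffs
        }

    @property
    def core_pathways(self) -> frozenset[str]:
        sets = list(self.enriched_at.values())
        core = sets[0]
        for s in sets[1:]:
            core &= s
        return core

    def to_tsv(self, path) -> None:
        self.membership.rename_axis("pathway").rename(
            columns=lambda c: f"enriched_at_{c:g}"
        ).to_csv(path, sep="\t")


def sensitivity_analysis(
    fc: FoldChangeTable,
    kb: KnowledgeBase,
    cutoffs: tuple[float, ...] = (0.5, 1.0, 1.5),
    alpha: float = 0.05,
    tail: str = "greater",
) -> SensitivityReport:
    """Re-run DEG calling and enrichment across several cutoffs.

    Because DEG sets nest as the cutoff grows, pathways robustly enriched
    at a strict cutoff are expected to recur at looser ones; the report's
    ``core_pathways`` make that robustness explicit.
    """
    from .enrichment import enrich_all  # local import avoids a cycle

    cutoffs = tuple(cutoffs)
    if len(cutoffs) < 2:
        raise ConfigError(f"sensitivity analysis needs >= 2 cutoffs, got {len(cutoffs)}")
    if len(set(cutoffs)) != len(cutoffs):
        raise ConfigError("sensitivity cutoffs must be distinct")
    count_rows = []
    membership = {}
    for cutoff in cutoffs:
        deg_sets = call_degs(fc, cutoff)
        for ds in deg_sets:
            count_rows.append(
                {"cutoff": cutoff, "column": ds.column_id,
                 "n_up": len(ds.up), "n_down": len(ds.down)}
            )
        summary = enrich_all(deg_sets, kb, alpha=alpha, tail=tail)
        membership[cutoff] = summary.counts > 0
    membership_df = pd.DataFrame(membership).fillna(False)
    return SensitivityReport(
        cutoffs=cutoffs,
        deg_counts=pd.DataFrame(count_rows),
        membership=membership_df,
        alpha=alpha,
    )
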