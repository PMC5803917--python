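"""Probe-level preprocessing: normalization, detection filtering, collapse.

The pipeline mirrors classic single-channel microarray practice: each
sample is scaled so its median intensity is 1 (MAS5-style 50th-percentile
normalization on the linear scale), probes are filtered by their
Present/Marginal/Absent detection calls within the analysis groups of the
arm under study, and surviving probes are collapsed to gene level by
taking the median probe value per gene.  The log2 transform happens
downstream, in fold-change computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DesignError, ParseError

logger = logging.getLogger(__name__)

CALL_PRESENT = "P"
CALL_MARGINAL = "M"
CALL_ABSENT = "A"

COND_BASELINE = "baseline"
COND_TREATED = "treated"


@dataclass
class ExpressionMatrix:
    """Probe × sample intensities with a parallel detection-call matrix.

    ``calls`` may be None, in which case every probe is treated as Present
    in every sample (detection filtering becomes a no-op).
    """

    values: pd.DataFrame
    calls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DataError(f"duplicate sample ids: {dupes}")
        if (self.values.to_numpy() < 0).any():
            raise DataError("negative intensities in expression matrix")
        if self.calls is not None:
            if self.calls.shape != self.values.shape:
                raise DataError(
                    f"calls shape {self.calls.shape} != values shape {self.values.shape}"
                )
            if not self.calls.index.equals(self.values.index) or not self.calls.columns.equals(
                self.values.columns
            ):
                raise DataError("calls matrix index/columns differ from values matrix")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def effective_calls(self) -> pd.DataFrame:
        """Detection calls, defaulting to all-Present when absent."""
        if self.calls is not None:
            return self.calls
        return pd.DataFrame(
            CALL_PRESENT, index=self.values.index, columns=self.values.columns
        )


@dataclass
class GeneMatrix:
    """Gene × sample normalized intensities on the linear scale."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise DataError("duplicate gene symbols in gene matrix")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


class StudyDesign:
    """Sample annotation pairing treated samples with their baselines.

    One row per sample with columns ``patient``, ``arm`` and ``condition``
    (``baseline`` or ``treated``).  Construction verifies that every
    treated sample has exactly one baseline sample from the same
    (patient, arm); analysis groups are the (arm, condition) pairs.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"patient", "arm", "condition"}
        missing = required - set(table.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        if table.index.duplicated().any():
            raise DesignError("duplicate sample ids in design table")
        bad_cond = set(table["condition"]) - {COND_BASELINE, COND_TREATED}
        if bad_cond:
            raise DesignError(
                f"unknown condition values {sorted(bad_cond)}; "
                f"expected {COND_BASELINE!r} or {COND_TREATED!r}"
            )
        self.table = table.copy()
        for sample, row in self.table[self.table["condition"] == COND_TREATED].iterrows():
            mask = (
                (self.table["patient"] == row["patient"])
                & (self.table["arm"] == row["arm"])
                & (self.table["condition"] == COND_BASELINE)
            )
            n_base = int(mask.sum())
            if n_base != 1:
                raise DesignError(
                    f"treated sample {sample!r} (patient {row['patient']!r}, arm "
                    f"{row['arm']!r}) has {n_base} baseline samples; expected exactly 1"
                )

    @classmethod
    def from_tsv(cls, path) -> "StudyDesign":
        table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(table)

    def to_tsv(self, path) -> None:
        self.table.rename_axis("sample").to_csv(path, sep="\t")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def arms(self) -> list[str]:
        return sorted(self.table["arm"].unique())

    def samples(self, arm: str | None = None, condition: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if arm is not None:
            mask &= self.table["arm"] == arm
        if condition is not None:
            mask &= self.table["condition"] == condition
        return list(self.table.index[mask])

    def groups(self, arm: str | None = None) -> dict[tuple[str, str], list[str]]:
        """Analysis groups: (arm, condition) → sample ids, optionally one arm."""
        out: dict[tuple[str, str], list[str]] = {}
        for (a, cond), sub in self.table.groupby(["arm", "condition"], sort=True):
            if arm is not None and a != arm:
                continue
            out[(a, cond)] = list(sub.index)
        return out

    def pairs(self, arm: str) -> list[tuple[str, str]]:
        """(baseline sample, treated sample) pairs for one arm, by patient."""
        sub = self.table[self.table["arm"] == arm]
        if sub.empty:
            raise DesignError(f"no samples for arm {arm!r}")
        out = []
        treated = sub[sub["condition"] == COND_TREATED].sort_values("patient")
        for sample, row in treated.iterrows():
            base = sub[
                (sub["patient"] == row["patient"]) & (sub["condition"] == COND_BASELINE)
            ]
            out.append((base.index[0], sample))
        return out


def read_expression_matrix(values_path, calls_path=None) -> ExpressionMatrix:
    """Read tab-delimited intensity (and optional call) matrices.

    First column holds probe ids; header row holds sample ids.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    calls = None
    if calls_path is not None:
        calls = pd.read_csv(calls_path, sep="\t", index_col=0, dtype=str)
        calls.index = calls.index.astype(str)
    return ExpressionMatrix(values=values, calls=calls)


def write_expression_matrix(m: ExpressionMatrix, values_path, calls_path=None) -> None:
    m.values.rename_axis("probe_id").to_csv(values_path, sep="\t")
    if calls_path is not None and m.calls is not None:
        m.calls.rename_axis("probe_id").to_csv(calls_path, sep="\t")


def read_probe_gene_map(path) -> pd.DataFrame:
    """Read a 2-column probe → gene TSV; enforces one gene per probe."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: probe→gene map needs 2 columns (probe, gene)")
    table = table.iloc[:, :2]
    table.columns = ["probe", "gene"]
    return validate_probe_gene_map(table)


def validate_probe_gene_map(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["gene"] = table["gene"].str.upper()
    table = table.drop_duplicates()
    multi = table.groupby("probe")["gene"].nunique()
    offenders = list(multi.index[multi > 1])
    if offenders:
        raise DataError(
            f"probes mapping to multiple genes (one gene per probe required): {offenders[:10]}"
        )
    return table


def median_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample by its own median intensity (50th percentile).

    After normalization the median of every sample equals 1.  Idempotent.
    Even-count medians are the arithmetic mean of the two central values.
    """
    medians = m.values.median(axis=0)
    bad = [s for s in m.values.columns if not medians[s] > 0]
    if bad:
        raise DataError(f"samples with non-positive median intensity: {bad}")
    return replace(m, values=m.values / medians)


def filter_by_detection(
    m: ExpressionMatrix,
    design: StudyDesign,
    threshold: float = 0.70,
    arm: str | None = None,
    require: str = "every",
) -> ExpressionMatrix:
    """Keep probes reliably detected within the arm's analysis groups.

    A probe passes a group when its fraction of Present-or-Marginal calls
    among that group's samples is >= ``threshold`` (boundary inclusive; a
    probe P/M in 7 of 10 samples passes at 0.70).  With ``require="every"``
    (default) the probe must pass every (arm, condition) group of the arm
    under analysis; ``require="any"`` keeps probes passing at least one
    group.  Without a call matrix all probes are kept.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"detection threshold must lie in (0, 1], got {threshold}")
    if require not in ("every", "any"):
        raise ConfigError(f"require must be 'every' or 'any', got {require!r}")
    groups = design.groups(arm=arm)
    if not groups:
        raise DesignError(f"design defines no analysis groups for arm {arm!r}")
    missing = [s for g in groups.values() for s in g if s not in m.values.columns]
    if missing:
        raise DesignError(f"design samples absent from expression matrix: {missing}")
    calls = m.effective_calls()
    passed = []
    for samples in groups.values():
        sub = calls[samples]
        frac = sub.isin([CALL_PRESENT, CALL_MARGINAL]).sum(axis=1) / len(samples)
        passed.append(frac >= threshold)
    stacked = pd.concat(passed, axis=1)
    keep = stacked.all(axis=1) if require == "every" else stacked.any(axis=1)
    n_dropped = int((~keep).sum())
    logger.info(
        "detection filter (threshold=%.2f, require=%s, arm=%s): kept %d of %d probes "
        "(%d dropped)",
        threshold, require, arm, int(keep.sum()), len(keep), n_dropped,
    )
    return ExpressionMatrix(
        values=m.values.loc[keep],
        calls=None if m.calls is None else m.calls.loc[keep],
    )


def collapse_probes(m: ExpressionMatrix, mapping: pd.DataFrame) -> GeneMatrix:
    """Assign the median value of a gene's probes to that gene, per sample.

    ``mapping`` is a two-column table (probe, gene).  Probes without a gene
    mapping are dropped (their count is logged).  Even probe counts use the
    mean-of-central-pair median.
    """
    mapping = validate_probe_gene_map(mapping)
    probe_to_gene = mapping.set_index("probe")["gene"]
    mapped = m.values.index.intersection(probe_to_gene.index)
    n_unmapped = len(m.values.index) - len(mapped)
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_unmapped)
    if len(mapped) == 0:
        raise DataError("no probes in the matrix are covered by the probe→gene map")
    values = m.values.loc[mapped]
    genes = probe_to_gene.loc[mapped]
    collapsed = values.groupby(genes.to_numpy()).median()
    collapsed.index.name = "gene"
    return GeneMatrix(values=collapsed.sort_index())
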