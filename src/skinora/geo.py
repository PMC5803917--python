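"""GEO series-matrix ingestion and the reproduction entry point.

A GEO series matrix is a tab-separated text file: ``!``-prefixed metadata
lines (quoted, one value per sample) followed by a probe × sample value
table delimited by ``!series_matrix_table_begin`` / ``_end``.  This module
downloads and parses such files, infers a paired before/after treatment
design from the sample titles, and reruns the standard analysis (aggregate
DEG counts per arm plus per-sample enrichment) against a user-supplied
probe→gene mapping and knowledge base.

Design inference is heuristic by necessity: deposited sample titles encode
arm, patient and visit in free text.  Samples whose titles cannot be
resolved are reported together so the caller can supply an explicit design
table instead.
"""

from __future__ import annotations

import gzip
import io
import os
import re
import urllib.error
import urllib.request
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, DataError, NetworkError
from .diffexp import call_degs, fold_change_aggregate, fold_change_per_sample
from .enrichment import enrich_all, results_to_tsv
from .knowledge_base import KnowledgeBase, demo_kb
from .preprocessing import (
    ExpressionMatrix,
    GeneMatrix,
    StudyDesign,
    collapse_probes,
    median_normalize,
    read_probe_gene_map,
)

SERIES_MATRIX_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/{stem}nnn/{acc}/matrix/"
    "{acc}_series_matrix.txt.gz"
)


def series_matrix_url(accession: str) -> str:
    m = re.fullmatch(r"(GSE\d+)", accession)
    if not m:
        raise ConfigError(f"not a GEO series accession: {accession!r}")
    stem = accession[: max(3, len(accession) - 3)]
    return SERIES_MATRIX_URL.format(stem=stem, acc=accession)


def fetch_series_matrix(accession: str, dest_dir: str, timeout: float = 60.0) -> str:
    """Download the series-matrix file for an accession; returns the path."""
    url = series_matrix_url(accession)
    os.makedirs(dest_dir, exist_ok=True)
    dest = os.path.join(dest_dir, f"{accession}_series_matrix.txt.gz")
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp, open(dest, "wb") as out:
            out.write(resp.read())
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise NetworkError(f"could not retrieve {url}: {exc}") from exc
    return dest


@dataclass
class SeriesMatrix:
    """Parsed series matrix: per-sample metadata plus the value table."""

    metadata: dict[str, list[str]]
    table: pd.DataFrame  # probe × GSM sample values

    @property
    def sample_titles(self) -> list[str]:
        return self.metadata.get("Sample_title", [])


def parse_series_matrix(path) -> SeriesMatrix:
    """Parse a (possibly gzipped) series-matrix text file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    metadata: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with opener(path, "rt", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line[1:].partition("\t")
                values = [v.strip('"') for v in rest.split("\t")] if rest else []
                metadata.setdefault(key, []).extend(values)
    if not table_lines:
        raise DataError(f"{path}: no series_matrix table section found")
    table = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    table.index = table.index.astype(str).str.strip('"')
    table.columns = [c.strip('"') for c in table.columns]
    return SeriesMatrix(metadata=metadata, table=table)


_ARM_PATTERNS = [
    (re.compile(r"betameth|\bBM\b", re.I), "BM"),
    (re.compile(r"pimecrol|\bPC\b", re.I), "PC"),
]
_COND_PATTERNS = [
    (re.compile(r"before|baseline|\bpre\b|week\s*0|\bday\s*0\b|\bt0\b", re.I), "baseline"),
    (re.compile(r"after|post|treated|week\s*3|\bt1\b|end of", re.I), "treated"),
]
_PATIENT_PATTERN = re.compile(r"(?:patient|pat\.?|pt\.?|subject|\bP)\s*#?\s*(\d+)", re.I)


def infer_design(sm: SeriesMatrix) -> StudyDesign:
    """Infer (patient, arm, condition) per sample from series metadata titles."""
    titles = sm.sample_titles
    samples = list(sm.table.columns)
    if len(titles) != len(samples):
        raise DataError(
            f"{len(titles)} sample titles vs {len(samples)} table columns; "
            "cannot align metadata with data"
        )
    rows = []
    unresolved = []
    for sid, title in zip(samples, titles):
        arm = next((tag for pat, tag in _ARM_PATTERNS if pat.search(title)), None)
        cond = next((tag for pat, tag in _COND_PATTERNS if pat.search(title)), None)
        pm = _PATIENT_PATTERN.search(title)
        if arm is None or cond is None or pm is None:
            unresolved.append(f"{sid}: {title!r}")
            continue
        rows.append(
            {"sample": sid, "patient": f"p{int(pm.group(1)):02d}", "arm": arm, "condition": cond}
        )
    if unresolved:
        raise DataError(
            "could not infer design for samples (supply an explicit design table):\n  "
            + "\n  ".join(unresolved)
        )
    return StudyDesign(pd.DataFrame(rows).set_index("sample"))


def reproduce_geo(
    accession: str = "GSE32473",
    out_dir: str = "geo_reproduction",
    mapping=None,
    kb: KnowledgeBase | None = None,
    design: StudyDesign | None = None,
    cutoff: float = 1.0,
    alpha: float = 0.05,
    matrix_file: str | None = None,
    values_scale: str = "linear",
) -> list[str]:
    """Rerun the analysis on a deposited GEO series and report DEG counts.

    Downloads the series matrix (unless ``matrix_file`` points at a local
    copy), infers or accepts a design, collapses probes through the given
    probe→gene ``mapping`` (path or DataFrame; required), and computes
    aggregate-mode DEG counts per arm plus per-sample enrichment against
    ``kb`` (the demo knowledge base by default).  Returns the report lines
    and writes them, with the enrichment tables, under ``out_dir``.
    Deposited values may already be normalized and/or log2-scaled; set
    ``values_scale="log2"`` to undo the log before the pipeline's own
    median scaling.
    """
    if mapping is None:
        raise ConfigError(
            "a probe→gene mapping (TSV path or DataFrame) is required: series "
            "matrices carry no platform annotation"
        )
    if values_scale not in ("linear", "log2"):
        raise ConfigError(f"values_scale must be 'linear' or 'log2', got {values_scale!r}")
    if isinstance(mapping, (str, os.PathLike)):
        mapping = read_probe_gene_map(mapping)
    kb = kb or demo_kb()
    os.makedirs(out_dir, exist_ok=True)
    if matrix_file is None:
        matrix_file = fetch_series_matrix(accession, out_dir)
    sm = parse_series_matrix(matrix_file)
    if design is None:
        design = infer_design(sm)
    values = sm.table
    if values_scale == "log2":
        values = 2.0 ** values
    m = median_normalize(ExpressionMatrix(values=values))
    g = collapse_probes(m, mapping)
    lines = [f"accession: {accession}", f"cutoff: {cutoff:g}", f"alpha: {alpha:g}"]
    for arm in design.arms:
        fc_agg = fold_change_aggregate(g, design, arm)
        agg_degs = call_degs(fc_agg, cutoff)[0]
        lines.append(
            f"DEG count, {arm} arm, aggregate mode, cutoff {cutoff:g}: "
            f"{len(agg_degs)} ({len(agg_degs.up)} up, {len(agg_degs.down)} down)"
        )
        fc = fold_change_per_sample(g, design, arm)
        summary = enrich_all(call_degs(fc, cutoff), kb, alpha=alpha)
        results_to_tsv(summary.results, os.path.join(out_dir, f"{arm}_enrichment.tsv"))
        summary.to_tsv(os.path.join(out_dir, f"{arm}_summary.tsv"))
        enriched = summary.counts[summary.counts > 0]
        lines.append(
            f"pathways enriched in >=1 sample, {arm} arm: {len(enriched)} of {len(kb)}"
        )
    report_path = os.path.join(out_dir, "report.txt")
    with open(report_path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return lines
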