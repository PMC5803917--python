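"""Per-pathway, per-sample over-representation analysis (Fisher's exact test).

For each pathway and each fold-change column, genes of the knowledge-base
universe are cross-classified into a 2×2 table:

====================  ==================  =======================
                      in pathway          not in pathway
====================  ==================  =======================
DEG                   a                   b
non-DEG               c                   d
====================  ==================  =======================

with n = a + b + c + d equal to the number of unique genes in the
knowledge base.  Under the null hypothesis that DEG status is independent
of pathway membership, a follows the hypergeometric distribution with
point probability

    P(a) = (a+b)! (c+d)! (a+c)! (b+d)! / (a! b! c! d! n!)

and the reported p-value is the one-sided upper tail P(X >= a) — the
probability of observing at least as many DEGs in the pathway as seen,
i.e. over-representation.  The tail is summed in log space (log-gamma
binomial coefficients plus a stable log-sum-exp), which keeps it exact to
well beyond 10 significant digits for the table sizes that occur here.
A two-sided alternative (summing all tables with point probability not
exceeding the observed one) is available for completeness.

Up- and down-regulated genes are pooled into a single DEG set before
counting: the test asks whether the pathway is perturbed, not in which
direction.  Genes outside the knowledge-base universe are discarded
before counting, so the measured platform never dilutes the test.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, expm1, lgamma, log, log1p

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .diffexp import DEGSet
from .knowledge_base import KnowledgeBase, Pathway

TAIL_GREATER = "greater"
TAIL_TWO_SIDED = "two-sided"

#: relative fudge when collecting two-sided tables with equal point probability
_TWO_SIDED_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """The 2×2 gene cross-classification behind one enrichment test."""

    a: int  # DEGs in the pathway
    b: int  # DEGs outside the pathway
    c: int  # non-DEG pathway genes
    d: int  # non-DEG genes outside the pathway

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DataError(f"contingency count {name}={v!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def pathway_size(self) -> int:
        return self.a + self.c

    @property
    def n_degs(self) -> int:
        return self.a + self.b


def _lchoose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _log_point(k: int, r: int, s: int, n: int, ldenom: float) -> float:
    # log P(X = k) for hypergeometric with pathway size r, s DEGs among n genes
    return _lchoose(r, k) + _lchoose(n - r, s - k) - ldenom


def fisher_point_prob(t: ContingencyTable) -> float:
    """Probability of the observed table itself under fixed margins.

    Equals the factorial expression
    (a+b)!(c+d)!(a+c)!(b+d)! / (a!b!c!d!n!).
    """
    n = t.n
    if n == 0:
        return 1.0
    r, s = t.pathway_size, t.n_degs
    return exp(_log_point(t.a, r, s, n, _lchoose(n, s)))


def _logsumexp(logs: list[float]) -> float:
    m = max(logs)
    if m == -np.inf:
        return m
    return m + log(sum(exp(x - m) for x in logs))


def fisher_p(t: ContingencyTable, tail: str = TAIL_GREATER) -> float:
    """One- or two-sided Fisher exact p-value for a contingency table.

    ``tail="greater"`` (default) sums hypergeometric point probabilities
    over k >= a with margins fixed — the over-representation tail.
    ``tail="two-sided"`` sums every table whose point probability does not
    exceed the observed one.
    """
    if tail not in (TAIL_GREATER, TAIL_TWO_SIDED):
        raise ConfigError(f"tail must be {TAIL_GREATER!r} or {TAIL_TWO_SIDED!r}, got {tail!r}")
    n = t.n
    if n == 0:
        return 1.0
    r, s = t.pathway_size, t.n_degs
    kmin = max(0, r + s - n)
    kmax = min(r, s)
    ldenom = _lchoose(n, s)
    if tail == TAIL_GREATER:
        if t.a <= kmin:
            return 1.0  # every attainable table is at least as extreme
        logs = [_log_point(k, r, s, n, ldenom) for k in range(t.a, kmax + 1)]
        return min(1.0, exp(_logsumexp(logs)))
    lp_obs = _log_point(t.a, r, s, n, ldenom)
    cut = lp_obs + log1p(_TWO_SIDED_REL_TOL)
    logs = [
        lp
        for k in range(kmin, kmax + 1)
        if (lp := _log_point(k, r, s, n, ldenom)) <= cut
    ]
    return min(1.0, exp(_logsumexp(logs)))


def build_contingency(
    degs: DEGSet,
    pathway: Pathway,
    kb: KnowledgeBase,
    universe: frozenset[str] | None = None,
) -> ContingencyTable:
    """Count the 2×2 table for one DEG set against one pathway.

    Up and down genes are pooled; both the DEG pool and the pathway are
    intersected with the universe (by default the full KB gene
    population) before counting, so a + b + c + d = |universe| always.
    """
    if universe is None:
        universe = kb.universe
    if not universe:
        raise DataError("knowledge-base universe is empty; nothing to test against")
    pool = degs.all & universe
    members = pathway.genes & universe
    a = len(pool & members)
    b = len(pool) - a
    c = len(members) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher test outcome for one (pathway, column) pair."""

    pathway: str
    column_id: str
    table: ContingencyTable
    p_value: float
    enriched: bool
    p_adjusted: float | None = None


@dataclass
class EnrichmentSummary:
    """Cross-sample roll-up of per-column enrichment results.

    ``counts`` gives, per pathway, the number of columns in which the
    pathway was enriched; ``pvalues`` retains the full pathway × column
    p-value matrix; ``results`` the underlying per-test records.
    """

    counts: pd.Series
    total_columns: int
    pvalues: pd.DataFrame
    results: list[EnrichmentResult]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "enriched_sample_count": self.counts,
                "total_samples": self.total_columns,
            }
        ).rename_axis("pathway")

    def to_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t")


def enrich_column(
    degs: DEGSet,
    kb: KnowledgeBase,
    alpha: float = 0.05,
    tail: str = TAIL_GREATER,
    universe: frozenset[str] | None = None,
    bh: bool = False,
) -> list[EnrichmentResult]:
    """Test every KB pathway against one DEG set.

    The enriched flag uses strict p < alpha (on the Benjamini–Hochberg
    adjusted p when ``bh`` is set).  Results are ordered by (p ascending,
    pathway name ascending) for determinism.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigError(f"alpha must lie in [0, 1], got {alpha}")
    if not kb.pathways:
        raise DataError("knowledge base has no pathways")
    names = kb.pathway_names
    tables = [build_contingency(degs, kb.pathways[nm], kb, universe=universe) for nm in names]
    pvals = [fisher_p(t, tail=tail) for t in tables]
    adjusted = multipletests(pvals, method="fdr_bh")[1] if bh else [None] * len(pvals)
    results = []
    for nm, table, p, padj in zip(names, tables, pvals, adjusted):
        effective = padj if bh else p
        results.append(
            EnrichmentResult(
                pathway=nm,
                column_id=degs.column_id,
                table=table,
                p_value=p,
                p_adjusted=padj,
                enriched=bool(effective < alpha),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def enrich_all(
    deg_sets: list[DEGSet],
    kb: KnowledgeBase,
    alpha: float = 0.05,
    tail: str = TAIL_GREATER,
    universe: frozenset[str] | None = None,
    bh: bool = False,
) -> EnrichmentSummary:
    """Run enrichment for every column and summarize across columns."""
    if not deg_sets:
        raise ConfigError("enrich_all needs at least one DEG set")
    names = kb.pathway_names
    all_results: list[EnrichmentResult] = []
    pmat = pd.DataFrame(index=names, columns=[ds.column_id for ds in deg_sets], dtype=float)
    counts = pd.Series(0, index=names, dtype=int)
    for ds in deg_sets:
        for res in enrich_column(ds, kb, alpha=alpha, tail=tail, universe=universe, bh=bh):
            pmat.loc[res.pathway, res.column_id] = res.p_value
            if res.enriched:
                counts[res.pathway] += 1
            all_results.append(res)
    pmat.index.name = "pathway"
    return EnrichmentSummary(
        counts=counts,
        total_columns=len(deg_sets),
        pvalues=pmat,
        results=all_results,
    )


def results_to_tsv(results: list[EnrichmentResult], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("pathway\tcolumn\ta\tb\tc\td\tn\tp_value\tp_adjusted\tenriched\n")
        for r in results:
            t = r.table
            padj = "" if r.p_adjusted is None else f"{r.p_adjusted:.6g}"
            fh.write(
                f"{r.pathway}\t{r.column_id}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t{t.n}\t"
                f"{r.p_value:.6g}\t{padj}\t{int(r.enriched)}\n"
            )
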