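"""Synthetic paired-cohort generator with planted pathway perturbations.

The generator emulates the shape of a paired before/after topical-treatment
microarray study: ~10 patients per arm, a baseline and a treated sample
each, several probes per gene, log-normal intensities and
Present/Marginal/Absent detection calls.  Baseline log2 intensity of gene
g is drawn once (Normal(baseline_log2_mean, baseline_log2_sd)); the
treated sample of a responder patient adds a fixed log2 shift Δ to each
affected gene of a planted pathway; every observed probe value adds
probe-level jitter and Normal(0, noise_sd) measurement noise on the log2
scale.  Detection calls are drawn independently of intensity so that the
detection filter can be tested orthogonally.

Because the planted ground truth is known, the same machinery estimates
the enrichment test's type-I error under a null configuration and its
power to recover planted pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .knowledge_base import KnowledgeBase, Pathway
from .preprocessing import ExpressionMatrix, StudyDesign

ARM_BM = "BM"
ARM_PC = "PC"


@dataclass(frozen=True)
class PlantedEffect:
    """A pathway-level perturbation to plant into treated samples.

    ``delta`` is the log2 shift applied to ``affected_gene_fraction`` of
    the pathway's genes in the treated sample of every responder patient
    (``responder_fraction`` of the cohort).
    """

    pathway: str
    delta: float
    responder_fraction: float = 1.0
    affected_gene_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("responder_fraction", "affected_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fixes every random draw.

    Defaults are sized to the paired-treatment study shape the pipeline
    targets: 10 patients, two treatment arms, 1–3 probes per gene,
    log2-scale noise of 0.3.
    """

    n_genes: int = 2000
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (20, 40)
    overlap_fraction: float = 0.0
    n_patients: int = 10
    arms: tuple[str, ...] = (ARM_BM, ARM_PC)
    probes_per_gene_range: tuple[int, int] = (1, 3)
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.0
    probe_jitter_sd: float = 0.2
    noise_sd: float = 0.3
    absent_call_rate: float = 0.05
    marginal_call_rate: float = 0.05
    planted_pathways: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_pathways < 1 or self.n_patients < 1:
            raise ConfigError("n_genes, n_pathways and n_patients must be >= 1")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"bad pathway_size_range {self.pathway_size_range}")
        if hi > self.n_genes:
            raise ConfigError(
                f"max pathway size {hi} exceeds n_genes {self.n_genes}: infeasible"
            )
        plo, phi = self.probes_per_gene_range
        if not (1 <= plo <= phi):
            raise ConfigError(f"bad probes_per_gene_range {self.probes_per_gene_range}")
        for name in ("overlap_fraction", "absent_call_rate", "marginal_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.absent_call_rate + self.marginal_call_rate > 1.0:
            raise ConfigError("absent_call_rate + marginal_call_rate must be <= 1")
        for name in ("baseline_log2_sd", "noise_sd"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if not self.arms:
            raise ConfigError("at least one arm required")


@dataclass
class GroundTruth:
    """What was planted: per-pathway effects and the per-gene shift matrix."""

    effects: dict[str, PlantedEffect]
    responders: dict[str, tuple[str, ...]]
    affected_genes: dict[str, frozenset[str]]
    gene_shift: pd.DataFrame  # gene × patient log2 shift applied in treated samples

    @property
    def planted_pathways(self) -> list[str]:
        return sorted(self.effects)


@dataclass
class SimulatedCohort:
    """Bundle of everything the pipeline consumes, plus the ground truth."""

    expression: ExpressionMatrix
    design: StudyDesign
    mapping: pd.DataFrame
    kb: KnowledgeBase
    truth: GroundTruth
    config: SimulationConfig


def _assign_pathways(cfg: SimulationConfig, rng: np.random.Generator, genes: np.ndarray):
    """Partition genes into pathways, wrapping into overlap when slots exceed genes.

    Every gene ends up in at least one pathway, so the KB universe equals
    the full simulated gene population.
    """
    lo, hi = cfg.pathway_size_range
    sizes = rng.integers(lo, hi + 1, cfg.n_pathways)
    perm = rng.permutation(cfg.n_genes)
    members: dict[str, set[int]] = {}
    assigned: list[int] = []
    pos = 0
    for i, size in enumerate(sizes):
        fresh = perm[pos : pos + size]
        pos += len(fresh)
        chosen = set(int(x) for x in fresh)
        short = int(size) - len(chosen)
        if short > 0:
            if not assigned:
                raise ConfigError("pathway sizes exceed gene count with no overlap pool")
            pool = [g for g in assigned if g not in chosen]
            chosen |= set(
                int(x) for x in rng.choice(pool, size=min(short, len(pool)), replace=False)
            )
        assigned.extend(int(x) for x in fresh)
        members[f"P{i + 1:02d}"] = chosen
    names = list(members)
    for j, gi in enumerate(perm[pos:]):  # leftover genes: round-robin so none is orphaned
        members[names[j % len(names)]].add(int(gi))
    if cfg.overlap_fraction > 0:
        for name, chosen in members.items():
            extra = int(round(cfg.overlap_fraction * len(chosen)))
            pool = [g for g in range(cfg.n_genes) if g not in chosen]
            if extra and pool:
                chosen |= set(
                    int(x) for x in rng.choice(pool, size=min(extra, len(pool)), replace=False)
                )
    kb = KnowledgeBase()
    for name, chosen in members.items():
        kb.add_pathway(
            Pathway(
                name=name,
                category="Simulated",
                genes=frozenset(genes[g] for g in chosen),
            )
        )
    return kb, members


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate one paired cohort; byte-identical under a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    patients = [f"p{i + 1:02d}" for i in range(cfg.n_patients)]

    kb, members = _assign_pathways(cfg, rng, genes)

    # planted ground truth
    gene_shift = np.zeros((cfg.n_genes, cfg.n_patients))
    effects: dict[str, PlantedEffect] = {}
    responders: dict[str, tuple[str, ...]] = {}
    affected: dict[str, frozenset[str]] = {}
    for effect in cfg.planted_pathways:
        if effect.pathway not in members:
            raise ConfigError(f"planted pathway {effect.pathway!r} does not exist")
        if effect.pathway in effects:
            raise ConfigError(f"pathway {effect.pathway!r} planted twice")
        member_idx = np.array(sorted(members[effect.pathway]))
        n_resp = int(round(effect.responder_fraction * cfg.n_patients))
        n_aff = int(round(effect.affected_gene_fraction * len(member_idx)))
        resp_idx = np.sort(rng.choice(cfg.n_patients, size=n_resp, replace=False))
        aff_idx = np.sort(rng.choice(member_idx, size=n_aff, replace=False))
        gene_shift[np.ix_(aff_idx, resp_idx)] += effect.delta
        effects[effect.pathway] = effect
        responders[effect.pathway] = tuple(patients[i] for i in resp_idx)
        affected[effect.pathway] = frozenset(genes[i] for i in aff_idx)
    truth = GroundTruth(
        effects=effects,
        responders=responders,
        affected_genes=affected,
        gene_shift=pd.DataFrame(gene_shift, index=genes, columns=patients),
    )

    # probes
    plo, phi = cfg.probes_per_gene_range
    n_probes_per_gene = rng.integers(plo, phi + 1, cfg.n_genes)
    gene_of_probe = np.repeat(np.arange(cfg.n_genes), n_probes_per_gene)
    probe_rank = np.concatenate([np.arange(k) for k in n_probes_per_gene])
    probe_ids = np.array(
        [f"{genes[g]}_at{r + 1}" for g, r in zip(gene_of_probe, probe_rank)]
    )
    mapping = pd.DataFrame({"probe": probe_ids, "gene": genes[gene_of_probe]})

    mu_gene = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    probe_offset = rng.normal(0.0, cfg.probe_jitter_sd, len(probe_ids))
    base_log2 = mu_gene[gene_of_probe] + probe_offset

    # samples: per arm, per patient, baseline then treated
    sample_ids: list[str] = []
    rows = []
    shift_cols = []
    for arm in cfg.arms:
        for p, patient in enumerate(patients):
            for condition, tag in (("baseline", "t0"), ("treated", "t1")):
                sid = f"{arm}_{patient}_{tag}"
                sample_ids.append(sid)
                rows.append({"sample": sid, "patient": patient, "arm": arm, "condition": condition})
                if condition == "treated":
                    shift_cols.append(gene_shift[gene_of_probe, p])
                else:
                    shift_cols.append(np.zeros(len(probe_ids)))
    shift_matrix = np.column_stack(shift_cols)
    noise = rng.normal(0.0, cfg.noise_sd, shift_matrix.shape)
    log2_values = base_log2[:, None] + shift_matrix + noise
    values = pd.DataFrame(
        np.exp2(log2_values), index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
    )

    u = rng.random(shift_matrix.shape)
    call_codes = np.where(
        u < cfg.absent_call_rate,
        "A",
        np.where(u < cfg.absent_call_rate + cfg.marginal_call_rate, "M", "P"),
    )
    calls = pd.DataFrame(call_codes, index=values.index, columns=sample_ids)

    design = StudyDesign(pd.DataFrame(rows).set_index("sample"))
    return SimulatedCohort(
        expression=ExpressionMatrix(values=values, calls=calls),
        design=design,
        mapping=mapping,
        kb=kb,
        truth=truth,
        config=cfg,
    )


def _rep_seeds(base_seed: int, n_reps: int) -> np.ndarray:
    return np.random.default_rng(base_seed).integers(0, 2**31 - 1, n_reps)


@dataclass
class Type1Result:
    """Empirical type-I error of the enrichment test under a null cohort."""

    fraction: float
    n_calls: int
    n_reps: int

    @property
    def standard_error(self) -> float:
        return float(np.sqrt(self.fraction * (1 - self.fraction) / max(self.n_calls, 1)))


def estimate_type1(
    cfg_null: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    arm: str | None = None,
    cutoff: float = 1.0,
) -> Type1Result:
    """Fraction of (pathway, sample, replicate) tests significant at alpha.

    Runs the full pipeline (normalize → detection filter → collapse →
    per-sample fold change → DEG calling → enrichment) on fresh null
    cohorts.  Fisher's exact test is conservative, so the fraction should
    sit at or below alpha.
    """
    from .pipeline import analyze_cohort

    if cfg_null.planted_pathways:
        raise ConfigError("type-I estimation requires a null config (no planted pathways)")
    if n_reps < 1:
        raise ConfigError(f"n_reps must be >= 1, got {n_reps}")
    arm = arm or cfg_null.arms[0]
    n_sig = 0
    n_calls = 0
    for seed in _rep_seeds(cfg_null.seed, n_reps):
        cohort = simulate_cohort(replace(cfg_null, seed=int(seed)))
        summary = analyze_cohort(cohort, arm=arm, cutoff=cutoff, alpha=alpha)
        p = summary.pvalues.to_numpy()
        n_sig += int((p < alpha).sum())
        n_calls += p.size
    return Type1Result(fraction=n_sig / n_calls, n_calls=n_calls, n_reps=n_reps)


@dataclass
class PowerResult:
    """Recovery of one planted pathway across replicates."""

    pathway: str
    recovery_fraction: float   # replicate enriched in >= rf*n_patients - 1 samples
    top_rank_fraction: float   # replicate ranks it first by median p across samples
    n_reps: int


def estimate_power(
    cfg: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    arm: str | None = None,
    cutoff: float = 1.0,
) -> dict[str, PowerResult]:
    """Per planted pathway: recovery and top-rank fractions over replicates.

    A replicate "recovers" a planted pathway when the pathway is enriched
    (p < alpha) in at least responder_fraction * n_patients - 1 treated
    samples; "top rank" means the pathway has the smallest median p-value
    across samples among all pathways.
    """
    from .pipeline import analyze_cohort

    if not cfg.planted_pathways:
        raise ConfigError("power estimation requires at least one planted pathway")
    if n_reps < 1:
        raise ConfigError(f"n_reps must be >= 1, got {n_reps}")
    arm = arm or cfg.arms[0]
    recovered = {e.pathway: 0 for e in cfg.planted_pathways}
    top_ranked = {e.pathway: 0 for e in cfg.planted_pathways}
    thresholds = {
        e.pathway: e.responder_fraction * cfg.n_patients - 1 for e in cfg.planted_pathways
    }
    for seed in _rep_seeds(cfg.seed, n_reps):
        cohort = simulate_cohort(replace(cfg, seed=int(seed)))
        summary = analyze_cohort(cohort, arm=arm, cutoff=cutoff, alpha=alpha)
        median_p = summary.pvalues.median(axis=1)
        best = median_p.sort_values(kind="stable").index[0]
        for e in cfg.planted_pathways:
            if summary.counts[e.pathway] >= thresholds[e.pathway]:
                recovered[e.pathway] += 1
            if best == e.pathway:
                top_ranked[e.pathway] += 1
    return {
        name: PowerResult(
            pathway=name,
            recovery_fraction=recovered[name] / n_reps,
            top_rank_fraction=top_ranked[name] / n_reps,
            n_reps=n_reps,
        )
        for name in recovered
    }
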