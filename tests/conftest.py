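import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import skinora as sk

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_kb():
    return sk.demo_kb()


@pytest.fixture()
def tiny_design():
    """2 patients x 2 arms, baseline + treated each."""
    rows = []
    for arm in ("BM", "PC"):
        for patient in ("p01", "p02"):
            for cond, tag in (("baseline", "t0"), ("treated", "t1")):
                rows.append(
                    {"sample": f"{arm}_{patient}_{tag}", "patient": patient,
                     "arm": arm, "condition": cond}
                )
    return sk.StudyDesign(pd.DataFrame(rows).set_index("sample"))


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded synthetic cohort with one strongly planted pathway."""
    cfg = sk.SimulationConfig(
        n_genes=300,
        n_pathways=10,
        pathway_size_range=(30, 30),
        arms=("BM",),
        probes_per_gene_range=(1, 2),
        noise_sd=0.3,
        n_patients=6,
        planted_pathways=(
            sk.PlantedEffect("P01", delta=2.0, responder_fraction=1.0,
                             affected_gene_fraction=1.0),
        ),
        seed=42,
    )
    return sk.simulate_cohort(cfg)


def random_gene_matrix(rng: np.random.Generator, n_genes: int, samples) -> sk.GeneMatrix:
    values = pd.DataFrame(
        rng.lognormal(2.0, 0.8, (n_genes, len(samples))),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=list(samples),
    )
    return sk.GeneMatrix(values=values)
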