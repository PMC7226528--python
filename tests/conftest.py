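import numpy as np
import pandas as pd
import pytest

from cyclinpair.core_io import ExpressionMatrix, SampleTable
from cyclinpair.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def tiny_samples() -> SampleTable:
    """Three paired patients, mixed HPV status."""
    rows = []
    for i, hpv in enumerate(["positive", "negative", "negative"], start=1):
        for tissue, suffix in (("tumor", "T"), ("normal", "N")):
            rows.append(
                {
                    "sample_id": f"P{i}-{suffix}",
                    "patient_id": f"P{i}",
                    "tissue": tissue,
                    "hpv_status": hpv,
                    "batch": "b1",
                }
            )
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture
def tiny_matrix(tiny_samples) -> ExpressionMatrix:
    """Gene-level log2 matrix with known paired fold changes.

    GENE1 lfc per patient: +1, 0, -1.5; GENE2 lfc: +2, +0.5, 0.
    """
    samples = tiny_samples.table["sample_id"].tolist()
    values = pd.DataFrame(
        {
            "P1-T": [6.0, 9.0],
            "P1-N": [5.0, 7.0],
            "P2-T": [7.0, 7.5],
            "P2-N": [7.0, 7.0],
            "P3-T": [4.0, 8.0],
            "P3-N": [5.5, 8.0],
        },
        index=["GENE1", "GENE2"],
    )[samples]
    return ExpressionMatrix(values, level="gene", scale="log2")


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at study-scale defaults (82 paired + extras)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_gene_matrix(default_cohort):
    from cyclinpair.preprocess import (
        average_technical_replicates,
        collapse_probes_to_genes,
    )

    m, probes = average_technical_replicates(
        default_cohort.expression, default_cohort.probes
    )
    return collapse_probes_to_genes(m, probes)
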