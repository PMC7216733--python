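import numpy as np
import pandas as pd
import pytest

from contrastseq import (
    CountMatrix,
    DesignTable,
    align_and_validate,
    build_design_matrix,
)
from contrastseq.simulate import SimulationSpec, simulate_counts


def make_counts(values, genes=None, samples=None) -> CountMatrix:
    values = np.asarray(values)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_design(
    factors: dict[str, list[str]],
    biological: list[str],
    replicate: str | None = None,
    samples: list[str] | None = None,
) -> DesignTable:
    n = len(next(iter(factors.values())))
    samples = samples or [f"s{j + 1}" for j in range(n)]
    return DesignTable(pd.DataFrame(factors, index=samples), biological, replicate)


@pytest.fixture(scope="session")
def table1_design() -> DesignTable:
    """The worked-example design: 2 tissues x 2 treatments x 3 replicates."""
    rows = []
    samples = []
    for tissue in ("MatureLeaf", "Root"):
        for treatment in ("NoSi", "Si"):
            for rep in ("R1", "R2", "R3"):
                samples.append(f"{tissue}_{treatment}_{rep}")
                rows.append((tissue, treatment, rep))
    table = pd.DataFrame(rows, index=samples, columns=["Tissue", "Treatment", "Replicate"])
    return DesignTable(table, ["Tissue", "Treatment"], "Replicate")


@pytest.fixture(scope="session")
def table1_spec() -> SimulationSpec:
    return SimulationSpec(
        n_genes=400,
        factor_names=("Tissue", "Treatment"),
        modalities=(("MatureLeaf", "Root"), ("NoSi", "Si")),
        replicates=3,
        frac_de_a=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def table1_project(table1_spec):
    counts, design, truth = simulate_counts(table1_spec)
    project = align_and_validate(counts, design, "demo")
    return project, truth


@pytest.fixture(scope="session")
def table1_glm(table1_design):
    return build_design_matrix(table1_design, with_interaction=True)
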