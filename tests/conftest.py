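import numpy as np
import pandas as pd
import pytest

from factorial_de import SimulationConfig, generate_dataset, normalize
from factorial_de.contrasts import SampleDesign
from factorial_de.enrichment import GeneSetCollection
from factorial_de.normalization import CountMatrix


def make_matrix(values, sample_ids=None, mito=None) -> CountMatrix:
    """Small CountMatrix from a 2-D array; genes named g1.., samples s1..."""
    arr = np.asarray(values, dtype=float)
    genes = [f"g{i + 1}" for i in range(arr.shape[0])]
    samples = sample_ids or [f"s{j + 1}" for j in range(arr.shape[1])]
    is_mito = pd.Series(
        [False] * len(genes) if mito is None else mito, index=pd.Index(genes, name="gene")
    )
    return CountMatrix(
        values=pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=samples),
        is_mito=is_mito,
    )


def make_design(reps: int = 3) -> SampleDesign:
    """Standard 4-group design; sample ids follow the simulator convention."""
    groups = ("IW", "AW", "IM", "AM")
    table = pd.DataFrame(
        {
            "genotype": ["WT" if g[1] == "W" else "MR" for g in groups for _ in range(reps)],
            "activity": [
                "INACTIVE" if g[0] == "I" else "ACTIVE" for g in groups for _ in range(reps)
            ],
        },
        index=pd.Index([f"{g}_{r + 1}" for g in groups for r in range(reps)], name="sample"),
    )
    return SampleDesign(table)


def as_normalized(matrix: CountMatrix):
    """Wrap a matrix as already-normalized (all size factors 1).

    Noise-free single-gene fixtures would otherwise have their planted signal
    equalized away by the trimmed-mean step.
    """
    from factorial_de.normalization import NormalizedMatrix

    return NormalizedMatrix(
        values=matrix.values.copy(),
        is_mito=matrix.is_mito.copy(),
        size_factors=pd.Series(1.0, index=matrix.values.columns),
        trim_fraction=0.0,
    )


def noise_free_matrix(group_log2_means, reps: int = 3) -> CountMatrix:
    """Matrix whose replicates equal 2**mu exactly for each (gene, group).

    ``group_log2_means`` is a list of (mu_IW, mu_AW, mu_IM, mu_AM) per gene.
    """
    rows = []
    for mus in group_log2_means:
        row = []
        for mu in mus:
            row.extend([2.0**mu] * reps)
        rows.append(row)
    design = make_design(reps)
    return make_matrix(rows, sample_ids=list(design.table.index))


@pytest.fixture(scope="session")
def mixed_dataset():
    """Seeded factorial dataset with all effect classes planted."""
    cfg = SimulationConfig(
        n_genes=2000,
        seed=42,
        dispersion=0.05,
        baseline_log2_mean_range=(9.0, 9.0),  # mean counts 512
    )
    matrix, design, truth = generate_dataset(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def null_dataset():
    """All-null dataset used for type-I-error calibration."""
    cfg = SimulationConfig(
        n_genes=2000,
        seed=7,
        dispersion=0.05,
        baseline_log2_mean_range=(9.0, 9.0),
        class_proportions={"null": 1.0},
        n_mito_genes=0,
    )
    matrix, design, truth = generate_dataset(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def normalized_mixed(mixed_dataset):
    _, matrix, design, truth = mixed_dataset
    return normalize(matrix), design, truth


@pytest.fixture()
def toy_collection():
    """Ten deterministic gene sets in a 200-gene universe."""
    rng = np.random.default_rng(123)
    universe = [f"u{i:03d}" for i in range(200)]
    sets = {}
    for t in range(10):
        size = int(rng.integers(8, 40))
        members = set(rng.choice(universe, size=size, replace=False))
        sets[f"term{t:02d}"] = (f"synthetic term {t}", members)
    return GeneSetCollection.from_sets(sets, background=universe)
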