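"""Seeded negative-binomial simulator for 2x2 factorial count data.

Emulates the study design the pipeline targets: four activity-by-genotype
groups of 3 replicates each, overdispersed gene-level counts, a small block of
highly abundant mitochondrially encoded genes, and planted per-gene effect
classes (null, single main effects, additive, synergistic, antagonistic) so
downstream inference can be checked against known truth.

Group log2 means are built from a baseline plus marginal effects: with ``a``
the activity effect, ``g`` the genotype effect and ``delta`` the interaction,

    mu_IW = baseline            mu_AW = baseline + a
    mu_IM = baseline + g        mu_AM = baseline + a + g + delta

Counts are negative-binomial with variance mu + dispersion * mu**2
(gamma-Poisson mixture; dispersion 0 degenerates to Poisson). Baselines are
quantized to 1/1024 log2 units so that recomputing delta from the four stored
group means is exact in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from factorial_de.contrasts import GROUPS, SampleDesign
from factorial_de.normalization import CountMatrix

EFFECT_CLASSES = (
    "null",
    "main_genotype",
    "main_activity",
    "additive_both",
    "synergistic",
    "antagonistic",
)

_DEFAULT_PROPORTIONS = {
    "null": 0.70,
    "main_genotype": 0.06,
    "main_activity": 0.06,
    "additive_both": 0.06,
    "synergistic": 0.06,
    "antagonistic": 0.06,
}

#: log2(10): mitochondrial genes are planted ~10x above baseline abundance.
_MITO_BOOST_LOG2 = np.log2(10.0)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic factorial dataset.

    ``effect_size_log2`` is the magnitude of the marginal activity/genotype
    effects; ``interaction_size_log2`` the magnitude of the planted
    interaction; ``dispersion`` the NB overdispersion phi in
    var = mu + phi * mu**2.
    """

    n_genes: int = 10_000
    n_replicates_per_group: int = 3
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    baseline_log2_mean_range: tuple[float, float] = (5.0, 11.0)
    effect_size_log2: float = 2.0
    interaction_size_log2: float = 2.0
    dispersion: float = 0.05
    n_mito_genes: int = 13
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_replicates_per_group <= 0:
            raise ValueError("n_genes and n_replicates_per_group must be positive")
        unknown = set(self.class_proportions) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect class(es): {sorted(unknown)}")
        total = sum(self.class_proportions.get(c, 0.0) for c in EFFECT_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.n_mito_genes < 0 or self.n_mito_genes > self.n_genes:
            raise ValueError("need 0 <= n_mito_genes <= n_genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        lo, hi = self.baseline_log2_mean_range
        if not lo <= hi:
            raise ValueError("baseline_log2_mean_range must be a (lo, hi) interval")
        if self.effect_size_log2 <= 0 or self.interaction_size_log2 <= 0:
            raise ValueError("effect sizes must be positive")


def plant_effect(
    baseline_log2: float, effect_class: str, a: float, g: float, delta: float
) -> tuple[float, float, float, float]:
    """Four group log2 means (IW, AW, IM, AM) for one gene.

    Raises if the effect parameters are inconsistent with the class (null
    genes must have a = g = delta = 0; purely additive classes must have
    delta = 0, and single-main-effect classes a zero other margin).
    """
    if effect_class not in EFFECT_CLASSES:
        raise ValueError(f"unknown effect class {effect_class!r}")
    constraints = {
        "null": (a == 0 and g == 0 and delta == 0, "a = g = delta = 0"),
        "main_genotype": (a == 0 and delta == 0, "a = delta = 0"),
        "main_activity": (g == 0 and delta == 0, "g = delta = 0"),
        "additive_both": (delta == 0, "delta = 0"),
        "synergistic": (True, ""),
        "antagonistic": (True, ""),
    }
    ok, rule = constraints[effect_class]
    if not ok:
        raise ValueError(f"class {effect_class!r} requires {rule}")
    return (
        baseline_log2,
        baseline_log2 + a,
        baseline_log2 + g,
        baseline_log2 + a + g + delta,
    )


def nb_sample(log2_mean: float, dispersion: float, rng: np.random.Generator, size=None):
    """Negative-binomial count(s) with mean 2**log2_mean, var mu + phi*mu^2."""
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    mu = 2.0**log2_mean
    if dispersion == 0:
        return rng.poisson(mu, size=size)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu, size=size)
    return rng.poisson(lam)


def _class_counts(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genes to classes, deterministic."""
    exact = {c: proportions.get(c, 0.0) * n for c in EFFECT_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    short = n - sum(counts.values())
    by_frac = sorted(
        EFFECT_CLASSES, key=lambda c: (-(exact[c] - counts[c]), EFFECT_CLASSES.index(c))
    )
    for c in by_frac[:short]:
        counts[c] += 1
    return counts


def generate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Simulate counts, the matching design, and the per-gene truth table.

    The first ``n_mito_genes`` genes are flagged mitochondrial and forced to
    the null class at ~10x baseline abundance. Per-gene random streams are
    derived from (seed, gene index), so the output is reproducible for a fixed
    config regardless of how genes are ordered or how many there are.
    """
    config.validate()
    n = config.n_genes
    n_mito = config.n_mito_genes
    reps = config.n_replicates_per_group
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    counts_by_class = _class_counts(config.class_proportions, n - n_mito)
    labels = [c for c in EFFECT_CLASSES for _ in range(counts_by_class[c])]
    order = master.permutation(n - n_mito)
    classes = ["null"] * n_mito + [labels[i] for i in order]

    lo, hi = config.baseline_log2_mean_range
    baselines = np.round(master.uniform(lo, hi, size=n) * 1024.0) / 1024.0
    baselines[:n_mito] += _MITO_BOOST_LOG2
    a_sign = master.choice([-1.0, 1.0], size=n)
    g_sign = master.choice([-1.0, 1.0], size=n)

    e = config.effect_size_log2
    d = config.interaction_size_log2
    gene_ids = [f"MT{i + 1:03d}" for i in range(n_mito)] + [
        f"G{i + 1:06d}" for i in range(n - n_mito)
    ]
    sample_ids = [f"{grp}_{r + 1}" for grp in GROUPS for r in range(reps)]

    rows = np.empty((n, 4 * reps), dtype=float)
    truth_rows = []
    for i, cls in enumerate(classes):
        a = g = delta = 0.0
        if cls == "main_genotype":
            g = g_sign[i] * e
        elif cls == "main_activity":
            a = a_sign[i] * e
        elif cls == "additive_both":
            a, g = a_sign[i] * e, g_sign[i] * e
        elif cls == "synergistic":
            a, g = a_sign[i] * e, a_sign[i] * e  # concordant margins
            delta = np.sign(a + g) * d
        elif cls == "antagonistic":
            a, g = a_sign[i] * e, a_sign[i] * e
            delta = -np.sign(a + g) * d
        mus = plant_effect(baselines[i], cls, a, g, delta)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, i]))
        for j, mu in enumerate(mus):  # group order IW, AW, IM, AM
            rows[i, j * reps : (j + 1) * reps] = nb_sample(
                mu, config.dispersion, rng, size=reps
            )
        truth_rows.append(
            {
                "gene": gene_ids[i],
                "class": cls,
                "a": a,
                "g": g,
                "delta": delta,
                "baseline_log2": baselines[i],
                "mu_IW": mus[0],
                "mu_AW": mus[1],
                "mu_IM": mus[2],
                "mu_AM": mus[3],
                "dispersion": config.dispersion,
            }
        )

    values = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
    is_mito = pd.Series(
        [i < n_mito for i in range(n)], index=values.index, name="is_mito"
    )
    matrix = CountMatrix(values=values, is_mito=is_mito)

    design_table = pd.DataFrame(
        {
            "genotype": ["WT" if grp[1] == "W" else "MR" for grp in GROUPS for _ in range(reps)],
            "activity": [
                "INACTIVE" if grp[0] == "I" else "ACTIVE" for grp in GROUPS for _ in range(reps)
            ],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    design = SampleDesign(design_table)
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return matrix, design, truth
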