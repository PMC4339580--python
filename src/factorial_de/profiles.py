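"""Expression-profile codes, interaction-mode calls and Venn partitions.

Each gene's six pairwise contrasts are discretized into trits: +1
(significantly over-expressed), -1 (under-expressed) or 0 (not differentially
expressed), in the canonical contrast order (AM-AW, AM-IM, AW-IM, IW-IM,
IW-AW, IW-AM). Genes sharing a code form a profile cluster.

Interaction mode compares the combined-condition effect ``c`` against the
additive prediction ``s = a + g`` of the two marginal effects (all log2, all
relative to the inactive wild-type baseline group): a combination more extreme
than the sum — in the same direction, or emerging where the additive
prediction is essentially zero — is synergistic; a combination weaker than or
opposed to the sum is antagonistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from factorial_de.contrasts import CONTRASTS, ContrastResult, SampleDesign, _require_groups
from factorial_de.normalization import NormalizedMatrix

DEFAULT_DISCRETIZE_P = 1e-4
DEFAULT_EPSILON = 0.1

MODES = ("synergistic", "antagonistic", "none")


def discretize(lfc: float, p: float, p_threshold: float = DEFAULT_DISCRETIZE_P) -> int:
    """Trit for one contrast: sign of lfc if p < p_threshold, else 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < p_threshold and lfc > 0:
        return 1
    if p < p_threshold and lfc < 0:
        return -1
    return 0


def profile_codes(
    contrasts: dict[str, ContrastResult], p_threshold: float = DEFAULT_DISCRETIZE_P
) -> pd.DataFrame:
    """Per-gene trit table with one column per canonical contrast."""
    missing = [c for c in CONTRASTS if c not in contrasts]
    if missing:
        raise ValueError(f"missing contrast(s): {missing}")
    genes = contrasts[CONTRASTS[0]].table.index
    out = {}
    for name in CONTRASTS:
        t = contrasts[name].table
        if not t.index.equals(genes):
            raise ValueError(f"contrast {name} gene list differs from {CONTRASTS[0]}")
        if ((t["p"] < 0) | (t["p"] > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        sig = t["p"] < p_threshold
        out[name] = np.where(sig & (t["lfc"] > 0), 1, np.where(sig & (t["lfc"] < 0), -1, 0))
    return pd.DataFrame(out, index=genes, dtype=np.int8)[list(CONTRASTS)]


def format_code(code) -> str:
    """Render a six-trit code with explicit signs, e.g. '0,+1,0,0,0,0'."""
    return ",".join("+1" if t == 1 else "-1" if t == -1 else "0" for t in code)


def tabulate_profiles(codes: pd.DataFrame, min_size: int = 50) -> pd.DataFrame:
    """Profile clusters of at least ``min_size`` genes, largest first.

    Returns columns code (rendered string), count, genes (sorted list). Ties
    in count are broken by the lexicographic code string so the order is
    deterministic.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    groups: dict[tuple, list] = {}
    for gene, row in zip(codes.index, codes.to_numpy()):
        groups.setdefault(tuple(int(v) for v in row), []).append(str(gene))
    rows = [
        {"code": format_code(code), "count": len(genes), "genes": sorted(genes)}
        for code, genes in groups.items()
        if len(genes) >= min_size
    ]
    rows.sort(key=lambda r: (-r["count"], r["code"]))
    return pd.DataFrame(rows, columns=["code", "count", "genes"])


def classify_mode(
    a: float,
    g: float,
    c: float,
    q_delta: float,
    sig_threshold: float = 0.005,
    epsilon: float = DEFAULT_EPSILON,
) -> str:
    """Synergistic / antagonistic / none for one gene.

    With s = a + g the additive prediction: non-significant interactions are
    'none'; a combined effect exceeding |s| in magnitude with consistent sign
    (or where |s| < epsilon, so any emerging effect is super-additive) is
    synergistic; a combined effect smaller than |s| or of opposite sign is
    antagonistic. epsilon guards against sign instability near s = 0.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if q_delta >= sig_threshold:
        return "none"
    s = a + g
    if abs(c) > abs(s) and (c * s > 0 or abs(s) < epsilon):
        return "synergistic"
    if abs(s) >= epsilon and (abs(c) < abs(s) or c * s < 0):
        return "antagonistic"
    return "none"  # measure-zero ties (|c| == |s| with consistent signs)


def interaction_effects(
    norm: NormalizedMatrix,
    design: SampleDesign,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene a, g, c, delta relative to the IW baseline group.

    a = mean log2 AW - mean log2 IW (activity alone), g likewise for IM
    (genotype alone), c for AM (the combination); delta = c - a - g.
    """
    _require_groups(design)
    logm = np.log2(norm.values + pseudocount)
    m = {
        grp: logm[design.samples_in_group(grp)].mean(axis=1)
        for grp in ("IW", "AW", "IM", "AM")
    }
    a = m["AW"] - m["IW"]
    g = m["IM"] - m["IW"]
    c = m["AM"] - m["IW"]
    return pd.DataFrame({"a": a, "g": g, "c": c, "delta": c - a - g})


def call_interactions(
    effects: pd.DataFrame,
    interaction: pd.DataFrame,
    sig_threshold: float = 0.005,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Combine effect estimates with interaction-test p/q into mode calls."""
    if not effects.index.equals(interaction.index):
        raise ValueError("effects and interaction tables are misaligned")
    modes = [
        classify_mode(row.a, row.g, row.c, q, sig_threshold, epsilon)
        for row, q in zip(effects.itertuples(), interaction["q"])
    ]
    out = effects.copy()
    out["p"] = interaction["p"]
    out["q"] = interaction["q"]
    out["mode"] = modes
    return out


@dataclass(frozen=True)
class VennPartition:
    """The seven disjoint regions of a three-set Venn diagram."""

    a_only: frozenset
    b_only: frozenset
    c_only: frozenset
    ab_only: frozenset
    ac_only: frozenset
    bc_only: frozenset
    abc: frozenset

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "c_only": len(self.c_only),
            "ab_only": len(self.ab_only),
            "ac_only": len(self.ac_only),
            "bc_only": len(self.bc_only),
            "abc": len(self.abc),
        }


def venn_partition(set_a, set_b, set_c) -> VennPartition:
    """Disjoint partition of the union of three gene sets."""
    a, b, c = frozenset(set_a), frozenset(set_b), frozenset(set_c)
    return VennPartition(
        a_only=a - b - c,
        b_only=b - a - c,
        c_only=c - a - b,
        ab_only=(a & b) - c,
        ac_only=(a & c) - b,
        bc_only=(b & c) - a,
        abc=a & b & c,
    )
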