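"""Differential-expression statistics for the 2x2 factorial design.

Six pairwise group contrasts, the two main effects and the activity-by-genotype
interaction are tested per gene. The test is Welch's unequal-variance t on
log2(normalized value + pseudocount); fold changes are ratios of group means on
the linear normalized scale. A contrast named ``"A-B"`` reports
``log2(mean_B / mean_A)``, so a positive value means higher expression in B.
Raw P-values are adjusted with the Benjamini-Hochberg step-up within each
contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from factorial_de.normalization import NormalizedMatrix

#: Group codes: first letter activity (I/A), second genotype (W = wild-type,
#: M = myostatin-reduced).
GROUPS = ("IW", "AW", "IM", "AM")

#: Canonical contrast order used for profile codes and output files.
CONTRASTS = ("AM-AW", "AM-IM", "AW-IM", "IW-IM", "IW-AW", "IW-AM")

GENOTYPES = ("WT", "MR")
ACTIVITIES = ("INACTIVE", "ACTIVE")

DEFAULT_PSEUDOCOUNT = 1.0

_GENOTYPE_TOKENS = {
    "wild-type": "WT",
    "wildtype": "WT",
    "wt": "WT",
    "myostatin-reduced": "MR",
    "myostatinreduced": "MR",
    "mr": "MR",
}
_ACTIVITY_TOKENS = {"inactive": "INACTIVE", "active": "ACTIVE"}


def _group_code(genotype: str, activity: str) -> str:
    return ("I" if activity == "INACTIVE" else "A") + ("W" if genotype == "WT" else "M")


@dataclass
class SampleDesign:
    """Sample-to-(genotype, activity) map defining the four factorial groups."""

    table: pd.DataFrame  # index: sample id; columns: genotype, activity, group

    def __post_init__(self) -> None:
        t = self.table
        if not t.index.is_unique:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in design: {dups}")
        bad_g = set(t["genotype"]) - set(GENOTYPES)
        if bad_g:
            raise ValueError(f"unknown genotype token(s): {sorted(bad_g)}")
        bad_a = set(t["activity"]) - set(ACTIVITIES)
        if bad_a:
            raise ValueError(f"unknown activity token(s): {sorted(bad_a)}")
        t["group"] = [
            _group_code(g, a) for g, a in zip(t["genotype"], t["activity"])
        ]
        sizes = t.groupby("group").size()
        small = sizes.index[sizes < 2].tolist()
        if small:
            raise ValueError(
                f"group(s) with fewer than 2 replicates: {small}; "
                "within-group variance cannot be estimated"
            )

    @classmethod
    def from_tokens(cls, samples, genotypes, activities) -> "SampleDesign":
        """Build a design from raw tokens such as 'wild-type' / 'active'."""
        geno, act = [], []
        for s, g, a in zip(samples, genotypes, activities):
            gkey = str(g).strip().lower()
            akey = str(a).strip().lower()
            if gkey not in _GENOTYPE_TOKENS:
                raise ValueError(f"unknown genotype token {g!r} for sample {s!r}")
            if akey not in _ACTIVITY_TOKENS:
                raise ValueError(f"unknown activity token {a!r} for sample {s!r}")
            geno.append(_GENOTYPE_TOKENS[gkey])
            act.append(_ACTIVITY_TOKENS[akey])
        table = pd.DataFrame(
            {"genotype": geno, "activity": act}, index=pd.Index(samples, name="sample")
        )
        return cls(table)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    @property
    def groups_present(self) -> set[str]:
        return set(self.table["group"])


@dataclass
class ContrastResult:
    """Per-gene log2 fold change, raw P and BH-adjusted P for one comparison."""

    name: str
    table: pd.DataFrame  # index: gene id; columns: lfc, p, q (+ optional excluded)

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def log2_fold_change(
    mean_ref: float, mean_alt: float, pseudocount: float = 0.0
) -> float:
    """log2((mean_alt + c) / (mean_ref + c)); antisymmetric in its arguments."""
    num = mean_alt + pseudocount
    den = mean_ref + pseudocount
    if num <= 0 or den <= 0:
        raise ValueError(
            "log2 fold change undefined: use a positive pseudocount when a mean can be 0"
        )
    return math.log2(num) - math.log2(den)


def welch_test(values_a, values_b) -> tuple[float, float, float]:
    """Welch's two-sided t-test: returns (statistic, df, p).

    Degenerate zero-variance inputs are resolved deterministically: equal
    means give p = 1, unequal means give p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test requires at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.copysign(math.inf, b.mean() - a.mean()), float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(b, a, equal_var=False)  # statistic oriented as b - a
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _log_values(norm: NormalizedMatrix, pseudocount: float) -> pd.DataFrame:
    if pseudocount <= 0 and (norm.values.to_numpy() <= 0).any():
        raise ValueError("pseudocount must be > 0 when the matrix contains zeros")
    return np.log2(norm.values + pseudocount)


def _welch_rows(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test on 2-D (genes x replicates) arrays."""
    n1, n2 = A.shape[1], B.shape[1]
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    v1, v2 = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0.0
    if degenerate.any():
        eq = degenerate & (m1 == m2)
        diff = (m2 - m1)[degenerate]
        t[degenerate] = np.where(eq[degenerate], 0.0, np.copysign(np.inf, diff))
        df[degenerate] = n1 + n2 - 2
        p[degenerate] = np.where(eq[degenerate], 1.0, 0.0)
    return t, df, p


def _require_groups(design: SampleDesign, groups=GROUPS) -> None:
    missing = sorted(set(groups) - design.groups_present)
    if missing:
        raise ValueError(f"design is missing group(s): {missing}")


def run_pairwise_contrasts(
    norm: NormalizedMatrix,
    design: SampleDesign,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, ContrastResult]:
    """Test the six canonical pairwise contrasts.

    Fold change for contrast "A-B" is log2 of the ratio of group mean
    normalized values (B over A, pseudocount-stabilized); P-values come from
    row-wise Welch tests on log2(x + pseudocount), BH-adjusted per contrast.
    """
    _require_groups(design)
    missing = sorted(set(design.table.index) - set(norm.values.columns))
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing}")
    logm = _log_values(norm, pseudocount)
    results: dict[str, ContrastResult] = {}
    for name in CONTRASTS:
        ref, alt = name.split("-")
        ref_cols = design.samples_in_group(ref)
        alt_cols = design.samples_in_group(alt)
        mean_ref = norm.values[ref_cols].mean(axis=1).to_numpy()
        mean_alt = norm.values[alt_cols].mean(axis=1).to_numpy()
        lfc = np.log2(mean_alt + pseudocount) - np.log2(mean_ref + pseudocount)
        _, _, p = _welch_rows(logm[ref_cols].to_numpy(), logm[alt_cols].to_numpy())
        q = bh_adjust(p)
        results[name] = ContrastResult(
            name, pd.DataFrame({"lfc": lfc, "p": p, "q": q}, index=norm.values.index)
        )
    return results


def test_interaction(
    norm: NormalizedMatrix,
    design: SampleDesign,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene activity-by-genotype interaction on the log2 scale.

    delta = (mean_AM - mean_IM) - (mean_AW - mean_IW) of log2(x + pseudocount),
    i.e. the deviation of the combined condition from additivity of the two
    marginal effects. The t reference uses a Welch-Satterthwaite df pooled
    over the four groups. Returns columns delta, p, q.
    """
    _require_groups(design)
    logm = _log_values(norm, pseudocount)
    means, varn, varn2 = {}, [], []
    dfs_terms = []
    for g in GROUPS:
        cols = design.samples_in_group(g)
        X = logm[cols].to_numpy()
        n = X.shape[1]
        means[g] = X.mean(axis=1)
        v = X.var(axis=1, ddof=1)
        varn.append(v / n)
        dfs_terms.append((v / n) ** 2 / (n - 1))
    delta = (means["AM"] - means["IM"]) - (means["AW"] - means["IW"])
    se2 = np.sum(varn, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        df = se2**2 / np.sum(dfs_terms, axis=0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0.0
    if degenerate.any():
        p[degenerate] = np.where(delta[degenerate] == 0.0, 1.0, 0.0)
    q = bh_adjust(p)
    return pd.DataFrame({"delta": delta, "p": p, "q": q}, index=norm.values.index)


def test_main_effects(
    norm: NormalizedMatrix,
    design: SampleDesign,
    interaction_q,
    exclusion_threshold: float = 0.005,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[ContrastResult, ContrastResult, pd.Series]:
    """Pooled main-effect tests with interaction-significant genes flagged.

    main_genotype pools {IW, AW} vs {IM, AM} (lfc = log2 MR/WT); main_activity
    pools {IW, IM} vs {AW, AM} (lfc = log2 active/inactive). Genes with
    interaction q below ``exclusion_threshold`` get ``excluded=True``:
    statistics are still computed, but reported main-effect gene lists omit
    them.
    """
    _require_groups(design)
    iq = pd.Series(np.asarray(interaction_q, dtype=float), index=norm.values.index)
    if iq.isna().any():
        raise ValueError("interaction_q misaligned with gene list")
    excluded = iq < exclusion_threshold
    excluded.name = "excluded"
    logm = _log_values(norm, pseudocount)
    out = []
    for name, ref_groups, alt_groups in (
        ("main_genotype", ("IW", "AW"), ("IM", "AM")),
        ("main_activity", ("IW", "IM"), ("AW", "AM")),
    ):
        ref_cols = [s for g in ref_groups for s in design.samples_in_group(g)]
        alt_cols = [s for g in alt_groups for s in design.samples_in_group(g)]
        mean_ref = norm.values[ref_cols].mean(axis=1).to_numpy()
        mean_alt = norm.values[alt_cols].mean(axis=1).to_numpy()
        lfc = np.log2(mean_alt + pseudocount) - np.log2(mean_ref + pseudocount)
        _, _, p = _welch_rows(logm[ref_cols].to_numpy(), logm[alt_cols].to_numpy())
        q = bh_adjust(p)
        out.append(
            ContrastResult(
                name,
                pd.DataFrame(
                    {"lfc": lfc, "p": p, "q": q, "excluded": excluded.to_numpy()},
                    index=norm.values.index,
                ),
            )
        )
    return out[0], out[1], excluded


def select_de_genes(
    result: ContrastResult, q_threshold: float = 0.005, lfc_threshold: float = 1.3
) -> list[str]:
    """Genes with q <= q_threshold and |lfc| >= lfc_threshold.

    Both boundaries are inclusive; genes are returned in descending |lfc|
    order (ties broken by gene id). If the result carries an ``excluded``
    flag (main effects), flagged genes are omitted.
    """
    if q_threshold <= 0 or lfc_threshold < 0:
        raise ValueError("thresholds must be positive")
    t = result.table
    keep = (t["q"] <= q_threshold) & (t["lfc"].abs() >= lfc_threshold)
    if "excluded" in t.columns:
        keep &= ~t["excluded"].astype(bool)
    sel = t.loc[keep]
    order = sorted(sel.index, key=lambda g: (-abs(sel.at[g, "lfc"]), str(g)))
    return [str(g) for g in order]
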