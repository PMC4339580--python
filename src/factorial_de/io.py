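"""Readers and writers for the pipeline's plain-text formats.

Count matrices and designs travel as TSV (or CSV, auto-detected from the
extension); gene sets as standard GMT. All writer/reader pairs round-trip
losslessly at full float precision.
"""

from __future__ import annotations

import os

import pandas as pd

from factorial_de.contrasts import ContrastResult, SampleDesign
from factorial_de.enrichment import GeneSetCollection
from factorial_de.normalization import CountMatrix, NormalizedMatrix


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_counts(path, mito_genes=None) -> CountMatrix:
    """Read a gene x sample matrix; first column gene id, header sample ids.

    The mitochondrial flag comes from an ``is_mito`` column if present,
    otherwise from the ``mito_genes`` id list (default: no gene is
    mitochondrial).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if "is_mito" in df.columns:
        is_mito = df.pop("is_mito").astype(bool)
    elif mito_genes is not None:
        wanted = set(mito_genes)
        unknown = wanted - set(df.index)
        if unknown:
            raise ValueError(f"mito gene ids not in matrix: {sorted(unknown)[:5]}")
        is_mito = pd.Series(df.index.isin(wanted), index=df.index)
    else:
        is_mito = pd.Series(False, index=df.index)
    return CountMatrix(values=df, is_mito=is_mito)


def write_counts(matrix: CountMatrix, path) -> None:
    out = matrix.values.copy()
    out["is_mito"] = matrix.is_mito.astype(int)
    out.index.name = "gene"
    out.to_csv(path, sep=_sep_for(path))


def read_design(path) -> SampleDesign:
    """Read a sample design table with columns sample, genotype, activity."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample", "genotype", "activity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file missing column(s): {sorted(missing)}")
    return SampleDesign.from_tokens(
        df["sample"].astype(str).tolist(), df["genotype"], df["activity"]
    )


def write_design(design: SampleDesign, path) -> None:
    out = design.table[["genotype", "activity"]].copy()
    out.index.name = "sample"
    out.to_csv(path, sep=_sep_for(path))


def read_gmt(path, background=None) -> GeneSetCollection:
    """Read a GMT gene-set file (term id, description, member genes...).

    The background universe defaults to the union of all members unless an
    explicit iterable of gene ids is supplied.
    """
    sets: dict[str, tuple[str, set]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 member"
                )
            tid, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: term {tid!r} has no members")
            if tid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term id {tid!r}")
            sets[tid] = (desc, set(members))
    return GeneSetCollection.from_sets(sets, background=background)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(collection.terms):
            desc, members = collection.terms[tid]
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")


def write_contrast(result: ContrastResult, path) -> None:
    out = result.table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_normalized(norm: NormalizedMatrix, path) -> None:
    out = norm.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
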