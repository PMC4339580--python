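"""Packaged transcriptions of the source study's printed result tables.

These small TSVs are the exact inputs the test suite uses as oracles: the
headline differential-expression gene lists for the genotype and activity main
effects (tables 7 and 9), the shared-gene list of the inactive-wild-type Venn
triplet (table 2), the top interaction genes with their six-contrast fold
changes (table 1), and the enriched functional-category clusters with printed
member P-values (tables 4, 8 and 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

_FILES = {
    "T1": "table1.tsv",
    "T2": "table2.tsv",
    "T4": "table4.tsv",
    "T7": "table7.tsv",
    "T8": "table8.tsv",
    "T9": "table9.tsv",
    "T10": "table10.tsv",
}

#: Printed row counts, enforced on load.
_ROW_COUNTS = {"T1": 34, "T2": 34, "T4": 15, "T7": 13, "T8": 5, "T9": 21, "T10": 17}


@dataclass
class FixtureTable:
    table_id: str
    data: pd.DataFrame


def load_fixture(table_id: str) -> FixtureTable:
    """Load one packaged table by id ('T1', 'T2', 'T4', 'T7', 'T8', 'T9', 'T10')."""
    if table_id not in _FILES:
        raise ValueError(
            f"unknown fixture table {table_id!r}; available: {sorted(_FILES)}"
        )
    ref = resources.files("factorial_de").joinpath("data/tables", _FILES[table_id])
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    expected = _ROW_COUNTS[table_id]
    if len(df) != expected:
        raise RuntimeError(
            f"fixture {table_id} has {len(df)} rows, expected {expected}"
        )
    return FixtureTable(table_id=table_id, data=df)
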