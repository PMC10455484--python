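"""Packaged transcriptions of the published summary tables.

Four tables ship with the package as TSV files:

* ``table4`` — per-species curation outcome of the genome-wide P450 search in
  19 Pezizomycetes: total InterPro hits and their split into true P450s,
  fragments, false positives and no-hits, with lifestyle labels (SAP/ECM).
* ``table5`` — per-family member and subfamily counts across the cohort
  (153 families, 668 members, 245 subfamilies).
* ``table6`` — per-species family and subfamily counts.
* ``table7`` — per-species secondary-metabolite biosynthetic gene cluster
  counts for the 12 species with cluster predictions; the companion
  ``table7_p450s`` lists the nine P450 cluster memberships.

Row counts and column totals are asserted at load time so a transcription
error cannot silently propagate into downstream statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_TABLE_FILES = {
    "table4": "table4.tsv",
    "table5": "table5.tsv",
    "table6": "table6.tsv",
    "table7": "table7.tsv",
    "table7_p450s": "table7_p450s.tsv",
}

_EXPECTED_ROWS = {
    "table4": 19,
    "table5": 153,
    "table6": 19,
    "table7": 12,
    "table7_p450s": 9,
}


def _validate(table_id: str, df: pd.DataFrame) -> None:
    if len(df) != _EXPECTED_ROWS[table_id]:
        raise ValueError(
            f"{table_id}: expected {_EXPECTED_ROWS[table_id]} rows, "
            f"got {len(df)}")
    if table_id == "table4":
        checks = {
            "total_hits": 779, "p450s": 668, "fragments": 88,
            "false_positives": 7, "no_hits": 16,
        }
        for col, expected in checks.items():
            got = int(df[col].sum())
            if got != expected:
                raise ValueError(
                    f"table4: column {col} sums to {got}, expected {expected}")
        parts = df[["p450s", "fragments", "false_positives", "no_hits"]]
        if not (parts.sum(axis=1) == df["total_hits"]).all():
            raise ValueError("table4: category counts do not partition hits")
    elif table_id == "table5":
        if int(df["members"].sum()) != 668:
            raise ValueError("table5: member counts do not sum to 668")
        if int(df["n_subfamilies"].sum()) != 245:
            raise ValueError("table5: subfamily counts do not sum to 245")
    elif table_id == "table7":
        if int(df["n_clusters"].sum()) != 142:
            raise ValueError("table7: cluster counts do not sum to 142")


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load one packaged table by id (``table4`` ... ``table7``).

    ``table7_p450s`` is also accepted and returns the P450 cluster-membership
    companion of table7.
    """
    if table_id not in _TABLE_FILES:
        raise KeyError(
            f"unknown table id {table_id!r}; "
            f"known: {sorted(_TABLE_FILES)}")
    ref = resources.files("cypome.data") / _TABLE_FILES[table_id]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    _validate(table_id, df)
    return df


def species_meta_from_table4() -> pd.DataFrame:
    """Species metadata (id, display name, lifestyle) as recorded in table4."""
    return load_fixture("table4")[["species_id", "display_name", "lifestyle"]]
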