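"""Table readers/writers and packaged synthetic fixtures.

The tabular formats are plain TSV:

* count tables — columns ``assay_id``, ``block``, ``phenotype_class``,
  ``count``;
* trajectory tables — columns ``population``, ``generation``,
  ``n_xxy_females``, ``n_xx_females``, ``n_males_total``;
* detection tables — columns ``family_id``, ``method``, ``k_tested``,
  ``detected``.

The packaged fixtures are synthetic stand-ins for the study's raw count
tables, constructed by the generators in :mod:`karyodyn.synth` and frozen
so the full pipeline runs without any download; see each loader's
docstring.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .abc import read_detection_table
from .inference import CountTable, REQUIRED_COLUMNS
from .designs import builtin_designs

__all__ = [
    "read_counts",
    "write_counts",
    "read_trajectories",
    "write_trajectories",
    "load_ndj_counts",
    "load_trajectories",
    "load_detection",
    "NDJ_DESIGN_MAP",
]

TRAJECTORY_COLUMNS = ("population", "generation", "n_xxy_females",
                      "n_xx_females", "n_males_total")

#: assay id -> built-in design name for the packaged nondisjunction counts
NDJ_DESIGN_MAP = {
    "ndj_survey": "spontaneous_pooled_females",
    "ndj_full": "spontaneous_pooled",
    "ndj_sexed": "spontaneous_sexed",
}


def _read_table(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        return path_or_df
    df = pd.read_csv(path_or_df, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"empty table: {path_or_df}")
    return df


def read_counts(path, designs: dict | None = None) -> CountTable:
    """Read and validate an offspring count table (TSV/CSV).

    When ``designs`` (assay_id -> CrossDesign) is given, phenotype classes
    are checked against each assay's design; unknown classes raise with
    the offending names listed.
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    table = CountTable(df[list(REQUIRED_COLUMNS)].copy())
    if designs is not None:
        table.validate_classes(designs)
    return table


def write_counts(table: CountTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_trajectories(path) -> pd.DataFrame:
    """Read a trajectory table; validates columns and value ranges."""
    df = _read_table(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    for col in TRAJECTORY_COLUMNS[1:]:
        if (df[col] < 0).any():
            raise ValueError(f"negative values in column {col!r}")
    return df[list(TRAJECTORY_COLUMNS)].copy()


def write_trajectories(df: pd.DataFrame, path) -> None:
    df[list(TRAJECTORY_COLUMNS)].to_csv(path, sep="\t", index=False)


def _data_path(name: str):
    return resources.files("karyodyn.data").joinpath(name)


def load_ndj_counts():
    """Packaged nondisjunction count fixture and its designs.

    Synthetic stand-in for the study's spontaneous-nondisjunction count
    tables (38178 offspring over three assays: a female-only survey, a
    fully scored batch of the same cross, and the Bar-Y sexed test
    cross), constructed so the combined ML fit reproduces the published
    rate estimates.  Returns ``(CountTable, designs_by_assay)``.
    """
    designs = builtin_designs()
    with resources.as_file(_data_path("synthetic_ndj_counts.tsv")) as p:
        table = read_counts(p)
    assay_designs = {aid: designs[name] for aid, name in NDJ_DESIGN_MAP.items()}
    table.validate_classes(assay_designs)
    return table, assay_designs


def load_trajectories() -> pd.DataFrame:
    """Packaged experimental-evolution fixture (synthetic stand-in).

    Three populations of census 287 founded by 60 XXY females and 60 XY
    males, followed for 12 generations; the pooled logistic slope is
    anchored to the decline the study reports.
    """
    with resources.as_file(_data_path("synthetic_trajectories.tsv")) as p:
        return read_trajectories(p)


def load_detection():
    """Packaged detection fixture (synthetic stand-in).

    158 test-cross families (775 sons total, 1-6 tested per family, mean
    4.9) with one detection, plus 75 PCR-assayed females with one
    detection.  Returns ``(assays, observed)``.
    """
    with resources.as_file(_data_path("synthetic_detection.tsv")) as p:
        return read_detection_table(p)
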