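"""Descriptor-table I/O and bundled reference data.

Descriptor tables follow the PaDEL-Descriptor CSV layout: a header row, a
first column ``Name`` holding compound labels, and one numeric column per
descriptor.  An activity column (pIC50) may live in the same file and is
split out on read.

The printed experimental/predicted activity tables of the source study —
24 ester compounds assayed against the MiaPaCa-2 pancreatic cancer cell
line — ship as built-in fixtures so the published statistics can be
recomputed without any external download.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "QsarDataset",
    "read_descriptor_table",
    "write_descriptor_table",
    "load_fixture",
    "ic50_to_pic50",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("table4", "table5", "table10")

LABEL_COLUMN = "Name"


@dataclass
class DescriptorTable:
    """Compounds × descriptors matrix with unique labels on both axes.

    ``data`` is a pandas DataFrame indexed by compound label (str) with one
    float column per descriptor.  Missing entries are NaN and are permitted
    on read; downstream operations reject them unless documented otherwise.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate compound label(s): {dupes}")
        cols = self.data.columns
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate descriptor name(s): {dupes}")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_compounds(self) -> int:
        return self.data.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.data.shape[1]

    def select(self, descriptor_names: list[str]) -> "DescriptorTable":
        missing = [d for d in descriptor_names if d not in self.data.columns]
        if missing:
            raise KeyError(f"unknown descriptor(s): {missing}")
        return DescriptorTable(self.data[descriptor_names].copy())


@dataclass
class QsarDataset:
    """A descriptor table joined with a pIC50 activity vector.

    ``partition``, when present, tags every compound as ``"train"`` or
    ``"test"`` exactly once.
    """

    table: DescriptorTable
    activity: pd.Series
    partition: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.activity = self.activity.astype(float)
        self.activity.index = self.activity.index.astype(str)
        if list(self.activity.index) != self.table.compound_ids:
            if len(self.activity) != self.table.n_compounds:
                raise ValueError(
                    "activity length does not match number of compounds"
                )
            self.activity = self.activity.reindex(self.table.compound_ids)
            if self.activity.isna().any():
                raise ValueError("activity labels do not match compound ids")
        if self.partition is not None:
            self.partition = self.partition.astype(str)
            self.partition.index = self.partition.index.astype(str)
            self.partition = self.partition.reindex(self.table.compound_ids)
            bad = set(self.partition.dropna().unique()) - {"train", "test"}
            if bad or self.partition.isna().any():
                raise ValueError(
                    "partition must tag every compound as 'train' or 'test'"
                )

    @property
    def compound_ids(self) -> list[str]:
        return self.table.compound_ids

    @property
    def y(self) -> np.ndarray:
        return self.activity.to_numpy(dtype=float)

    def subset(self, which: str) -> "QsarDataset":
        """Return the train or test rows as a new dataset (partition dropped)."""
        if self.partition is None:
            raise ValueError("dataset has no partition")
        if which not in ("train", "test"):
            raise ValueError("which must be 'train' or 'test'")
        mask = (self.partition == which).to_numpy()
        return QsarDataset(
            DescriptorTable(self.table.data.loc[mask].copy()),
            self.activity.loc[mask].copy(),
        )

    def with_partition(self, partition: pd.Series) -> "QsarDataset":
        return QsarDataset(self.table, self.activity, partition)


def read_descriptor_table(
    path: str | Path, activity_column: str | None = None
) -> QsarDataset:
    """Read a PaDEL-style descriptor CSV into a :class:`QsarDataset`.

    The first column holds compound labels.  All other columns are parsed as
    numeric descriptors; non-numeric cells become NaN.  When
    ``activity_column`` is given, that column is split out as the activity.
    A ``set`` column holding train/test tags, if present, becomes the
    partition.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str)
    if raw.empty and raw.columns.size == 0:
        raise ValueError(f"empty descriptor file: {path}")
    label_col = raw.columns[0]
    labels = raw[label_col].astype(str)
    if labels.duplicated().any():
        dupes = labels[labels.duplicated()].unique().tolist()
        raise ValueError(f"duplicate compound label(s): {dupes}")
    body = raw.drop(columns=[label_col])
    body.index = pd.Index(labels, name=LABEL_COLUMN)

    partition = None
    if "set" in body.columns:
        partition = body.pop("set")

    numeric = body.apply(pd.to_numeric, errors="coerce")

    activity = None
    if activity_column is not None:
        if activity_column not in numeric.columns:
            raise KeyError(
                f"activity column {activity_column!r} not found in {path}"
            )
        activity = numeric.pop(activity_column)

    table = DescriptorTable(numeric)
    if activity is None:
        # no activity requested: NaN activity vector, same labels
        activity = pd.Series(np.nan, index=numeric.index, name="activity")
    return QsarDataset(table, activity, partition)


def write_descriptor_table(dataset: QsarDataset, path: str | Path) -> None:
    """Write a dataset back to the CSV dialect ``read_descriptor_table`` accepts.

    Values are rendered at full precision; missing values become empty cells.
    """
    path = Path(path)
    out = dataset.table.data.copy()
    if not np.all(np.isnan(dataset.y)):
        out[dataset.activity.name or "activity"] = dataset.activity
    if dataset.partition is not None:
        out["set"] = dataset.partition
    out.index.name = LABEL_COLUMN
    out.to_csv(path, float_format="%.17g")


def _fixture_frame(name: str) -> pd.DataFrame:
    ref = resources.files("qsarforge.fixtures").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, dtype={0: str}).set_index(LABEL_COLUMN)


def load_fixture(name: str) -> QsarDataset:
    """Load one of the bundled printed tables as a :class:`QsarDataset`.

    - ``table4``: 24 compounds; experimental pIC50 as activity, the QSAR
      model's predicted pIC50 and printed residual as columns, and the
      published 16 train / 8 test partition.
    - ``table5``: the 8 test compounds with raw values of the four model
      descriptors (ATSC3c, MATS5p, minHBint5, ETA_Shape_P) plus the
      predicted activity column; experimental pIC50 as activity.
    - ``table10``: 24 compounds with QSAR, ELM-sine and ELM-sigmoid
      predictions and per-compound percentage errors; experimental pIC50 as
      activity.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
    frame = _fixture_frame(name)
    partition = None
    if "set" in frame.columns:
        partition = frame.pop("set")
    activity = frame.pop("pIC50_exp")
    activity.name = "pIC50"
    return QsarDataset(DescriptorTable(frame), activity, partition)


def ic50_to_pic50(ic50_um: float) -> float:
    """Convert a micromolar IC50 to pIC50 = −log10(IC50 in mol/L).

    Expressed on the micromolar input this is ``6 − log10(IC50[µM])``, the
    only convention consistent with the study's 4.0–5.5 activity range
    (1 µM → 6.0).
    """
    if not ic50_um > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_um}")
    return 6.0 - math.log10(ic50_um)
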