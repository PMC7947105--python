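"""Descriptor pretreatment and training/test-set division.

Pretreatment removes descriptors that carry no usable signal before model
building: columns with missing values, near-constant columns, and one of
each highly intercorrelated pair.  Min–max normalization (Eq. ``(x −
min)/(max − min)``) is available as an optional aid; the published model
was fitted on raw descriptor values, so normalization is never applied
implicitly.

The Kennard–Stone algorithm divides compounds into a space-covering
training set and a test set: it seeds with the two most distant compounds
in descriptor space and then repeatedly adds the compound whose minimum
distance to the already-selected set is largest.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .dataio import DescriptorTable, QsarDataset

__all__ = [
    "PretreatConfig",
    "RemovalReport",
    "normalize_minmax",
    "pretreat",
    "kennard_stone_split",
    "random_split",
]


@dataclass
class PretreatConfig:
    """Settings for :func:`pretreat`.

    variance_epsilon
        Descriptors whose value range or variance falls below this are
        dropped as near-constant.  Default 1e-4.
    correlation_cutoff
        For each pair with absolute Pearson correlation above this, the
        later column is dropped.  Default 0.95.
    normalize_first
        Min–max normalize surviving descriptors after filtering.
    """

    variance_epsilon: float = 1e-4
    correlation_cutoff: float = 0.95
    normalize_first: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.correlation_cutoff <= 1.0):
            raise ValueError("correlation_cutoff must lie in (0, 1]")
        if self.variance_epsilon < 0:
            raise ValueError("variance_epsilon must be non-negative")


@dataclass
class RemovalReport:
    """Which descriptors :func:`pretreat` removed and why."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    def names(self, reason: str | None = None) -> list[str]:
        return [n for n, r in self.removed if reason is None or r == reason]

    def __len__(self) -> int:
        return len(self.removed)


def normalize_minmax(table: DescriptorTable) -> DescriptorTable:
    """Rescale every descriptor column to [0, 1].

    Raises if any column is constant (remove those with :func:`pretreat`
    first).
    """
    vals = table.values
    lo = np.nanmin(vals, axis=0)
    hi = np.nanmax(vals, axis=0)
    span = hi - lo
    constant = np.flatnonzero(span == 0)
    if constant.size:
        names = [table.descriptor_names[i] for i in constant]
        raise ValueError(f"constant descriptor(s) cannot be normalized: {names}")
    scaled = (vals - lo) / span
    return DescriptorTable(
        pd.DataFrame(scaled, index=table.data.index, columns=table.data.columns)
    )


def pretreat(
    dataset: QsarDataset, config: PretreatConfig | None = None
) -> tuple[QsarDataset, RemovalReport]:
    """Remove uninformative and redundant descriptors.

    Removal reasons, applied in order:

    1. ``"missing values"`` — any NaN entry;
    2. ``"near-zero variance"`` — value range or variance below
       ``variance_epsilon``;
    3. ``"correlation"`` — |Pearson r| with an earlier-kept descriptor
       above ``correlation_cutoff``.

    Kept-descriptor order is preserved, which makes the operation
    idempotent.
    """
    config = config or PretreatConfig()
    frame = dataset.table.data
    report = RemovalReport()
    keep: list[str] = []

    vals = frame.to_numpy(dtype=float)
    candidates: list[int] = []
    for j, name in enumerate(frame.columns):
        col = vals[:, j]
        if np.isnan(col).any():
            report.removed.append((name, "missing values"))
            continue
        if np.ptp(col) < config.variance_epsilon or np.var(col) < config.variance_epsilon:
            report.removed.append((name, "near-zero variance"))
            continue
        candidates.append(j)

    if candidates:
        sub = vals[:, candidates]
        corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(corr)
        kept_pos: list[int] = []
        for local, j in enumerate(candidates):
            name = frame.columns[j]
            if kept_pos and np.any(
                np.abs(corr[local, kept_pos]) > config.correlation_cutoff
            ):
                report.removed.append((name, "correlation"))
                continue
            kept_pos.append(local)
            keep.append(name)

    if not keep:
        raise ValueError("pretreatment removed every descriptor")

    table = DescriptorTable(frame[keep].copy())
    if config.normalize_first:
        table = normalize_minmax(table)
    return QsarDataset(table, dataset.activity, dataset.partition), report


def _normalized_coords(table: DescriptorTable, normalize: bool) -> np.ndarray:
    vals = table.values
    if np.isnan(vals).any():
        raise ValueError("Kennard-Stone requires a table without missing values")
    if not normalize:
        return vals
    lo = vals.min(axis=0)
    span = vals.max(axis=0) - lo
    span[span == 0] = 1.0  # constant columns contribute nothing either way
    return (vals - lo) / span


def kennard_stone_split(
    table: DescriptorTable, train_fraction: float, *, normalize: bool = True
) -> pd.Series:
    """Deterministic max–min-distance train/test division.

    Selects ``floor(train_fraction · n)`` training compounds: first the
    most distant pair (Euclidean, on min–max normalized descriptors by
    default), then repeatedly the compound maximizing the minimum distance
    to the selected set.  Ties break toward the lowest compound index.
    Returns a per-compound partition Series of ``"train"``/``"test"`` tags.
    """
    n = table.n_compounds
    if n < 2:
        raise ValueError("need at least two compounds to split")
    n_train = int(train_fraction * n)
    if n_train < 2 or n_train >= n:
        raise ValueError(
            f"train_fraction {train_fraction} gives {n_train} training "
            f"compounds out of {n}; need >=2 train and >=1 test"
        )
    coords = _normalized_coords(table, normalize)
    dist = squareform(pdist(coords))

    # Seed: the pair at maximum distance, lexicographically first on ties.
    iu = np.triu_indices(n, k=1)
    flat = dist[iu]
    best = np.flatnonzero(flat == flat.max())[0]
    selected = [int(iu[0][best]), int(iu[1][best])]

    remaining = [i for i in range(n) if i not in selected]
    while len(selected) < n_train:
        dmin = dist[np.ix_(remaining, selected)].min(axis=1)
        pick = remaining[int(np.argmax(dmin))]  # argmax keeps first on ties
        selected.append(pick)
        remaining.remove(pick)

    tags = np.full(n, "test", dtype=object)
    tags[selected] = "train"
    return pd.Series(tags, index=table.data.index, name="set")


def random_split(
    table: DescriptorTable, train_fraction: float, seed: int
) -> pd.Series:
    """Seeded uniformly-random partition (used by the ELM 4:1 protocol)."""
    n = table.n_compounds
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("train_fraction leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tags = np.full(n, "test", dtype=object)
    tags[order[:n_train]] = "train"
    return pd.Series(tags, index=table.data.index, name="set")
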