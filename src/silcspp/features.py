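"""Feature-table and sample-design ingestion, co-elution grouping, and
per-time-point aggregation.

A feature table is a pandas DataFrame with columns ``id``, ``mz``, ``rt`` and
one intensity column per sample; intensities of zero mean "not detected"
(below the detection limit).  The sample design maps each sample column to a
time point (hours after feeding) and a biological replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TIMES_H",
    "DEFAULT_REPLICATES",
    "SampleDesign",
    "read_feature_table",
    "write_feature_table",
    "group_by_coelution",
    "mean_by_timepoint",
]

#: The feeding-experiment layout: sampling times in hours after feeding.
DEFAULT_TIMES_H: tuple[float, ...] = (0, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 24, 36)
DEFAULT_REPLICATES: int = 3

META_COLUMNS = ("id", "mz", "rt")


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample ids to (time point, replicate), in canonical order."""

    table: pd.DataFrame  # columns: sample, time_h, replicate

    def __post_init__(self) -> None:
        required = {"sample", "time_h", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design is missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        canon = self.table.sort_values(["time_h", "replicate"], kind="mergesort")
        object.__setattr__(self, "table", canon.reset_index(drop=True))
        counts = self.table.groupby("time_h").size()
        if (counts < 1).any():
            raise ValueError("every time point needs at least one replicate")

    @classmethod
    def default(
        cls,
        times_h: tuple[float, ...] = DEFAULT_TIMES_H,
        n_replicates: int = DEFAULT_REPLICATES,
    ) -> "SampleDesign":
        rows = [
            {"sample": f"t{i:02d}_r{r}", "time_h": t, "replicate": r}
            for i, t in enumerate(times_h)
            for r in range(1, n_replicates + 1)
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def times(self) -> np.ndarray:
        return np.array(sorted(self.table["time_h"].unique()))

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def samples_at(self, time_h: float) -> list[str]:
        return list(self.table.loc[self.table["time_h"] == time_h, "sample"])


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_feature_table(
    path: str | Path, design: SampleDesign | str | Path
) -> tuple[pd.DataFrame, SampleDesign]:
    """Read and validate a feature table against its sample design.

    Sample columns are reordered canonically by (time point, replicate).
    """
    if not isinstance(design, SampleDesign):
        design = SampleDesign.from_csv(design)
    df = _read_table(path)
    for col in META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"feature table is missing column {col!r}")
    missing = [s for s in design.samples if s not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing intensity columns for samples: {missing}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")
    extra = [
        c for c in df.columns if c not in META_COLUMNS and c not in design.samples
    ]
    if extra:
        raise ValueError(f"samples in table absent from design: {extra}")
    if (df["mz"] <= 0).any():
        raise ValueError("m/z values must be positive")
    if (df["rt"] < 0).any():
        raise ValueError("retention times must be nonnegative")
    df = df[list(META_COLUMNS) + design.samples].copy()
    values = df[design.samples].to_numpy(float)
    if (values < 0).any():
        raise ValueError("intensities must be nonnegative")
    return df.reset_index(drop=True), design


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    features.to_csv(path, sep=sep, index=False)


def group_by_coelution(features: pd.DataFrame, rt_tol: float = 0.1) -> pd.Series:
    """Single-linkage grouping of features on retention time.

    Two features are chained into one group whenever their RT difference is
    within ``rt_tol`` minutes; the result is the transitive closure, which for
    one dimension reduces to chaining sorted adjacent gaps.  Group ids are
    1-based, ordered by the minimum RT of the group.  Returns a Series mapping
    feature id -> group id (a partition of the feature set).
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    order = features[["id", "rt"]].sort_values(["rt", "id"], kind="mergesort")
    group_ids = np.zeros(len(order), dtype=int)
    current = 0
    prev_rt = None
    for i, rt in enumerate(order["rt"].to_numpy(float)):
        if prev_rt is None or rt - prev_rt > rt_tol:
            current += 1
        group_ids[i] = current
        prev_rt = rt
    return pd.Series(group_ids, index=order["id"], name="group").reindex(features["id"])


def mean_by_timepoint(features: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Per-time-point mean intensity over replicates (missing counted as 0).

    Returns a DataFrame indexed by feature id with one column per time value.
    """
    out = {}
    for t in design.times:
        cols = design.samples_at(t)
        out[t] = features[cols].to_numpy(float).mean(axis=1)
    result = pd.DataFrame(out, index=features["id"])
    result.columns.name = "time_h"
    return result
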