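"""Time-course profiles, shape-based-distance clustering, and the
native-reference dendrogram cut.

Profiles are per-time-point replicate means.  Before clustering each profile
is z-normalized (mean 0, SD 1 with the n-1 denominator); the shape-based
distance (SBD) between two series is 1 minus the maximum of the normalized
cross-correlation over all integer lags, as in the k-Shape clustering
literature, giving a scale- and shift-invariant dissimilarity in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .features import SampleDesign, mean_by_timepoint
from .sil_trace import Multiplet

__all__ = [
    "ConstantProfileError",
    "znorm",
    "sbd",
    "sbd_matrix",
    "ClusterResult",
    "hcluster",
    "native_reference_cut",
    "RatioProfile",
    "ratio_profiles",
    "peak_time",
]


class ConstantProfileError(ValueError):
    """Raised for series with zero standard deviation."""


def znorm(series: Sequence[float]) -> np.ndarray:
    """(x - mean) / SD with the n-1 denominator; constant series are rejected."""
    x = np.asarray(series, float)
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ConstantProfileError("constant series cannot be z-normalized")
    return (x - x.mean()) / sd


def sbd(x: Sequence[float], y: Sequence[float]) -> float:
    """Shape-based distance: 1 - max_w CC_w(x, y) / sqrt(CC_0(x,x) CC_0(y,y)).

    CC_w is the zero-padded cross-correlation at integer lag w over the full
    lag range -(L-1)..L-1.  Bounded in [0, 2]; 0 for identical (or positively
    scaled) inputs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
    if denom == 0:
        raise ConstantProfileError("all-zero series has no shape")
    ncc = np.correlate(x, y, mode="full") / denom
    return float(max(0.0, 1.0 - ncc.max()))


def sbd_matrix(profiles: np.ndarray) -> np.ndarray:
    """Condensed pairwise SBD matrix over rows of ``profiles``."""
    n = profiles.shape[0]
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[idx] = sbd(profiles[i], profiles[j])
            idx += 1
    return out


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of named profiles.

    ``linkage`` is a scipy linkage matrix over ``ids`` (leaf order matches).
    """

    ids: tuple[str, ...]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def labels(self, k: int | None = None, height: float | None = None) -> dict[str, int]:
        if (k is None) == (height is None):
            raise ValueError("give exactly one of k or height")
        if k is not None:
            flat = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        else:
            flat = hierarchy.fcluster(self.linkage, height, criterion="distance")
        return {fid: int(label) for fid, label in zip(self.ids, flat)}

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            length = max(0.0, (node.parent_dist if hasattr(node, "parent_dist") else 0.0))
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6f}"
            left, right = node.get_left(), node.get_right()
            for child in (left, right):
                child.parent_dist = node.dist - child.dist
            return f"({render(left)},{render(right)}):{length:.6f}"

        tree.parent_dist = 0.0
        return render(tree) + ";"


def hcluster(
    profiles: Mapping[str, Sequence[float]] | pd.DataFrame,
    linkage: str = "average",
    normalize: bool = True,
) -> ClusterResult:
    """Hierarchical clustering on the full pairwise SBD matrix.

    Constant profiles cannot be z-normalized and are rejected; filter them out
    beforehand.  Deterministic for a fixed input (scipy's agglomerative
    implementation; exact-tie merge order follows its internal ordering).
    """
    if isinstance(profiles, pd.DataFrame):
        ids = tuple(str(i) for i in profiles.index)
        data = profiles.to_numpy(float)
    else:
        ids = tuple(profiles)
        data = np.array([np.asarray(profiles[i], float) for i in ids])
    if len(ids) < 2:
        raise ValueError("need at least 2 profiles")
    if normalize:
        data = np.array([znorm(row) for row in data])
    z = hierarchy.linkage(sbd_matrix(data), method=linkage)
    return ClusterResult(ids, z)


def native_reference_cut(
    result: ClusterResult,
    native_ids: Sequence[str],
    labeled_ids: Sequence[str],
) -> tuple[float, dict[str, int]]:
    """Largest cut height at which no cluster mixes a native reference with a
    labeled profile, with the labels at that height.

    The dendrogram only changes at merge heights: the cut is placed at the
    highest merge height strictly below the first merge that joins a native
    reference with a labeled profile (0 if that is the first merge; the root
    height if they never mix).
    """
    natives = set(native_ids)
    labeled = set(labeled_ids)
    missing = natives - set(result.ids)
    if missing:
        raise ValueError(f"native reference ids absent from clustering: {sorted(missing)}")
    n = len(result.ids)
    members: dict[int, set[str]] = {i: {fid} for i, fid in enumerate(result.ids)}
    mix_height = None
    for row_idx, (a, b, height, _) in enumerate(result.linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        if merged & natives and merged & labeled and mix_height is None:
            mix_height = height
            bad_row = row_idx
            break
    if mix_height is None:
        cut = float(result.heights.max())
    else:
        below = result.heights[:bad_row]
        below = below[below < mix_height]
        cut = float(below.max()) if below.size else 0.0
    return cut, result.labels(height=cut)


@dataclass(frozen=True)
class RatioProfile:
    """Heavy/light intensity ratio per time point for one multiplet member."""

    heavy_id: str
    light_id: str
    k: int
    times: tuple[float, ...]
    ratios: tuple[float, ...]  # NaN where the light feature is below floor

    @property
    def isotopologue_class(self) -> str:
        return f"13C{3 * self.k}"


def ratio_profiles(
    multiplets: Sequence[Multiplet],
    features: pd.DataFrame,
    design: SampleDesign,
    floor: float | None = None,
    max_time_h: float | None = None,
) -> list[RatioProfile]:
    """Per-time-point mean-heavy / mean-light ratios for every heavy feature.

    ``floor`` guards against division blow-ups when the light isotopologue is
    near the detection limit; by default it is half the smallest nonzero
    intensity in the table.  ``max_time_h`` truncates the series (label
    incorporation is typically followed over the feeding window only).
    """
    means = mean_by_timepoint(features, design)
    times = np.array(means.columns, float)
    if max_time_h is not None:
        keep = times <= max_time_h
        means = means.loc[:, means.columns[keep]]
        times = times[keep]
    if floor is None:
        sample_cols = [c for c in features.columns if c not in ("id", "mz", "rt")]
        values = features[sample_cols].to_numpy(float)
        nonzero = values[values > 0]
        floor = 0.5 * nonzero.min() if nonzero.size else 0.0
    out = []
    for m in multiplets:
        light = means.loc[m.light_id].to_numpy(float)
        for k, heavy_id, _ in m.members:
            heavy = means.loc[heavy_id].to_numpy(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(light >= floor, heavy / np.maximum(light, 1e-300), np.nan)
            out.append(
                RatioProfile(heavy_id, m.light_id, k, tuple(times), tuple(ratio))
            )
    return out


def peak_time(times: Sequence[float], values: Sequence[float]) -> float:
    """Time of the maximum value; ties resolve to the earliest time point."""
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    if np.all(np.isnan(values)):
        raise ValueError("all values missing")
    return float(times[np.nanargmax(values)])
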