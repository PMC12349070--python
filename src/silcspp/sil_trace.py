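"""Detection of isotopologue multiplets within co-elution groups.

A metabolite that incorporated k labeled three-carbon moieties appears as a
"heavy" LC-MS feature k x 3 x 1.003355 Da above its "light" (native)
counterpart at the same retention time.  A light feature plus one heavy
partner is a doublet (one moiety), plus two heavies a triplet (two moieties).
No intensity-ratio constraint is applied by default: unlike natural-abundance
isotope peaks, label enrichment varies over the time course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .chem import SIL_CARBON

__all__ = ["Multiplet", "find_multiplets", "multiplet_census", "write_multiplets", "read_multiplets"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Multiplet:
    """A light feature and its heavy isotopologue partners.

    ``members`` holds (k, heavy feature id, observed spacing error in Da)
    with distinct k >= 1; size = 1 + number of heavies.
    """

    light_id: str
    group_id: int
    members: tuple[tuple[int, str, float], ...]

    @property
    def size(self) -> int:
        return 1 + len(self.members)

    @property
    def feature_ids(self) -> frozenset[str]:
        return frozenset({self.light_id} | {fid for _, fid, _ in self.members})

    def k_of(self, feature_id: str) -> int:
        if feature_id == self.light_id:
            return 0
        for k, fid, _ in self.members:
            if fid == feature_id:
                return k
        raise KeyError(feature_id)


def find_multiplets(
    features: pd.DataFrame,
    groups: pd.Series,
    mz_tol: float = 0.005,
    max_k: int = 5,
    carbons_per_step: int = 3,
) -> list[Multiplet]:
    """Collect isotopologue multiplets within each co-elution group.

    Within a group, candidate light features are scanned in ascending m/z; the
    lowest-m/z member of a spacing chain anchors the multiplet, and a feature
    already claimed as a heavy cannot anchor its own.  For each k in
    ``1..max_k`` the unclaimed feature nearest to
    ``light m/z + k x carbons_per_step x 1.003355`` within ``mz_tol`` is taken
    (ties broken by smaller error, then id); discarded equally-matching
    candidates are logged.  ``carbons_per_step=1`` traces natural-abundance
    +1.003355 Da isotopes instead of labeled three-carbon moieties.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    if not 1 <= max_k <= 5:
        raise ValueError("max_k must be in 1..5")
    step = carbons_per_step * SIL_CARBON
    by_id = features.set_index("id")
    multiplets: list[Multiplet] = []
    for group_id, ids in groups.groupby(groups).groups.items():
        member_ids = sorted(ids, key=lambda fid: (by_id.at[fid, "mz"], fid))
        claimed: set[str] = set()
        for anchor in member_ids:
            if anchor in claimed:
                continue
            anchor_mz = by_id.at[anchor, "mz"]
            found: list[tuple[int, str, float]] = []
            for k in range(1, max_k + 1):
                target = anchor_mz + k * step
                candidates = [
                    (abs(by_id.at[fid, "mz"] - target), fid)
                    for fid in member_ids
                    if fid != anchor and fid not in claimed
                    and abs(by_id.at[fid, "mz"] - target) <= mz_tol
                ]
                if not candidates:
                    continue
                candidates.sort()
                err, best = candidates[0]
                for other_err, other in candidates[1:]:
                    log.debug(
                        "multiplet tie in group %s: %s kept over %s at k=%d "
                        "(|err| %.5f vs %.5f)", group_id, best, other, k, err, other_err,
                    )
                signed_err = by_id.at[best, "mz"] - target
                found.append((k, best, signed_err))
                claimed.add(best)
            if found:
                claimed.add(anchor)
                multiplets.append(Multiplet(anchor, int(group_id), tuple(found)))
    return multiplets


def multiplet_census(multiplets: list[Multiplet]) -> dict[int, int]:
    """Counts by multiplet size (2 = doublet, 3 = triplet, ...)."""
    census: dict[int, int] = {}
    for m in multiplets:
        census[m.size] = census.get(m.size, 0) + 1
    return dict(sorted(census.items()))


def write_multiplets(multiplets: list[Multiplet], path: str | Path) -> None:
    rows = [
        {"light_id": m.light_id, "k": k, "heavy_id": fid,
         "delta_error": f"{err:.6f}", "group_id": m.group_id}
        for m in multiplets
        for k, fid, err in m.members
    ]
    pd.DataFrame(rows, columns=["light_id", "k", "heavy_id", "delta_error", "group_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_multiplets(path: str | Path) -> list[Multiplet]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (light, group), sub in df.groupby(["light_id", "group_id"], sort=False):
        members = tuple(
            (int(r.k), str(r.heavy_id), float(r.delta_error)) for r in sub.itertuples()
        )
        out.append(Multiplet(str(light), int(group), members))
    return out
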