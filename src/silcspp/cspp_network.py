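"""Candidate substrate-product pair (CSPP) network construction.

Two features form a CSPP when their m/z difference matches a biotransformation
mass delta within tolerance AND their elution order matches the direction the
rule prescribes (reversed-phase convention).  Following the mass-difference
sign convention, the observed difference is computed as
``m/z(later-eluting) - m/z(earlier-eluting)``: a rule whose product elutes
later (order 2) matches d = +delta with the earlier feature as substrate; a
rule whose product elutes earlier (order 1) matches d = -delta with the later
feature as substrate.

The network is restricted to features validated by stable-isotope labeling
(members of isotopologue multiplets); pairs inside one multiplet (pure label
shifts) are excluded.  Edges carry the Pearson correlation of the two
features' intensities across all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chem import ADDUCTS, ATOMIC_MASS, Conversion, Ruleset
from .sil_trace import Multiplet

__all__ = [
    "FeatureIon",
    "RuleMatch",
    "match_pair",
    "edge_correlation",
    "build_network",
    "annotate_adduct_artifacts",
    "export_network",
    "read_sif",
    "component_census",
]

log = logging.getLogger(__name__)


class FeatureIon(NamedTuple):
    id: str
    mz: float
    rt: float


@dataclass(frozen=True)
class RuleMatch:
    conversion: Conversion
    substrate_id: str
    product_id: str
    error: float


def match_pair(
    feat_a: FeatureIon,
    feat_b: FeatureIon,
    ruleset: Sequence[Conversion],
    mass_tol: float = 0.002,
) -> list[RuleMatch]:
    """All ruleset conversions matching one feature pair, with direction.

    Pairs with identical retention time are skipped (direction undefined).
    """
    if feat_a.rt == feat_b.rt:
        log.debug("RT tie between %s and %s: pair skipped", feat_a.id, feat_b.id)
        return []
    earlier, later = (feat_a, feat_b) if feat_a.rt < feat_b.rt else (feat_b, feat_a)
    d = later.mz - earlier.mz
    matches = []
    for rule in ruleset:
        if rule.elution_order == 2:
            err = d - rule.delta_mass
            if abs(err) <= mass_tol:
                matches.append(RuleMatch(rule, earlier.id, later.id, err))
        else:
            err = d + rule.delta_mass
            if abs(err) <= mass_tol:
                matches.append(RuleMatch(rule, later.id, earlier.id, err))
    return matches


def edge_correlation(x: Iterable[float], y: Iterable[float]) -> float:
    """Pearson product-moment r; NaN when either vector is constant."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


_ROLE_BY_K = {0: "native", 1: "13C3", 2: "13C6"}


def build_network(
    features: pd.DataFrame,
    ruleset: Ruleset,
    multiplets: Sequence[Multiplet] | None = None,
    mass_tol: float = 0.002,
    sample_columns: Sequence[str] | None = None,
) -> nx.MultiDiGraph:
    """Concatenate all pairwise CSPP matches into a directed network.

    When ``multiplets`` is given, matching is restricted to multiplet member
    features and pairs within one multiplet are excluded; node attributes
    record the isotopologue role (native / 13C3 / 13C6 from the member's k)
    and multiplet id.  Edge attributes: conversion short label, mass error,
    Pearson r across the intensity columns.
    """
    membership: dict[str, tuple[str, int]] = {}
    if multiplets is not None:
        for m in multiplets:
            membership[m.light_id] = (m.light_id, 0)
            for k, fid, _ in m.members:
                membership[fid] = (m.light_id, k)
        features = features[features["id"].isin(membership)].reset_index(drop=True)

    if sample_columns is None:
        sample_columns = [c for c in features.columns if c not in ("id", "mz", "rt")]
    ions = [FeatureIon(str(r.id), float(r.mz), float(r.rt)) for r in features.itertuples()]
    intensities = {
        str(r.id): features.loc[features["id"] == r.id, list(sample_columns)].to_numpy(float)[0]
        for r in features.itertuples()
    } if sample_columns else {}

    graph = nx.MultiDiGraph(mass_tol=mass_tol)
    for ion in ions:
        mult_id, k = membership.get(ion.id, (None, None))
        graph.add_node(
            ion.id,
            mz=ion.mz,
            rt=ion.rt,
            role=_ROLE_BY_K.get(k, f"13C{3*k}" if k else "unknown"),
            multiplet=mult_id if mult_id is not None else "",
        )
    for i in range(len(ions)):
        for j in range(i + 1, len(ions)):
            a, b = ions[i], ions[j]
            if multiplets is not None and membership[a.id][0] == membership[b.id][0]:
                continue  # pure label shift inside one multiplet
            for hit in match_pair(a, b, ruleset, mass_tol):
                r = float("nan")
                if sample_columns:
                    r = edge_correlation(intensities[hit.substrate_id], intensities[hit.product_id])
                graph.add_edge(
                    hit.substrate_id,
                    hit.product_id,
                    key=hit.conversion.short,
                    short=hit.conversion.short,
                    error=hit.error,
                    r=r,
                )
    return graph


def component_census(graph: nx.MultiDiGraph) -> dict[int, int]:
    """Counts of weakly connected components by node count (isolated nodes
    excluded)."""
    census: dict[int, int] = {}
    for comp in nx.weakly_connected_components(graph):
        if len(comp) < 2:
            continue
        census[len(comp)] = census.get(len(comp), 0) + 1
    return dict(sorted(census.items()))


def annotate_adduct_artifacts(
    graph: nx.MultiDiGraph,
    features: pd.DataFrame,
    groups: pd.Series,
    mz_tol: float = 0.005,
) -> list[tuple[str, str, str]]:
    """Flag co-eluting dimer/acetate adduct pairs and their incident edges.

    Within each co-elution group, every pair of features is tested against
    every pair of known negative-mode adduct forms: if interpreting feature a
    as one form yields a neutral mass whose other form predicts feature b
    within tolerance, the pair is recorded as an adduct relation.  Putative
    non-monomer ([2M-H] homodimer) ions are marked ``adduct_suspect`` and
    every CSPP edge touching them is flagged (kept, not removed).  Returns
    the recorded (feature, adduct_ion, kind) relations.
    """
    by_id = features.set_index("id")
    flagged: list[tuple[str, str, str]] = []
    for _, ids in groups.groupby(groups).groups.items():
        ids = list(ids)
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                mz_a, mz_b = by_id.at[a, "mz"], by_id.at[b, "mz"]
                for form_a in ADDUCTS.values():
                    neutral = (mz_a - form_a.offset) / form_a.multimer
                    if neutral <= 0:
                        continue
                    for form_b in ADDUCTS.values():
                        if form_b.name == form_a.name:
                            continue
                        predicted = form_b.multimer * neutral + form_b.offset
                        if abs(mz_b - predicted) > mz_tol:
                            continue
                        if form_b.multimer == 2:
                            kind = "dimer"
                        elif form_b.name == "[M+Ac-H]-":
                            kind = "acetate"
                        else:
                            continue  # the molecular ion is not an artifact
                        flagged.append((a, b, kind))
    flagged = sorted(set(flagged))
    suspects = {b for _, b, kind in flagged if kind == "dimer"}
    for node in graph.nodes:
        if node in suspects:
            graph.nodes[node]["adduct_suspect"] = True
    for u, v, key in graph.edges(keys=True):
        if u in suspects or v in suspects:
            graph.edges[u, v, key]["adduct_suspect"] = True
    return flagged


def export_network(
    graph: nx.MultiDiGraph,
    outdir: str | Path,
    basename: str = "network",
    formats: Sequence[str] = ("sif", "tsv", "graphml"),
) -> list[Path]:
    """Write the network for external visualization (e.g. Cytoscape).

    ``sif``: one ``substrate<TAB>short<TAB>product`` line per edge;
    ``tsv``: node and edge attribute tables; ``graphml``: full graph.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "sif" in formats:
        path = outdir / f"{basename}.sif"
        lines = [f"{u}\t{data['short']}\t{v}" for u, v, data in graph.edges(data=True)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        written.append(path)
    if "tsv" in formats:
        node_path = outdir / f"{basename}.nodes.tsv"
        rows = [{"id": n, **{k: v for k, v in d.items()}} for n, d in graph.nodes(data=True)]
        pd.DataFrame(rows).to_csv(node_path, sep="\t", index=False)
        edge_path = outdir / f"{basename}.edges.tsv"
        erows = [
            {"substrate": u, "product": v, **{k: val for k, val in d.items()}}
            for u, v, d in graph.edges(data=True)
        ]
        cols = ["substrate", "product", "short", "error", "r"]
        pd.DataFrame(erows, columns=cols + sorted(
            {c for row in erows for c in row} - set(cols) - {"substrate", "product"}
        ) if erows else cols).to_csv(edge_path, sep="\t", index=False)
        written += [node_path, edge_path]
    if "graphml" in formats:
        path = outdir / f"{basename}.graphml"
        clean = nx.MultiDiGraph()
        clean.add_nodes_from(
            (n, {k: v for k, v in d.items() if v is not None}) for n, d in graph.nodes(data=True)
        )
        for u, v, key, d in graph.edges(keys=True, data=True):
            clean.add_edge(u, v, key=key, **{
                k: val for k, val in d.items()
                if val is not None and not (isinstance(val, float) and np.isnan(val))
            })
        nx.write_graphml(clean, path)
        written.append(path)
    return written


def read_sif(path: str | Path) -> nx.MultiDiGraph:
    graph = nx.MultiDiGraph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        u, short, v = line.split("\t")
        graph.add_edge(u, v, key=short, short=short)
    return graph
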