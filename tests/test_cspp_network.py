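"""CSPP pair matching, network construction, and export."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from silcspp.cspp_network import (
    FeatureIon,
    annotate_adduct_artifacts,
    build_network,
    component_census,
    edge_correlation,
    export_network,
    match_pair,
    read_sif,
)
from silcspp.features import group_by_coelution
from silcspp.sil_trace import Multiplet, find_multiplets

COUMARIC = FeatureIon("coumaric", 163.0398, 9.6)
COUMAROYL_GLC = FeatureIon("coumaroyl_glc", 325.0924, 8.8)
COUMAROYL_TAR = FeatureIon("coumaroyl_tar", 295.0453, 3.1)


class TestMatchPair:
    def test_hexosylation_product_elutes_earlier(self, ruleset):
        hits = match_pair(COUMARIC, COUMAROYL_GLC, ruleset)
        assert [h.conversion.short for h in hits] == ["Hex"]
        assert hits[0].substrate_id == "coumaric"
        assert hits[0].product_id == "coumaroyl_glc"
        assert abs(hits[0].error) <= 0.0003

    def test_tartarate_conjugation(self, ruleset):
        hits = match_pair(COUMARIC, COUMAROYL_TAR, ruleset)
        assert {h.conversion.short for h in hits} == {"Tar"}
        assert hits[0].substrate_id == "coumaric"

    def test_argument_order_is_irrelevant(self, ruleset):
        assert match_pair(COUMARIC, COUMAROYL_GLC, ruleset) == match_pair(
            COUMAROYL_GLC, COUMARIC, ruleset
        )

    def test_no_rule_within_tolerance(self, ruleset):
        assert match_pair(COUMARIC, FeatureIon("x", 170.0, 5.0), ruleset) == []

    def test_rt_tie_skipped(self, ruleset):
        tied = FeatureIon("tied", COUMARIC.mz + 162.0528, 9.6)
        assert match_pair(COUMARIC, tied, ruleset) == []

    def test_wrong_elution_order_rejected(self, ruleset):
        # hexosylated product eluting later than its substrate is not a Hex CSPP
        late = FeatureIon("late", COUMARIC.mz + 162.0528, 10.5)
        assert "Hex" not in {h.conversion.short for h in match_pair(COUMARIC, late, ruleset)}


class TestEdgeCorrelation:
    def test_perfect_and_inverse(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert edge_correlation(x, x) == pytest.approx(1.0)
        assert edge_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_example_matches_scipy(self):
        x, y = (1, 2, 3, 4), (2, 4, 5, 9)
        r = edge_correlation(x, y)
        assert r == pytest.approx(11 / np.sqrt(130), abs=1e-12)  # closed form
        assert r == pytest.approx(scipy.stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_constant_vector_gives_nan(self):
        assert np.isnan(edge_correlation([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            edge_correlation([1, 2], [1, 2, 3])


def feature_frame(ions, samples=()):
    rng = np.random.default_rng(0)
    rows = []
    for ion in ions:
        rows.append(
            {"id": ion.id, "mz": ion.mz, "rt": ion.rt,
             **{s: rng.uniform(10, 100) for s in samples}}
        )
    return pd.DataFrame(rows)


class TestBuildNetwork:
    def test_empty(self, ruleset):
        graph = build_network(feature_frame([]), ruleset)
        assert graph.number_of_nodes() == 0

    def test_matches_bruteforce_all_pairs_oracle(self, ruleset):
        rng = np.random.default_rng(13)
        ions = [
            FeatureIon(f"f{i}", float(m), float(r))
            for i, (m, r) in enumerate(
                zip(rng.uniform(150, 700, 60), rng.uniform(1, 14, 60))
            )
        ]
        # plant exact rule deltas so the network is non-trivial
        for i, short in enumerate(["Hex", "Cou", "Oxy", "Tar", "Caf"]):
            rule = ruleset.lookup(short)
            sign = 1 if rule.elution_order == 2 else -1
            base = ions[i]
            ions.append(
                FeatureIon(
                    f"p{i}", base.mz + rule.delta_mass, base.rt + sign * 1.0
                )
            )
        graph = build_network(feature_frame(ions), ruleset)
        got = {(u, v, d["short"]) for u, v, d in graph.edges(data=True)}
        expected = set()
        for i in range(len(ions)):
            for j in range(i + 1, len(ions)):
                for hit in match_pair(ions[i], ions[j], ruleset, 0.002):
                    expected.add((hit.substrate_id, hit.product_id, hit.conversion.short))
        assert got == expected
        assert len(got) >= 5

    def test_planted_pathways_and_components(self, ruleset):
        hex_rule = ruleset.lookup("Hex").delta_mass
        cou = ruleset.lookup("Cou").delta_mass
        ions = [
            # pathway 1: a -Hex-> b -Hex-> c (products elute earlier)
            FeatureIon("a", 300.0, 9.0),
            FeatureIon("b", 300.0 + hex_rule, 8.0),
            FeatureIon("c", 300.0 + 2 * hex_rule, 7.0),
            # pathway 2: d -Cou-> e (product elutes later)
            FeatureIon("d", 600.0, 3.0),
            FeatureIon("e", 600.0 + cou, 5.0),
        ]
        multiplets = [
            Multiplet(ion.id, i, ((1, f"{ion.id}_h", 0.0),)) for i, ion in enumerate(ions)
        ]
        frame = feature_frame(ions)
        graph = build_network(frame, ruleset, multiplets=multiplets)
        got = {(u, v, d["short"]) for u, v, d in graph.edges(data=True)}
        assert {("a", "b", "Hex"), ("b", "c", "Hex"), ("d", "e", "Cou")} <= got
        assert component_census(graph) == {2: 1, 3: 1}

    def test_sil_restriction_and_roles(self, clean_flax, ruleset):
        features, _, truth = clean_flax
        groups = group_by_coelution(features, 0.1)
        multiplets = find_multiplets(features, groups)
        graph = build_network(features, ruleset, multiplets=multiplets)
        member_ids = {fid for m in multiplets for fid in m.feature_ids}
        assert set(graph.nodes) <= member_ids
        roles = {graph.nodes[n]["role"] for n in graph.nodes}
        assert roles >= {"native", "13C3", "13C6"}
        got = {(u, v, d["short"]) for u, v, d in graph.edges(data=True)}
        assert got == set(truth.edges)

    def test_edge_count_monotone_in_mass_tol(self, clean_flax, ruleset):
        features, _, _ = clean_flax
        groups = group_by_coelution(features, 0.1)
        multiplets = find_multiplets(features, groups)
        counts = [
            build_network(features, ruleset, multiplets=multiplets, mass_tol=t).number_of_edges()
            for t in (0.0005, 0.001, 0.002, 0.004)
        ]
        assert counts == sorted(counts)


class TestAdductArtifacts:
    def test_dimer_flagged(self, ruleset):
        ions = [FeatureIon("mono", 325.0924, 6.9), FeatureIon("dimer", 651.1920, 6.9)]
        frame = feature_frame(ions)
        graph = build_network(frame, ruleset)
        graph.add_node("mono")
        graph.add_node("dimer")
        groups = group_by_coelution(frame, 0.1)
        flagged = annotate_adduct_artifacts(graph, frame, groups)
        assert ("mono", "dimer", "dimer") in flagged
        assert graph.nodes["dimer"].get("adduct_suspect") is True

    def test_no_pattern_no_flags(self, ruleset):
        ions = [FeatureIon("x", 325.0924, 6.9), FeatureIon("y", 400.1, 6.9)]
        frame = feature_frame(ions)
        graph = build_network(frame, ruleset)
        flagged = annotate_adduct_artifacts(graph, frame, group_by_coelution(frame, 0.1))
        assert flagged == []

    def test_fortuitous_dimer_edge_flagged_not_removed(self, clean_flax, ruleset):
        # a glucoside homodimer fortuitously matches a tartarate conjugation
        features, _, _ = clean_flax
        groups = group_by_coelution(features, 0.1)
        multiplets = find_multiplets(features, groups)
        graph = build_network(features, ruleset, multiplets=multiplets)
        annotate_adduct_artifacts(graph, features, groups)
        flagged_edges = [
            (u, v, d["short"])
            for u, v, d in graph.edges(data=True)
            if d.get("adduct_suspect")
        ]
        assert any(
            "2M-H" in u or "2M-H" in v for u, v, _ in flagged_edges
        ), "the dimer-mediated edge should be flagged but kept"


class TestExport:
    def test_sif_roundtrip(self, tmp_path, ruleset):
        ions = [COUMARIC, COUMAROYL_GLC, COUMAROYL_TAR]
        graph = build_network(feature_frame(ions, samples=("s1", "s2", "s3")), ruleset)
        files = export_network(graph, tmp_path, "net")
        sif = [f for f in files if f.suffix == ".sif"][0]
        lines = sif.read_text().strip().splitlines()
        assert len(lines) == graph.number_of_edges() == 2
        reloaded = read_sif(sif)
        assert set(reloaded.edges(keys=True)) == set(graph.edges(keys=True))

    def test_graphml_preserves_nodes_and_edges(self, tmp_path, ruleset):
        import networkx as nx

        ions = [COUMARIC, COUMAROYL_GLC]
        graph = build_network(feature_frame(ions, samples=("s1", "s2", "s3")), ruleset)
        files = export_network(graph, tmp_path, "net", formats=("graphml",))
        loaded = nx.read_graphml(files[0])
        assert set(loaded.nodes) == set(graph.nodes)
        assert loaded.number_of_edges() == graph.number_of_edges()
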