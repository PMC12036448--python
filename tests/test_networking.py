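"""Modified cosine, clustering, network pruning, edge re-addition, annotation."""

import networkx as nx
import numpy as np
import pytest

from gluconet import (
    NETWORK_PRESETS,
    NetworkParams,
    Spectrum,
    SpectrumCollection,
    SynthConfig,
    build_network,
    cluster_spectra,
    export_network,
    library_search,
    make_conjugate_network_dataset,
    modified_cosine,
    propagate_suspect_annotations,
    readd_delta_edges,
)
from gluconet.networking import Edge

from conftest import random_spectrum


def spec(scan_id, prec, mz, inten, **kw):
    return Spectrum(scan_id, prec, "negative", np.asarray(mz, float), np.asarray(inten, float), **kw)


class TestModifiedCosine:
    def test_identical_spectra_score_one(self, rng):
        s = random_spectrum(rng)
        cos, nm = modified_cosine(s, s.copy(scan_id="b"), 0.01)
        assert cos == pytest.approx(1.0, abs=1e-12)
        assert nm == s.n_peaks

    def test_disjoint_spectra_score_zero(self):
        a = spec("a", 500.0, [100.0, 150.0], [1.0, 1.0])
        b = spec("b", 500.0, [120.0, 170.0], [1.0, 1.0])
        assert modified_cosine(a, b, 0.01) == (0.0, 0)

    def test_aglycone_glucuronide_hand_case(self):
        # one direct pair (100) and one precursor-shifted pair (150 vs 326.0321)
        a = spec("agly", 300.0, [100.0, 150.0], [1.0, 0.5])
        b = spec("glu", 476.0321, [100.0, 326.0321], [1.0, 0.5])
        cos, nm = modified_cosine(a, b, 0.01)
        assert cos == pytest.approx(1.0, abs=1e-9)
        assert nm == 2

    def test_symmetry_and_scale_invariance(self, rng):
        for _ in range(50):
            a, b = random_spectrum(rng, "a"), random_spectrum(rng, "b")
            cab = modified_cosine(a, b, 0.01)
            cba = modified_cosine(b, a, 0.01)
            assert cab[0] == pytest.approx(cba[0], abs=1e-9) and cab[1] == cba[1]
            scaled = a.copy(intensity=a.intensity * 31.0)
            assert modified_cosine(scaled, b, 0.01)[0] == pytest.approx(cab[0], abs=1e-9)
            assert 0.0 <= cab[0] <= 1.0

    def test_empty_peak_list_raises(self):
        a = spec("a", 500.0, [100.0], [1.0])
        with pytest.raises(ValueError):
            modified_cosine(a, spec("b", 500.0, [100.0], [0.0]), 0.01)

    def test_greedy_equals_exhaustive_optimal_matching(self, rng):
        """On small spectra the greedy pairing attains the optimal assignment."""
        from scipy.optimize import linear_sum_assignment

        from gluconet.networking import _candidate_pairs, _sqrt_l2_weights

        n_pairs = 0
        while n_pairs < 500:
            a = random_spectrum(rng, "a", n_peaks=int(rng.integers(2, 7)))
            b = random_spectrum(rng, "b", n_peaks=int(rng.integers(2, 7)))
            if rng.uniform() < 0.5:  # plant overlap so scores are non-trivial
                take = min(2, a.n_peaks, b.n_peaks)
                b = spec("b", b.precursor_mz,
                         np.concatenate([b.mz[:-take], a.mz[:take] + rng.uniform(-0.005, 0.005, take)]),
                         np.concatenate([b.intensity[:-take], a.intensity[:take]]))
                if b.n_peaks > 6:
                    continue
            cos, _ = modified_cosine(a, b, 0.01)
            wa, wb = _sqrt_l2_weights(a), _sqrt_l2_weights(b)
            weights = np.zeros((a.n_peaks, b.n_peaks))
            for (i, j), _err in _candidate_pairs(a, b, 0.01).items():
                weights[i, j] = wa[i] * wb[j]
            rows, cols = linear_sum_assignment(-weights)
            optimal = weights[rows, cols].sum()
            assert cos == pytest.approx(min(optimal, 1.0), abs=1e-9)
            n_pairs += 1

    def test_agrees_with_matchms_reference(self, rng):
        """Independent oracle: matchms ModifiedCosine fed sqrt intensities."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        def as_matchms(s):
            return matchms.Spectrum(mz=s.mz, intensities=np.sqrt(s.intensity),
                                    metadata={"precursor_mz": s.precursor_mz},
                                    metadata_harmonization=False)

        sim = ModifiedCosine(tolerance=0.01)
        for k in range(100):
            a, b = random_spectrum(rng, "a"), random_spectrum(rng, "b")
            if k % 2:  # plant direct + shifted overlap
                extra = a.mz[:2] + (b.precursor_mz - a.precursor_mz)
                extra = extra[extra > 1.0]
                b = spec("b", b.precursor_mz,
                         np.concatenate([b.mz, a.mz[2:5], extra]),
                         np.concatenate([b.intensity, a.intensity[2:5], a.intensity[: len(extra)]]))
            cos, nm = modified_cosine(a, b, 0.01)
            ref = sim.pair(as_matchms(a), as_matchms(b))
            assert cos == pytest.approx(float(ref["score"]), abs=1e-9)
            assert nm == int(ref["matches"])


class TestClustering:
    def _replicates(self, n_files):
        base = spec("base", 400.0, [100.0, 150.0, 200.0], [50.0, 100.0, 25.0])
        return [
            base.copy(scan_id=f"scan{i}", source_file=f"file{i}.mzML")
            for i in range(n_files)
        ]

    def test_replicates_collapse_to_one_consensus(self):
        coll = SpectrumCollection(self._replicates(3))
        out = cluster_spectra(coll, min_files=2)
        assert len(out) == 1
        assert out[0].metadata["n_files"] == 3
        assert sorted(out[0].metadata["member_scan_ids"]) == ["scan0", "scan1", "scan2"]

    def test_single_file_cluster_dropped_at_min_files_2(self):
        spectra = self._replicates(2) + [
            spec("lonely", 600.0, [300.0, 310.0], [100.0, 50.0], source_file="file0.mzML")
        ]
        out = cluster_spectra(SpectrumCollection(spectra), min_files=2)
        assert len(out) == 1  # the lonely spectrum's cluster is dropped

    def test_min_files_1_keeps_every_cluster(self):
        spectra = self._replicates(2) + [
            spec("lonely", 600.0, [300.0, 310.0], [100.0, 50.0], source_file="file0.mzML")
        ]
        out = cluster_spectra(SpectrumCollection(spectra), min_files=1)
        assert len(out) == 2


class TestBuildNetwork:
    def test_identical_triplet_fully_connected(self):
        s = spec("a", 400.0, [100.0, 150.0, 200.0], [50.0, 100.0, 25.0])
        coll = SpectrumCollection([s, s.copy(scan_id="b"), s.copy(scan_id="c")])
        net = build_network(coll, NETWORK_PRESETS["biological"])
        assert net.graph.number_of_edges() == 3
        assert all(d["cosine"] == pytest.approx(1.0) for _, _, d in net.graph.edges(data=True))

    def test_component_cap_enforced_on_chain(self, rng):
        # chain of similar nodes: each neighbor shares most peaks
        base_mz = np.sort(rng.uniform(60, 350, 8))
        spectra = []
        for i in range(5):
            inten = rng.uniform(20, 100, 8)
            spectra.append(spec(f"n{i}", 400.0 + i * 0.5, base_mz, inten))
        params = NetworkParams(frag_tol=0.01, cosine_min=0.4, min_matched=3,
                               top_k=10, max_component=2, min_files=1)
        net = build_network(SpectrumCollection(spectra), params)
        assert max(len(c) for c in nx.connected_components(net.graph)) <= 2

    def test_scored_edges_meet_thresholds_and_topk(self):
        cfg = SynthConfig(seed=13)
        coll, _, _ = make_conjugate_network_dataset(cfg)
        params = NETWORK_PRESETS["biological"]
        net = build_network(coll, params)
        degrees = {}
        for e in net.edges(origin="scored"):
            assert e.cosine >= params.cosine_min
            assert e.n_matched >= params.min_matched
            degrees[e.node_a] = degrees.get(e.node_a, 0) + 1
            degrees[e.node_b] = degrees.get(e.node_b, 0) + 1
        assert max(degrees.values()) <= params.top_k
        assert max(len(c) for c in nx.connected_components(net.graph)) <= params.max_component

    def test_standards_preset_recovers_conjugate_edges(self):
        cfg = SynthConfig(seed=21, n_families=2, family_size=5)
        coll, pairs, _ = make_conjugate_network_dataset(cfg)
        net = build_network(coll, NETWORK_PRESETS["standards"])
        net = readd_delta_edges(net)
        edges = {frozenset((a, b)) for a, b in net.graph.edges}
        for _, row in pairs.iterrows():
            assert frozenset((row["glucuronide_scan_id"], row["aglycone_scan_id"])) in edges


class TestReaddDeltaEdges:
    def _tiny_network(self):
        a = spec("naringenin", 271.0612, [119.0, 151.0, 177.0], [100.0, 80.0, 40.0])
        b = spec("naringenin_glucuronide", 447.0933, [119.0, 151.0, 295.0], [90.0, 70.0, 30.0])
        g = nx.Graph()
        for s in (a, b):
            g.add_node(s.scan_id, spectrum=s, precursor_mz=s.precursor_mz)
        from gluconet.networking import MolecularNetwork
        return MolecularNetwork(graph=g, params=NETWORK_PRESETS["biological"], scored_pairs=[])

    def test_pruned_glucuronide_pair_readded(self):
        net = self._tiny_network()
        scored = [Edge("naringenin_glucuronide", "naringenin", 0.55, 3, 447.0933 - 271.0612)]
        out = readd_delta_edges(net, scored_pairs=scored)
        assert out.graph.has_edge("naringenin", "naringenin_glucuronide")
        assert out.graph.edges["naringenin", "naringenin_glucuronide"]["origin"] == "readded"

    def test_non_target_delta_not_readded(self):
        net = self._tiny_network()
        scored = [Edge("naringenin_glucuronide", "naringenin", 0.55, 3, 150.02)]
        out = readd_delta_edges(net, scored_pairs=scored)
        assert out.graph.number_of_edges() == 0

    def test_never_removes_and_readds_exactly_missing_qualifying_pairs(self):
        cfg = SynthConfig(seed=8)
        coll, _, _ = make_conjugate_network_dataset(cfg)
        net = build_network(coll, NETWORK_PRESETS["biological"])
        out = readd_delta_edges(net)
        before = {frozenset((a, b)) for a, b in net.graph.edges}
        after = {frozenset((a, b)) for a, b in out.graph.edges}
        assert before <= after
        expected = {
            frozenset((e.node_a, e.node_b))
            for e in net.scored_pairs
            if any(abs(abs(e.delta_prec_mz) - t) <= 0.003 for t in (176.032, 194.042, 96.075))
        } - before
        readded = {frozenset((e.node_a, e.node_b)) for e in out.edges(origin="readded")}
        assert readded == expected

    def test_empty_targets_raise(self):
        net = self._tiny_network()
        with pytest.raises(ValueError):
            readd_delta_edges(net, targets=())


class TestLibrarySearch:
    def _library(self):
        ref = spec("lib0", 271.0612, [119.0, 151.0, 177.0, 227.0], [100.0, 80.0, 40.0, 20.0],
                   retention_time=300.0, metadata={"compound_name": "naringenin"})
        return SpectrumCollection([ref])

    def test_identical_node_matches_tier_library(self):
        lib = self._library()
        node = lib[0].copy(scan_id="node0")
        (m,) = library_search([node], lib)
        assert m.compound_name == "naringenin"
        assert m.annotation_tier == "library"
        assert m.cosine == pytest.approx(1.0)

    def test_rt_shift_marks_suspected_isomer(self):
        lib = self._library()
        node = lib[0].copy(scan_id="node0", retention_time=500.0)
        (m,) = library_search([node], lib, rt_tol=30.0)
        assert m.annotation_tier == "suspected_isomer"

    def test_too_few_shared_peaks_no_match(self):
        lib = self._library()
        node = spec("node0", 271.0612, [119.0, 151.0, 177.0], [100.0, 80.0, 40.0],
                    retention_time=300.0)
        assert library_search([node], lib, min_peaks=4) == []

    def test_empty_library_raises(self):
        with pytest.raises(ValueError):
            library_search([], SpectrumCollection([]))


class TestSuspectPropagation:
    def _network_with(self, edges, spectra, library_named):
        g = nx.Graph()
        for s in spectra:
            g.add_node(s.scan_id, spectrum=s, precursor_mz=s.precursor_mz)
        for a, b, cos, delta in edges:
            g.add_edge(a, b, cosine=cos, n_matched=4, delta_prec_mz=delta, origin="scored")
        from gluconet.networking import LibraryMatch, MolecularNetwork
        net = MolecularNetwork(graph=g, params=NETWORK_PRESETS["biological"])
        matches = [
            LibraryMatch(node_id=n, compound_name=name, cosine=1.0, n_shared_peaks=5,
                         delta_prec_mz=0.0, annotation_tier="library")
            for n, name in library_named.items()
        ]
        return net, matches

    def test_glucuronide_node_gets_suspect_label(self):
        agly = spec("n_agly", 271.0612, [119.0], [100.0], )
        glu = spec("n_glu", 447.0933, [119.0], [100.0])
        net, matches = self._network_with(
            [("n_glu", "n_agly", 0.8, 447.0933 - 271.0612)], [agly, glu],
            {"n_agly": "naringenin"},
        )
        calls = {"n_glu": type("C", (), {"is_match": True})(), "n_agly": type("C", (), {"is_match": False})()}
        ann = propagate_suspect_annotations(net, matches, calls)
        assert list(ann["node_id"]) == ["n_glu"]
        assert ann.iloc[0]["suspect_annotation"] == "suspect naringenin glucuronide"

    def test_conflicting_neighbors_all_listed_ranked_by_cosine(self):
        glu = spec("glu", 447.0933, [119.0], [100.0])
        a1 = spec("a1", 271.0612, [119.0], [100.0])
        a2 = spec("a2", 271.0612, [119.0], [100.0])
        net, matches = self._network_with(
            [("glu", "a1", 0.6, 176.0321), ("glu", "a2", 0.9, 176.0321)],
            [glu, a1, a2], {"a1": "apigenin", "a2": "genistein"},
        )
        calls = {"glu": type("C", (), {"is_match": True})()}
        ann = propagate_suspect_annotations(net, matches, calls)
        assert ann.iloc[0]["candidates"] == (
            "suspect genistein glucuronide;suspect apigenin glucuronide"
        )
        assert ann.iloc[0]["suspect_annotation"] == "suspect genistein glucuronide"

    def test_sulfate_delta_from_annotated_glucuronide(self):
        sulf = spec("sulf", 351.0180, [119.0], [100.0])
        glu = spec("glu", 447.0933, [119.0], [100.0])
        delta = 351.0180 - 447.0933  # ~ -96.0753
        net, matches = self._network_with(
            [("sulf", "glu", 0.7, delta)], [sulf, glu], {"glu": "naringenin glucuronide"},
        )
        ann = propagate_suspect_annotations(net, matches, calls={})
        assert ann.iloc[0]["suspect_annotation"] == "suspect naringenin sulfate"

    def test_no_qualifying_edge_no_label_and_library_not_overwritten(self):
        a = spec("a", 271.0612, [119.0], [100.0])
        b = spec("b", 300.0, [119.0], [100.0])
        net, matches = self._network_with(
            [("a", "b", 0.9, 271.0612 - 300.0)], [a, b], {"a": "naringenin"},
        )
        calls = {"b": type("C", (), {"is_match": True})()}
        ann = propagate_suspect_annotations(net, matches, calls)
        assert len(ann) == 0  # delta ~29 matches no conjugation shift
        assert "a" not in set(ann["node_id"]) if len(ann) else True


class TestExport:
    def test_graphml_and_edge_list_round_trip(self, tmp_path):
        cfg = SynthConfig(seed=5, n_families=1, family_size=4)
        coll, _, _ = make_conjugate_network_dataset(cfg)
        net = readd_delta_edges(build_network(coll, NETWORK_PRESETS["standards"]))
        out = tmp_path / "net.graphml"
        export_network(net, out)
        back = nx.read_graphml(out)
        assert back.number_of_nodes() == net.graph.number_of_nodes()
        assert back.number_of_edges() == net.graph.number_of_edges()
        origins = {d["origin"] for _, _, d in back.edges(data=True)}
        assert origins <= {"scored", "readded"}
        import pandas as pd
        edges = pd.read_csv(tmp_path / "net.edges.tsv", sep="\t")
        assert len(edges) == net.graph.number_of_edges()
        assert set(edges.columns) == {"node_a", "node_b", "cosine", "n_matched",
                                      "delta_prec_mz", "origin"}
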