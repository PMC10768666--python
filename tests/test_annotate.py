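"""Annotation cascade: adduct matching, taxonomic re-ranking, consensus
classes, identity confirmation."""

import numpy as np
import pandas as pd
import pytest

from holometab.core import Spectrum
from holometab.annotate import (MAX_DISTANCE, AnnotationCandidate,
                                AnnotationParams, LibraryEntry, TaxonomyTree,
                                annotate_dataset, consensus_class,
                                identity_match, ms1_adduct_match,
                                ms2_library_search, read_library,
                                read_msp, read_taxonomy, reweight_candidates,
                                taxonomic_distance, write_library, write_msp,
                                write_taxonomy)
from holometab.msnet import MolecularNetwork, NetworkParams
from holometab.synthio import make_library, make_taxonomy


def spec(prec, mzs, its, rt=1.0):
    return Spectrum(precursor_mz=prec, rt=rt,
                    mz=np.asarray(mzs, float), intensities=np.asarray(its, float))


def entry(sid, mass, triple=("P", "S", "C"), taxa=(), spectrum=None):
    spectrum = spectrum or spec(mass + 1.007276,
                                [50.0, 60.0, 70.0, 80.0, 90.0, 100.0],
                                [1.0, 0.8, 0.6, 0.5, 0.4, 0.3])
    return LibraryEntry(structure_id=sid, name=sid, monoisotopic_mass=mass,
                        spectrum=spectrum, class_triple=triple,
                        source_taxa=frozenset(taxa))


@pytest.fixture(scope="module")
def toy_tree():
    nodes = {"root": ("root", "root", None)}
    for side in ("plant", "fungus"):
        prev = "root"
        for rank in ("kingdom", "phylum", "class", "order", "family", "genus"):
            nid = f"{side}_{rank}"
            nodes[nid] = (nid, rank, prev)
            prev = nid
    nodes["sp_a"] = ("species a", "species", "plant_genus")
    nodes["sp_b"] = ("species b", "species", "plant_genus")
    nodes["sp_f"] = ("species f", "species", "fungus_genus")
    return TaxonomyTree(nodes=nodes)


class TestTaxonomy:
    def test_same_species_distance_zero(self, toy_tree):
        assert taxonomic_distance("sp_a", "sp_a", toy_tree) == 0

    def test_congeners_distance_one(self, toy_tree):
        assert taxonomic_distance("sp_a", "sp_b", toy_tree) == 1

    def test_cross_kingdom_distance_maximal(self, toy_tree):
        assert taxonomic_distance("sp_a", "sp_f", toy_tree) == MAX_DISTANCE == 7

    def test_unknown_taxon_rejected(self, toy_tree):
        with pytest.raises(KeyError):
            taxonomic_distance("sp_a", "nope", toy_tree)

    def test_taxonomy_tsv_round_trip(self, toy_tree, tmp_path):
        path = write_taxonomy(toy_tree, tmp_path / "tax.tsv")
        back = read_taxonomy(path)
        assert back.nodes == toy_tree.nodes

    def test_rank_order_enforced(self):
        with pytest.raises(ValueError):
            TaxonomyTree(nodes={"root": ("r", "root", None),
                                "g": ("g", "genus", "root"),
                                "f": ("f", "family", "g")})


class TestMS1AdductMatch:
    def test_sodiated_adduct_arithmetic(self, toy_tree):
        # 180.063388 + 22.989218 = 203.052606, within 0.01 Da of 203.0526
        lib = [entry("glc", 180.063388, taxa={"sp_b"})]
        out = ms1_adduct_match(203.0526, lib, ["sp_a"], toy_tree)
        assert len(out) == 1
        assert out[0][1] == "[M+Na]+"
        assert out[0][2] == pytest.approx(abs(180.063388 + 22.989218 - 203.0526),
                                          abs=1e-9)

    def test_no_adduct_within_tolerance(self, toy_tree):
        lib = [entry("glc", 180.063388, taxa={"sp_b"})]
        assert ms1_adduct_match(210.0, lib, ["sp_a"], toy_tree) == []

    def test_out_of_family_source_excluded(self, toy_tree):
        lib = [entry("glc", 180.063388, taxa={"sp_f"})]
        assert ms1_adduct_match(203.0526, lib, ["sp_a"], toy_tree) == []

    def test_unknown_sample_taxon_rejected(self, toy_tree):
        with pytest.raises(KeyError):
            ms1_adduct_match(203.0526, [], ["martian"], toy_tree)


class TestMS2Search:
    def test_exact_spectrum_ranks_first_with_unit_score(self):
        e = entry("hit", 300.0)
        probe = e.spectrum
        out = ms2_library_search("f1", probe, [e, entry("other", 300.001)])
        assert out[0].structure_id == "hit"
        assert out[0].sigma == 1.0

    def test_low_score_candidates_excluded(self):
        e = entry("far", 300.0,
                  spectrum=spec(301.007276, [55.0, 65.0, 75.0, 85.0, 95.0, 105.0],
                                [1.0] * 6))
        probe = spec(301.007276, [50.0, 60.0, 70.0, 80.0, 90.0, 100.0], [1.0] * 6)
        assert ms2_library_search("f1", probe, [e]) == []

    def test_truncation_to_candidate_limit(self):
        base = spec(301.007276, [50.0, 60.0, 70.0, 80.0, 90.0, 100.0], [1.0] * 6)
        lib = [entry(f"c{i:02d}", 300.0, spectrum=base) for i in range(60)]
        out = ms2_library_search("f1", base, lib)
        assert len(out) == 50

    def test_missing_spectrum_warns_empty(self):
        with pytest.warns(UserWarning):
            assert ms2_library_search("f1", None, [entry("x", 300.0)]) == []

    def test_parent_mass_gate(self):
        e = entry("off", 300.1)  # precursor 0.1 Da away
        probe = spec(301.007276, e.spectrum.mz, e.spectrum.intensities)
        assert ms2_library_search("f1", probe, [e]) == []


def cand(sid, sigma, taxa=(), triple=("P", "S", "C")):
    return AnnotationCandidate(feature_id="f", entry=entry(sid, 300.0, triple, taxa),
                               sigma=sigma, n_matched=6, final_score=sigma)


class TestReweighting:
    def test_formula_at_zero_distance(self, toy_tree):
        out = reweight_candidates([cand("x", 0.5, {"sp_a"})], ["sp_a"], toy_tree)
        assert out[0].final_score == pytest.approx(1.5)
        assert out[0].taxonomic_distance == 0

    def test_zero_bonus_at_max_distance(self, toy_tree):
        out = reweight_candidates([cand("x", 0.5, {"sp_f"})], ["sp_a"], toy_tree)
        assert out[0].final_score == pytest.approx(0.5)
        assert out[0].taxonomic_distance == 7

    def test_close_source_overtakes_distant_higher_sigma(self, toy_tree):
        a = cand("far", 0.6, {"sp_f"})
        b = cand("near", 0.5, {"sp_a"})
        out = reweight_candidates([a, b], ["sp_a"], toy_tree)
        assert [c.structure_id for c in out] == ["near", "far"]
        assert out[0].final_score == pytest.approx(1.5)
        assert out[1].final_score == pytest.approx(0.6)

    def test_candidate_set_preserved(self, toy_tree):
        cands = [cand(f"c{i}", 0.1 * i, {"sp_b"}) for i in range(1, 8)]
        out = reweight_candidates(cands, ["sp_a"], toy_tree)
        assert {c.structure_id for c in out} == {c.structure_id for c in cands}

    def test_monotonicity_in_sigma_and_distance(self, toy_tree):
        taxa_by_d = {0: "sp_a", 1: "sp_b", 7: "sp_f"}
        rng = np.random.default_rng(20)
        for _ in range(100):
            sigma = float(rng.uniform(0, 1))
            d_lo, d_hi = sorted(rng.choice([0, 1, 7], size=2, replace=False))
            lo = reweight_candidates([cand("x", sigma, {taxa_by_d[d_lo]})],
                                     ["sp_a"], toy_tree)[0]
            hi = reweight_candidates([cand("x", sigma, {taxa_by_d[d_hi]})],
                                     ["sp_a"], toy_tree)[0]
            assert lo.final_score >= hi.final_score  # closer never worse
            s2 = reweight_candidates([cand("x", sigma + 0.1, {taxa_by_d[d_lo]})],
                                     ["sp_a"], toy_tree)[0]
            assert s2.final_score > lo.final_score  # strictly increasing in sigma


def toy_network(nodes, edges):
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    fams = {}
    for i, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for n in comp:
            fams[n] = i
    return MolecularNetwork(graph=g, families=fams,
                            edges=pd.DataFrame(columns=["u", "v", "score", "n_matched"]),
                            params=NetworkParams())


class TestConsensusClass:
    def test_isolated_unanimous_node(self):
        net = toy_network(["n1"], [])
        cands = {"n1": [cand("a", 0.9), cand("b", 0.8)]}
        cons, top = consensus_class(net, cands)["n1"]
        assert cons == ("P", "S", "C")
        assert [c.structure_id for c in top] == ["a", "b"]

    def test_neighbor_majority_promotes_matching_candidate(self):
        net = toy_network(["n1", "n2", "n3"], [("n1", "n2"), ("n1", "n3")])
        x = ("PX", "SX", "CX")
        y = ("PY", "SY", "CY")
        cands = {
            "n1": [cand("y_top", 0.6, triple=y), cand("x_alt", 0.6, triple=x)],
            "n2": [cand("x2", 0.9, triple=x)],
            "n3": [cand("x3", 0.9, triple=x)],
        }
        result = consensus_class(net, cands)
        cons, top = result["n1"]
        assert cons == x
        assert top[0].structure_id == "x_alt"  # bonus flips the sigma tie

    def test_five_node_family_matches_hand_tally(self):
        net = toy_network(list("abcde"),
                          [("a", "b"), ("a", "c"), ("a", "d"), ("a", "e")])
        tx = ("P1", "S1", "C1")
        ty = ("P2", "S2", "C2")
        cands = {
            "a": [cand("a1", 0.5, triple=tx)],
            "b": [cand("b1", 0.9, triple=ty)],
            "c": [cand("c1", 0.3, triple=tx)],
            "d": [cand("d1", 0.4, triple=tx)],
            "e": [cand("e1", 0.7, triple=ty)],
        }
        # hand tally for node a: tx = 0.5+0.3+0.4 = 1.2 < ty = 0.9+0.7 = 1.6
        cons, _ = consensus_class(net, cands)["a"]
        assert cons == ty
        # node b sees only a and itself: ty = 0.9 > tx = 0.5
        cons_b, _ = consensus_class(net, cands)["b"]
        assert cons_b == ty

    def test_tie_breaks_lexicographically(self):
        net = toy_network(["n1"], [])
        cands = {"n1": [cand("z", 0.5, triple=("PB", "SB", "CB")),
                        cand("a", 0.5, triple=("PA", "SA", "CA"))]}
        cons, _ = consensus_class(net, cands)["n1"]
        assert cons == ("PB", "SB", "CB")  # rank-1 vote only; z listed first
        # two isolated equal-weight voters cannot occur on one node; check
        # the label tie rule directly with equal-sigma voters via neighbors
        net2 = toy_network(["m", "u", "v"], [("m", "u"), ("m", "v")])
        cands2 = {"u": [cand("u1", 0.5, triple=("PB", "SB", "CB"))],
                  "v": [cand("v1", 0.5, triple=("PA", "SA", "CA"))]}
        cons_m, _ = consensus_class(net2, cands2)["m"]
        assert cons_m == ("PA", "SA", "CA")


class TestIdentityMatch:
    def test_exact_standard_confirms(self):
        e = entry("std", 300.0)
        out = identity_match(e.spectrum, [e])
        assert out is not None and out.structure_id == "std"
        assert out.score == 1.0

    def test_mass_error_beyond_20ppm_rejected(self):
        e = entry("std", 300.0)
        probe = spec(e.spectrum.precursor_mz * (1 + 25e-6),
                     e.spectrum.mz, e.spectrum.intensities)
        assert identity_match(probe, [e]) is None

    def test_score_below_threshold_rejected(self):
        e = entry("std", 300.0)
        # share 4 of 6 peaks: cosine ~ 0.66 < 0.8
        probe = spec(e.spectrum.precursor_mz,
                     [50.0, 60.0, 70.0, 80.0, 130.0, 140.0], [1.0] * 6)
        assert identity_match(probe, [e]) is None
        relaxed = AnnotationParams(identity_min_score=0.3)
        assert identity_match(probe, [e], relaxed) is not None


class TestDatasetCascade:
    def test_perfect_information_recovers_truth(self, zero_noise_study,
                                                processed, network):
        truth, _, _ = zero_noise_study
        general, _, _ = processed
        lib = make_library(truth)
        tree = make_taxonomy(truth.design)
        records, stats = annotate_dataset(general, network, lib, tree,
                                          standards=lib)
        assert stats["fraction_annotated"] == 1.0
        assert stats["fraction_confirmed"] == 1.0
        from holometab.compare import match_features_to_truth
        mapping = match_features_to_truth(general, truth)
        bio = {f: m for f, m in mapping.items() if m.startswith("M")}
        assert bio
        for fid, mid in bio.items():
            assert records[fid].candidates[0].structure_id == mid
            met = next(m for m in truth.metabolites if m.id == mid)
            assert records[fid].consensus_triple == met.class_triple

    def test_empty_library_yields_unannotated(self, processed, network):
        general, _, _ = processed
        tree = TaxonomyTree(nodes={"root": ("root", "root", None)})
        records, stats = annotate_dataset(general, network, [], tree)
        assert stats["fraction_annotated"] == 0.0
        assert all(r.tier == "unannotated" for r in records.values())
        assert all(r.consensus_triple == (None, None, None)
                   for r in records.values())


class TestLibraryIO:
    def test_mgf_tsv_round_trip(self, library_and_tree, tmp_path):
        lib, _ = library_and_tree
        paths = write_library(lib, tmp_path)
        back = read_library(paths["mgf"], paths["tsv"])
        assert len(back) == len(lib)
        for a, b in zip(lib, back):
            assert a.structure_id == b.structure_id
            assert a.class_triple == b.class_triple
            assert a.source_taxa == b.source_taxa
            assert a.monoisotopic_mass == pytest.approx(b.monoisotopic_mass)
            np.testing.assert_allclose(a.spectrum.mz, b.spectrum.mz, atol=1e-9)

    def test_msp_round_trip(self, library_and_tree, tmp_path):
        lib, _ = library_and_tree
        path = write_msp(lib[:5], tmp_path / "standards.msp")
        back = read_msp(path)
        assert [e.structure_id for e in back] == [e.structure_id for e in lib[:5]]
        np.testing.assert_allclose(back[0].spectrum.intensities,
                                   lib[0].spectrum.intensities /
                                   lib[0].spectrum.intensities.max(),
                                   atol=1e-6)
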