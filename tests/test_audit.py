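import math

import numpy as np
import pytest

from barcodeaudit.audit import (
    AuditConfig,
    Concordance,
    classify_species,
    concordance_counts,
    detect_sharing,
    genus_size_sharing,
    identification_success,
    regional_success,
    run_full_audit,
)
from barcodeaudit.clustering import ClusterPartition, single_linkage_clusters
from barcodeaudit.distances import SpeciesSummary, distance_matrix, species_summaries
from barcodeaudit.simulate import SimulationParams, simulate_library

from conftest import make_library, matrix_from_array


def _summary(sp, n=2, max_intra=0.5, nn=5.0, nn_sp="other"):
    return SpeciesSummary(sp, n, max_intra, max_intra / 2, nn, nn_sp)


class TestDetectSharing:
    def test_identical_haplotypes_form_a_group(self):
        m = matrix_from_array([[0.0, 0.0], [0.0, 0.0]], labels=["x", "y"])
        groups = detect_sharing(m, {"x": "A", "y": "B"})
        assert groups == [{"A", "B"}]

    def test_assemblage_by_chaining(self):
        # A-B identical through one haplotype, B-C through another, A-C distinct
        vals = np.array(
            [
                [0.0, 0.0, 4.0, 4.0],
                [0.0, 0.0, 4.0, 4.0],
                [4.0, 4.0, 0.0, 0.0],
                [4.0, 4.0, 0.0, 0.0],
            ]
        )
        m = matrix_from_array(vals, labels=["a1", "b1", "b2", "c1"])
        smap = {"a1": "A", "b1": "B", "b2": "B", "c1": "C"}
        groups = detect_sharing(m, smap)
        assert groups == [{"A", "B", "C"}]

    def test_planted_events_recovered_without_false_groups(self):
        params = SimulationParams(
            n_species=40, seqs_per_species=(4, 6), p_share=0.1, p_deep=0.0, seed=5
        )
        library, truth = simulate_library(params)
        m = distance_matrix(library)
        groups = detect_sharing(m, library.species_map)
        found = {sp for g in groups for sp in g}
        assert found == truth.sharing_species
        for g in groups:
            for sp in g:
                assert g - {sp} == set(truth.species[sp].sharing_partners)


class TestClassify:
    def _partition(self, mapping):
        return ClusterPartition(
            assignment=mapping, threshold=2.2, n_clusters=len(set(mapping.values()))
        )

    def test_singleton_private_cluster_is_match(self):
        part = self._partition({"x": 0, "z": 1})
        smap = {"x": "A", "z": "B"}
        audits = classify_species(
            [_summary("A", n=1, max_intra=float("nan")), _summary("B", n=1, max_intra=float("nan"))],
            [], part, smap,
        )
        a = audits[0]
        assert a.concordance is Concordance.MATCH
        assert not (a.sharing or a.low_divergence or a.deep_divergence)

    def test_two_private_clusters_with_deep_intra_is_split(self):
        part = self._partition({"x1": 0, "x2": 1, "z": 2})
        smap = {"x1": "A", "x2": "A", "z": "B"}
        audits = classify_species(
            [_summary("A", max_intra=3.0), _summary("B", n=1)], [], part, smap
        )
        a = {x.species: x for x in audits}["A"]
        assert a.concordance is Concordance.SPLIT
        assert a.deep_divergence and a.n_clusters == 2

    def test_cooccupied_cluster_with_zero_distance_is_merge_and_sharing(self):
        part = self._partition({"x": 0, "y": 0})
        smap = {"x": "A", "y": "B"}
        audits = classify_species(
            [_summary("A", nn=0.0, nn_sp="B"), _summary("B", nn=0.0, nn_sp="A")],
            [{"A", "B"}], part, smap,
        )
        for a in audits:
            assert a.concordance is Concordance.MERGE and a.sharing

    def test_low_divergence_needs_positive_nn_below_ceiling(self):
        part = self._partition({"x": 0, "y": 1})
        smap = {"x": "A", "y": "B"}
        audits = classify_species(
            [_summary("A", nn=1.5, nn_sp="B"), _summary("B", nn=1.5, nn_sp="A")],
            [], part, smap,
        )
        assert all(a.low_divergence for a in audits)


class TestConcordanceCounts:
    def test_three_class_example(self):
        part = ClusterPartition(
            assignment={"a": 0, "b1": 1, "b2": 2, "c": 3, "d": 3},
            threshold=2.2, n_clusters=4,
        )
        smap = {"a": "A", "b1": "B", "b2": "B", "c": "C", "d": "D"}
        summaries = [
            _summary("A", n=1), _summary("B", max_intra=3.0),
            _summary("C", nn=0.0, nn_sp="D"), _summary("D", nn=0.0, nn_sp="C"),
        ]
        audits = classify_species(summaries, [{"C", "D"}], part, smap)
        s = concordance_counts(audits)
        assert (s.n_match, s.n_split, s.n_merge, s.n_mixed) == (1, 1, 2, 0)
        assert s.n_match + s.n_split + s.n_merge + s.n_mixed == s.n_species

    def test_empty_audit_list(self):
        s = concordance_counts([])
        assert s.n_species == 0 and math.isnan(s.pct_id_success)

    def test_counts_equal_generator_truth(self, small_sim):
        library, truth = small_sim
        audits, summary, *_ = run_full_audit(library)
        assert summary.n_sharing == len(truth.sharing_species)
        assert summary.n_deep == len(truth.deep_species)
        # identity holds exactly on every run
        assert summary.pct_id_success == identification_success(
            summary.n_species, summary.n_sharing
        )


class TestRegionalSuccess:
    def test_single_species_region_is_fully_diagnosable(self):
        lib = make_library(
            [("x", "ACGT" * 150, "A_a", "A", "F1", "north"),
             ("y", "AAGT" * 150, "B_b", "B", "F1", "south")]
        )
        m = distance_matrix(lib, min_overlap=100)
        out = regional_success(lib, m)
        assert out["north"] == (100.0, 1, 1)

    def test_printed_fraction_arithmetic(self):
        # 18 of 387 regional species in sharing groups
        assert round(identification_success(387, 18), 1) == 95.3

    def test_absent_partner_raises_regional_success(self):
        params = SimulationParams(
            n_species=30, seqs_per_species=(4, 6), p_share=0.15, p_deep=0.0,
            region_disjoint_sharing=True, seed=13,
        )
        library, truth = simulate_library(params)
        assert truth.sharing_species  # the contrast needs planted events
        m = distance_matrix(library)
        national = identification_success(
            len(truth.species), len(truth.sharing_species)
        )
        for region, (pct, _, _) in regional_success(library, m).items():
            assert pct >= national


def test_genus_size_bins_are_log2():
    part = ClusterPartition(
        assignment={f"s{i}": i for i in range(15)}, threshold=2.2, n_clusters=15
    )
    sizes = {"G1": 1, "G2": 2, "G4": 4, "G8": 8}
    summaries, smap, genus_map = [], {}, {}
    i = 0
    for genus, size in sizes.items():
        for k in range(size):
            sp = f"{genus}_sp{k}"
            summaries.append(_summary(sp, n=1))
            smap[f"s{i}"] = sp
            genus_map[sp] = genus
            i += 1
    audits = classify_species(summaries, [], part, smap)
    table, (gsizes, incidence) = genus_size_sharing(audits, genus_map)
    assert table["bin"].tolist() == [0, 1, 2, 3]
    assert sorted(gsizes) == [1, 2, 4, 8]
    assert all(v == 0.0 for v in incidence)


def test_sharing_in_large_genera_yields_positive_rank_correlation():
    from barcodeaudit.stats import spearman

    params = SimulationParams(
        n_species=60, seqs_per_species=(3, 5), p_share=0.12, p_deep=0.0, seed=21
    )
    library, truth = simulate_library(params)
    audits, *_ = run_full_audit(library)
    _, (sizes, incidence) = genus_size_sharing(audits, library.genus_map)
    assert truth.sharing_species
    rho, _ = spearman(sizes, incidence)
    assert rho > 0


def test_deep_set_invariant_to_cluster_threshold(small_sim):
    library, _ = small_sim
    m = distance_matrix(library)
    summaries = species_summaries(m, library.species_map)
    groups = detect_sharing(m, library.species_map)
    deep_sets = []
    split_sizes = []
    for threshold in (1.0, 2.2, 4.0):
        part = single_linkage_clusters(m, threshold)
        audits = classify_species(
            summaries, groups, part, library.species_map, AuditConfig()
        )
        deep_sets.append({a.species for a in audits if a.deep_divergence})
        split_sizes.append(sum(a.n_clusters >= 2 for a in audits))
    assert deep_sets[0] == deep_sets[1] == deep_sets[2]
    # split set shrinks (weakly) as the threshold coarsens the partition
    assert split_sizes[0] >= split_sizes[1] >= split_sizes[2]
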