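import itertools
import math

import numpy as np
import pytest

from nrpsarch.fixtures import LoopPopulationSpec, synth_loop_population
from nrpsarch.locator import LocatorError, locate_motifs
from nrpsarch.loops import (CodeRecord, LoopVector, assign_to_groups,
                            cluster_loop_groups, code_entropy,
                            loop_distance_matrix, loop_vector,
                            normalize_loop_profile)

REF_LOOPS = (25, 29, 19, 26, 20)  # derived by hand from the layout table


class TestLoopVector:
    def test_reference_loop_lengths(self, catalog):
        ref = catalog.reference("refA")
        arch = locate_motifs(ref.sequence, [ref], catalog)
        vec = loop_vector(arch, catalog)
        assert vec.lengths == REF_LOOPS

    def test_five_elements_always(self, catalog):
        from nrpsarch.fixtures import DomainRecipe, synth_domain

        for seed in range(5):
            dom = synth_domain(DomainRecipe(domain_type="A"), seed=seed)
            arch = locate_motifs(dom.sequence,
                                 [catalog.reference("refA")], catalog)
            vec = loop_vector(arch, catalog)
            assert len(vec.lengths) == 5
            assert all(v >= 0 for v in vec.lengths)

    def test_planted_indels_shift_loops(self, catalog):
        ref = catalog.reference("refA")
        s6 = catalog.code_positions["s6"]
        a5_start = dict((m, s) for m, s, _e in ref.motif_spans)["A5"]
        seq = ref.sequence
        # delete 3 residues strictly between s6 and the A5 motif
        edited = seq[:s6 + 3] + seq[s6 + 6:]
        arch = locate_motifs(edited, [ref], catalog)
        vec = loop_vector(arch, catalog)
        expected = list(REF_LOOPS)
        expected[3] -= 3
        assert vec.lengths == tuple(expected)
        assert s6 + 6 < a5_start

    def test_adjacent_anchors_zero_length(self, catalog):
        ref = catalog.reference("refA")
        s6 = catalog.code_positions["s6"]
        a5_start = dict((m, s) for m, s, _e in ref.motif_spans)["A5"]
        # remove the whole S6-A5 loop: anchors become adjacent
        edited = ref.sequence[:s6] + ref.sequence[a5_start - 1:]
        arch = locate_motifs(edited, [ref], catalog)
        vec = loop_vector(arch, catalog)
        assert vec.lengths[3] == 0

    def test_missing_anchor_named(self, catalog):
        ref = catalog.reference("refA")
        g_start = dict((m, s) for m, s, _e in ref.motif_spans)["G"]
        arch = locate_motifs(ref.sequence[:g_start - 5], [ref], catalog)
        with pytest.raises(LocatorError, match="G motif"):
            loop_vector(arch, catalog)

    def test_non_a_domain_rejected(self, catalog):
        ref = catalog.reference("refC")
        arch = locate_motifs(ref.sequence, [ref], catalog)
        with pytest.raises(LocatorError):
            loop_vector(arch, catalog)

    def test_vector_validation(self):
        with pytest.raises(ValueError):
            LoopVector(a_domain_id="x", lengths=(1, 2, 3))
        with pytest.raises(ValueError):
            LoopVector(a_domain_id="x", lengths=(1, 2, 3, 4, -1))


class TestDistanceMatrix:
    def _vec(self, lengths, name="v"):
        return LoopVector(a_domain_id=name, lengths=tuple(lengths))

    def test_identical_vectors_zero(self):
        vs = [self._vec([3, 4, 5, 6, 7]), self._vec([3, 4, 5, 6, 7])]
        d = loop_distance_matrix(vs)
        assert d[0, 1] == 0.0
        assert np.allclose(np.diag(d), 0.0)

    def test_hand_computed_345(self):
        vs = [self._vec([3, 4, 0, 0, 0]), self._vec([0, 0, 0, 0, 0])]
        assert loop_distance_matrix(vs)[0, 1] == pytest.approx(5.0)

    def test_cap_at_12(self):
        vs = [self._vec([13, 0, 0, 0, 0]), self._vec([0, 0, 0, 0, 0])]
        assert loop_distance_matrix(vs)[0, 1] == pytest.approx(12.0)

    def test_metric_properties(self):
        rng = np.random.default_rng(0)
        vs = [self._vec(rng.integers(0, 8, size=5)) for _ in range(12)]
        d = loop_distance_matrix(vs, cap=1e9)
        assert np.allclose(d, d.T)
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9


class TestClustering:
    def test_three_separated_clusters_recovered(self):
        spec = LoopPopulationSpec(
            centers=[(2, 2, 2, 2, 2), (9, 9, 9, 9, 9), (2, 9, 2, 9, 2)],
            n_per_group=15)
        vectors, truth = synth_loop_population(spec, seed=0)
        d = loop_distance_matrix(vectors)
        groups = cluster_loop_groups(d, k=3)
        # partition equality up to relabeling
        assert len(set(zip(groups, truth))) == 3

    def test_identical_points_single_group(self):
        vs = [LoopVector(a_domain_id=f"v{i}", lengths=(1, 1, 1, 1, 1))
              for i in range(5)]
        groups = cluster_loop_groups(loop_distance_matrix(vs), k=1)
        assert set(groups) == {1}

    def test_permutation_equivalent_partition(self):
        spec = LoopPopulationSpec(
            centers=[(1, 1, 1, 1, 1), (8, 8, 8, 8, 8)], n_per_group=10)
        vectors, _ = synth_loop_population(spec, seed=1)
        d = loop_distance_matrix(vectors)
        g1 = cluster_loop_groups(d, k=2)
        perm = np.random.default_rng(2).permutation(len(vectors))
        d2 = d[np.ix_(perm, perm)]
        g2 = cluster_loop_groups(d2, k=2)
        pairs1 = {(i, j) for i in range(len(vectors))
                  for j in range(len(vectors)) if g1[i] == g1[j]}
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        pairs2 = {(i, j) for i in range(len(vectors))
                  for j in range(len(vectors)) if g2[inv[i]] == g2[inv[j]]}
        assert pairs1 == pairs2

    def test_k_too_large(self):
        vs = [LoopVector(a_domain_id="a", lengths=(1, 1, 1, 1, 1)),
              LoopVector(a_domain_id="b", lengths=(2, 2, 2, 2, 2))]
        with pytest.raises(ValueError):
            cluster_loop_groups(loop_distance_matrix(vs), k=5)

    def test_planted_recovery_across_seeds(self):
        centers = [(2, 2, 2, 2, 2), (5, 5, 5, 5, 5), (8, 8, 8, 8, 8),
                   (2, 8, 2, 8, 2), (8, 2, 8, 2, 8)]
        for seed in range(10):
            spec = LoopPopulationSpec(centers=centers, n_per_group=40)
            vectors, truth = synth_loop_population(spec, seed=seed)
            d = loop_distance_matrix(vectors)
            groups = cluster_loop_groups(d, k=5)
            assert len(set(zip(groups, truth))) == 5

    def test_nearest_group_assignment_with_ties(self):
        centroids = np.array([[0, 0, 0, 0, 0], [4, 0, 0, 0, 0]],
                             dtype=float)
        near = LoopVector(a_domain_id="n", lengths=(1, 0, 0, 0, 0))
        tied = LoopVector(a_domain_id="t", lengths=(2, 0, 0, 0, 0))
        assert assign_to_groups([near, tied], centroids) == [1, None]


class TestNormalization:
    def test_printed_formula_values(self):
        assert np.allclose(normalize_loop_profile([2, 4, 6]),
                           [1 / 3, 1.0, 5 / 3])

    def test_constant_column_all_ones(self):
        assert np.allclose(normalize_loop_profile([7, 7, 7, 7]), 1.0)

    def test_minimum_maps_to_reciprocal(self):
        L = [3, 5, 10]
        normalized = normalize_loop_profile(L)
        expected = 1.0 / (np.mean(L) - 3 + 1)
        assert normalized[0] == pytest.approx(expected)


class TestCodeEntropy:
    def _rec(self, code, substrate, phylum=None, group=None):
        return CodeRecord(a_domain_id="x", code=code,
                          mask=tuple([True] * len(code)),
                          substrate=substrate, phylum=phylum,
                          loop_group=group)

    def test_identical_codes_zero_entropy(self):
        records = [self._rec("DAWTIAAVCK", "phe") for _ in range(4)]
        table = code_entropy(records)
        assert table.iloc[0]["entropy_bits"] == pytest.approx(0.0)

    def test_two_equiprobable_codes_one_bit(self):
        records = [self._rec("DAWTIAAVCK", "phe"),
                   self._rec("DAWTIAAVCK", "phe"),
                   self._rec("DLWNLSLIWK", "phe"),
                   self._rec("DLWNLSLIWK", "phe")]
        table = code_entropy(records)
        assert table.iloc[0]["entropy_bits"] == pytest.approx(1.0)

    def test_hand_enumerated_conditional(self):
        # 6 records, 2 groups; group g1: codes {a,a,b}, g2: {c,c,c}
        records = [self._rec("a", "x", group=1),
                   self._rec("a", "x", group=1),
                   self._rec("b", "x", group=1),
                   self._rec("c", "x", group=2),
                   self._rec("c", "x", group=2),
                   self._rec("c", "x", group=2)]
        unconditional = code_entropy(records).iloc[0]["entropy_bits"]
        conditional = code_entropy(records, "group").iloc[0]["entropy_bits"]
        h_g1 = -(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3)
        assert conditional == pytest.approx(0.5 * h_g1)
        assert conditional <= unconditional

    def test_monotone_under_finer_conditioning(self):
        rng = np.random.default_rng(3)
        codes = ["AA", "AB", "BA", "BB"]
        records = []
        for i in range(60):
            records.append(self._rec(
                codes[rng.integers(4)], "sub",
                phylum=f"p{rng.integers(2)}", group=int(rng.integers(3))))
        h = code_entropy(records).iloc[0]["entropy_bits"]
        h_p = code_entropy(records, "phylum").iloc[0]["entropy_bits"]
        h_pg = code_entropy(records, "both").iloc[0]["entropy_bits"]
        assert h_pg <= h_p + 1e-9 <= h + 1e-9

    def test_small_substrate_flagged(self):
        records = [self._rec("AA", "rare")]
        table = code_entropy(records)
        assert bool(table.iloc[0]["flagged_small"])

    def test_code_mask_validation(self):
        with pytest.raises(ValueError):
            CodeRecord(a_domain_id="x", code="ABC", mask=(True, False))
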