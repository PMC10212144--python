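import math

import numpy as np
import pytest

from nrpsarch.fixtures import AlignmentSpec, synth_labeled_alignment
from nrpsarch.sca import (SCAConfig, augment_with_labels,
                          binarize_alignment, clean_matrix,
                          conservation_Di, coupling_matrix, extract_sectors,
                          null_spectrum, position_weights,
                          sca_decomposition, sca_with_label,
                          substrate_related_modes)
from nrpsarch.stats import LabeledAlignment


def make_aln(rows, **labels):
    return LabeledAlignment(ids=[f"s{i}" for i in range(len(rows))],
                            rows=rows, labels=labels)


class TestBinarize:
    def test_fully_conserved_column(self):
        b = binarize_alignment(make_aln(["AC", "AC", "AC", "AC"]))
        assert b.consensus[0] == "A"
        assert (b.matrix[:, 0] == 1).all()
        # regularized: (4 + 0.5) / (4 + 1)
        assert b.f[0] == pytest.approx(4.5 / 5)

    def test_hand_counted_split_column(self):
        b = binarize_alignment(make_aln(["AC", "AC", "GC", "GC"]))
        assert b.consensus[0] == "A"  # tie broken alphabetically
        assert b.f[0] == pytest.approx(2.5 / 5)
        assert list(b.matrix[:, 0]) == [1, 1, 0, 0]

    def test_row_permutation_equivariance(self):
        rows = ["AC", "AD", "GC", "GD"]
        b1 = binarize_alignment(make_aln(rows))
        b2 = binarize_alignment(make_aln(rows[::-1]))
        assert np.array_equal(b1.matrix, b2.matrix[::-1])

    def test_all_gap_column_excluded(self):
        with pytest.warns(UserWarning, match="all-gap"):
            b = binarize_alignment(make_aln(["A-C", "A-C", "G-C"]))
        assert list(b.columns) == [0, 2]


class TestConservation:
    def test_f_equals_q_gives_zero(self):
        assert conservation_Di(0.3, 0.3) == pytest.approx(0.0)

    def test_closed_form_value(self):
        assert conservation_Di(0.9, 0.05) == pytest.approx(2.3762, abs=5e-5)

    def test_positive_off_diagonal(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            f, q = rng.uniform(0.01, 0.99, size=2)
            if abs(f - q) < 1e-6:
                continue
            assert conservation_Di(f, q) > 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            conservation_Di(0.0, 0.5)
        with pytest.raises(ValueError):
            conservation_Di(0.5, 1.0)


class TestCouplingMatrix:
    def test_identical_columns_closed_form(self):
        rows = ["AA"] * 6 + ["GG"] * 4
        b = binarize_alignment(make_aln(rows))
        C = coupling_matrix(b.matrix, b.f, b.q)
        phi = position_weights(b.f, b.q)
        x = b.matrix[:, 0].astype(float)
        cov = x.var()  # identical columns: cov = var = f_raw(1-f_raw)
        assert C[0, 1] == pytest.approx(phi[0] * phi[1] * cov)
        assert cov == pytest.approx(0.6 * 0.4)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        rows = ["".join("AG"[i] for i in rng.integers(0, 2, size=8))
                for _ in range(30)]
        b = binarize_alignment(make_aln(rows))
        C = coupling_matrix(b.matrix, b.f, b.q)
        assert np.allclose(C, C.T)
        assert (C >= 0).all()

    def test_independent_columns_below_null_scale(self):
        spec = AlignmentSpec(n_rows=1000, n_cols=12)
        aln, _ = synth_labeled_alignment(spec, seed=7)
        config = SCAConfig(n_trials=20, seed=7)
        result = sca_decomposition(aln, config)
        off = result.coupling - np.diag(np.diag(result.coupling))
        assert np.abs(off).max() < result.null_threshold


class TestNullSpectrum:
    def test_composition_preserved(self):
        spec = AlignmentSpec(n_rows=40, n_cols=6)
        aln, _ = synth_labeled_alignment(spec, seed=1)
        b = binarize_alignment(aln)
        rng = np.random.default_rng(0)
        shuffled = np.stack([b.matrix[rng.permutation(40), j]
                             for j in range(b.matrix.shape[1])], axis=1)
        assert (shuffled.sum(axis=0) == b.matrix.sum(axis=0)).all()

    def test_deterministic_given_seed(self):
        spec = AlignmentSpec(n_rows=60, n_cols=10)
        aln, _ = synth_labeled_alignment(spec, seed=2)
        b = binarize_alignment(aln)
        config = SCAConfig(n_trials=1, seed=123)
        t1 = null_spectrum(b, config)
        t2 = null_spectrum(b, config)
        assert np.array_equal(t1, t2)

    def test_iid_alignment_within_null(self):
        # unstructured alignments should rarely beat the null threshold
        # beyond mode 1
        hits = 0
        for seed in range(20):
            spec = AlignmentSpec(n_rows=120, n_cols=15)
            aln, _ = synth_labeled_alignment(spec, seed=seed)
            result = sca_decomposition(aln, SCAConfig(n_trials=20,
                                                      seed=seed))
            if result.eigenvalues[1] <= result.null_threshold:
                hits += 1
        assert hits >= 18


def planted_result(seed, n_rows=500, noise=0.02, n_trials=20):
    group_a = list(range(5, 15))
    group_b = list(range(25, 35))
    spec = AlignmentSpec(n_rows=n_rows, n_cols=60,
                         covarying_groups=[group_a, group_b],
                         covariation_noise=noise)
    aln, truth = synth_labeled_alignment(spec, seed=seed)
    result = sca_decomposition(aln, SCAConfig(n_trials=n_trials, seed=seed))
    return result, truth


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if a | b else 1.0


def recovered_groups(result):
    """Sectors of the two leading significant modes, both signs."""
    sectors = extract_sectors(result, [(1, "+"), (1, "-"),
                                       (2, "+"), (2, "-")])
    return [s.members for s in sectors if s.members]


class TestSectors:
    def test_below_epsilon_empty(self):
        spec = AlignmentSpec(n_rows=50, n_cols=8)
        aln, _ = synth_labeled_alignment(spec, seed=3)
        result = sca_decomposition(aln, SCAConfig(n_trials=1, seed=3))
        sectors = extract_sectors(result, [(4, "+"), (4, "-")],
                                  epsilon=10.0)
        assert all(not s.members for s in sectors)

    def test_planted_groups_recovered(self):
        result, truth = planted_result(seed=0)
        groups = recovered_groups(result)
        for planted in truth["covarying_groups"]:
            best = max(jaccard(g, planted) for g in groups)
            assert best >= 0.9

    def test_sign_flip_swaps_sectors(self):
        result, _ = planted_result(seed=1, n_rows=200, n_trials=5)
        plus, minus = extract_sectors(result, [(2, "+"), (2, "-")])
        flipped = result
        flipped.eigenvectors = -flipped.eigenvectors
        plus2, minus2 = extract_sectors(flipped, [(2, "+"), (2, "-")])
        assert set(plus.members) == set(minus2.members)
        assert set(minus.members) == set(plus2.members)

    def test_mode_out_of_range(self):
        result, _ = planted_result(seed=2, n_rows=100, n_trials=2)
        with pytest.raises(IndexError):
            extract_sectors(result, [(999, "+")])

    def test_planted_recovery_across_seeds(self):
        for seed in range(10):
            result, truth = planted_result(seed=seed, n_trials=5)
            groups = recovered_groups(result)
            for planted in truth["covarying_groups"]:
                assert max(jaccard(g, planted) for g in groups) >= 0.9

    def test_bootstrap_stability(self):
        result, truth = planted_result(seed=4)
        spec = AlignmentSpec(n_rows=500, n_cols=60,
                             covarying_groups=truth["covarying_groups"],
                             covariation_noise=0.02)
        aln, _ = synth_labeled_alignment(spec, seed=4)
        rng = np.random.default_rng(0)
        keep = sorted(rng.choice(500, size=450, replace=False))
        sub = LabeledAlignment(ids=[aln.ids[i] for i in keep],
                               rows=[aln.rows[i] for i in keep])
        sub_result = sca_decomposition(sub, SCAConfig(n_trials=5, seed=4))
        full_groups = recovered_groups(result)
        sub_groups = recovered_groups(sub_result)
        for g in full_groups:
            assert max(jaccard(g, h) for h in sub_groups) >= 0.7


class TestSpectrumIdentities:
    def test_trace_equals_eigenvalue_sum(self):
        result, _ = planted_result(seed=5, n_rows=150, n_trials=2)
        assert np.trace(result.coupling) == pytest.approx(
            result.eigenvalues.sum(), abs=1e-9)

    def test_eigenvectors_orthonormal(self):
        result, _ = planted_result(seed=6, n_rows=150, n_trials=2)
        V = result.eigenvectors
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)


class TestCleanMatrix:
    def test_pure_noise_cleans_to_zero(self):
        spec = AlignmentSpec(n_rows=400, n_cols=30)
        aln, _ = synth_labeled_alignment(spec, seed=8)
        result = sca_decomposition(aln, SCAConfig(n_trials=20, seed=8))
        cleaned = clean_matrix(result)
        assert (np.linalg.norm(cleaned, "fro")
                < 0.01 * np.linalg.norm(result.coupling, "fro"))

    def test_rank_bounded_by_significant_modes(self):
        result, _ = planted_result(seed=9)
        cleaned = clean_matrix(result)
        n_sig = int(((result.eigenvalues > result.null_threshold)[1:]).sum())
        rank = np.linalg.matrix_rank(cleaned, tol=1e-8)
        assert rank <= n_sig

    def test_keeping_everything_recovers_original(self):
        result, _ = planted_result(seed=10, n_rows=100, n_trials=2)
        full = clean_matrix(result, n_top_modes_removed=0,
                            noise_threshold=-np.inf)
        assert np.allclose(full, result.coupling, atol=1e-9)


class TestLabelAugmentation:
    def test_single_class_rejected(self):
        aln = make_aln(["AC", "GC"], substrate=["x", "x"])
        with pytest.raises(ValueError):
            augment_with_labels(aln, "substrate")

    def test_label_column_appended(self):
        aln = make_aln(["AC", "GC", "AC"], substrate=["x", "y", "x"])
        augmented, info = augment_with_labels(aln, "substrate")
        assert augmented.n_cols == 3
        assert info["label_column"] == 2
        assert info["background"] == pytest.approx(1 / 3)

    def test_deterministic_encoding_concentrates_contributions(self):
        spec = AlignmentSpec(n_rows=400, n_cols=30, n_classes=3,
                             class_probs=[0.6, 0.3, 0.1],
                             label_coupled_columns=[4, 12, 20],
                             label_coupling=1.0)
        aln, truth = synth_labeled_alignment(spec, seed=11)
        result, info = sca_with_label(aln, "subtype",
                                      SCAConfig(n_trials=10, seed=11))
        related = substrate_related_modes(result, info["label_column"])
        assert related, "label column should co-vary with some mode"
        member_cols = set()
        for mode in related[:3]:
            for sector in extract_sectors(result, [(mode, "+"),
                                                   (mode, "-")]):
                member_cols.update(
                    int(result.binarized.columns[i]) for i in sector.members)
        assert set(truth["label_coupled_columns"]) <= member_cols

    def test_contribution_threshold_semantics(self):
        spec = AlignmentSpec(n_rows=200, n_cols=20, n_classes=2,
                             label_coupled_columns=[3],
                             label_coupling=1.0)
        aln, _ = synth_labeled_alignment(spec, seed=12)
        result, info = sca_with_label(aln, "subtype",
                                      SCAConfig(n_trials=2, seed=12))
        from nrpsarch.sca import substrate_contributions

        contrib = substrate_contributions(result, info["label_column"])
        related = set(substrate_related_modes(result, info["label_column"]))
        for k, c in enumerate(contrib, start=1):
            if c <= 0.05:
                assert k not in related
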