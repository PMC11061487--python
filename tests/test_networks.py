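import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainnetdx import (
    ConnectivityMatrix,
    RegionalSummary,
    apply_zscore,
    cbf_network,
    extract_roi_samples,
    fit_zscore,
    fuse_features,
    gm_edge_weight,
    gm_network,
    regional_summaries,
    simulate_cohort,
    upper_triangle_vector,
)
from brainnetdx.cohort import CohortConfig, SubjectRecord
from brainnetdx.networks import DegenerateEdgeWarning

from _oracles import pearson_oracle


def _summary(u, sd, q=(1.0, 2.0, 3.0)):
    return RegionalSummary(region_index=0, mean_thickness=u, sd_thickness=sd,
                           cbf_quantiles=np.array(q))


def _subject(thickness, cbf):
    return SubjectRecord(subject_id="s", group="ASD", sex="M", age=4.0,
                         thickness_samples=[np.asarray(t, float) for t in thickness],
                         cbf_samples=[np.asarray(c, float) for c in cbf])


class TestRegionalSummaries:
    def test_mean_sd_and_quantiles(self):
        s = _subject([[2.0, 4.0]], [[10.0, 20.0, 30.0, 40.0]])
        (summ,) = regional_summaries(s, q=2)
        assert summ.mean_thickness == pytest.approx(3.0)
        assert summ.sd_thickness == pytest.approx(2.0 / np.sqrt(2))  # |diff|/sqrt(2)
        # levels (0.25, 0.75) with linear interpolation between order statistics
        assert summ.cbf_quantiles == pytest.approx(
            np.quantile([10.0, 20.0, 30.0, 40.0], [0.25, 0.75]))
        assert summ.cbf_quantiles == pytest.approx([17.5, 32.5])

    def test_constant_region(self):
        s = _subject([[2.5, 2.5, 2.5]], [[50.0, 50.0]])
        (summ,) = regional_summaries(s, q=3)
        assert summ.mean_thickness == pytest.approx(2.5)
        assert summ.sd_thickness == 0.0

    def test_too_few_thickness_samples_rejected(self):
        s = _subject([[2.5]], [[50.0]])
        with pytest.raises(ValueError, match="SD undefined"):
            regional_summaries(s)


class TestGrayMatterKernel:
    def test_equal_means_give_unit_weight(self):
        assert gm_edge_weight(_summary(3.0, 0.3), _summary(3.0, 0.5)) == 1.0

    def test_hand_computed_value(self):
        # u = 3 vs 1, both SDs 1: exp(-4 / (2*2)) = e^-1
        w = gm_edge_weight(_summary(3.0, 1.0), _summary(1.0, 1.0))
        assert w == pytest.approx(np.exp(-1.0), rel=1e-12)

    @given(
        ua=st.floats(0.5, 5), ub=st.floats(0.5, 5),
        sa=st.floats(0.01, 2), sb=st.floats(0.01, 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, ua, ub, sa, sb):
        a, b = _summary(ua, sa), _summary(ub, sb)
        w = gm_edge_weight(a, b)
        assert w == gm_edge_weight(b, a)
        assert 0.0 <= w <= 1.0
        # strictly positive except when exp underflows at double precision
        if (ua - ub) ** 2 / (2 * (sa**2 + sb**2)) < 700:
            assert w > 0.0

    def test_degenerate_zero_sds(self):
        with pytest.warns(DegenerateEdgeWarning):
            assert gm_edge_weight(_summary(2.0, 0.0), _summary(2.0, 0.0)) == 1.0
        with pytest.warns(DegenerateEdgeWarning):
            assert gm_edge_weight(_summary(2.0, 0.0), _summary(3.0, 0.0)) == 0.0


class TestGmNetwork:
    def test_matches_pairwise_kernel_and_symmetry(self, rng):
        summaries = [_summary(u, s) for u, s in zip(rng.uniform(2, 3.5, 7),
                                                    rng.uniform(0.2, 0.5, 7))]
        net = gm_network(summaries)
        assert net.weights.shape == (7, 7)
        assert np.array_equal(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 1.0)
        for a in range(7):
            for b in range(a + 1, 7):
                assert net.weights[a, b] == pytest.approx(
                    gm_edge_weight(summaries[a], summaries[b]), rel=1e-12)

    def test_identical_regions_give_all_ones(self):
        net = gm_network([_summary(2.5, 0.3)] * 4)
        assert np.all(net.weights == 1.0)

    @given(shift=st.floats(-1, 1))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariance(self, shift):
        # only the thickness difference enters the kernel
        base = [(2.4, 0.3), (3.1, 0.2), (2.9, 0.45)]
        n0 = gm_network([_summary(u, s) for u, s in base])
        n1 = gm_network([_summary(u + shift, s) for u, s in base])
        assert np.allclose(n0.weights, n1.weights, atol=1e-12)


class TestCbfNetwork:
    def test_perfect_linear_relations(self):
        # a positive affine transform of a descriptor correlates perfectly;
        # quantile descriptors are non-decreasing by construction, so the
        # network entries stay within [-1, 1] with unit diagonal
        qa = np.array([1.0, 2.0, 3.0, 4.0])
        summaries = [
            _summary(2.5, 0.3, qa),
            _summary(2.5, 0.3, 2 * qa + 5),
            _summary(2.5, 0.3, (1.0, 1.5, 4.0, 9.0)),
        ]
        net = cbf_network(summaries)
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert np.all(net.weights >= -1.0) and np.all(net.weights <= 1.0)
        assert np.all(np.diag(net.weights) == 1.0)

    def test_hand_computed_pearson(self):
        # direct evaluation of the sum-of-products formula gives 0.9234
        net = cbf_network([_summary(2.5, 0.3, (1.0, 2.0, 3.0, 4.0)),
                           _summary(2.5, 0.3, (1.0, 2.0, 2.0, 4.0))])
        expected = pearson_oracle([1, 2, 3, 4], [1, 2, 2, 4])
        assert net.weights[0, 1] == pytest.approx(expected, abs=1e-12)
        assert net.weights[0, 1] == pytest.approx(0.9233805, abs=1e-6)

    def test_constant_region_zeroed_with_warning(self):
        with pytest.warns(DegenerateEdgeWarning):
            net = cbf_network([_summary(2.5, 0.3, (1.0, 2.0, 3.0)),
                               _summary(2.5, 0.3, (5.0, 5.0, 5.0))])
        assert net.weights[0, 1] == 0.0
        assert net.weights[1, 1] == 1.0

    def test_affine_invariance_of_cbf_scale(self):
        # common positive affine transform of all CBF values leaves the network
        # unchanged (Pearson property)
        cfg = CohortConfig(n_asd=2, n_td=2, n_regions=6, vertices_per_region=10,
                           voxels_per_region=30, base_seed=2)
        subj = simulate_cohort(cfg)[0]
        net0 = cbf_network(regional_summaries(subj, q=10))
        subj.cbf_samples = [3.0 * v + 7.0 for v in subj.cbf_samples]
        net1 = cbf_network(regional_summaries(subj, q=10))
        assert np.allclose(net0.weights, net1.weights, atol=1e-10)


class TestVectorization:
    def test_row_major_ordering(self):
        w = np.array([[1.0, 0.2, 0.3], [0.2, 1.0, 0.4], [0.3, 0.4, 1.0]])
        vec, meta = upper_triangle_vector(ConnectivityMatrix("T1", w))
        assert vec == pytest.approx([0.2, 0.3, 0.4])
        assert meta == [("T1", 0, 1), ("T1", 0, 2), ("T1", 1, 2)]

    def test_full_atlas_length(self):
        subj = simulate_cohort(CohortConfig(n_asd=2, n_td=2, base_seed=0))[0]
        vec, meta = upper_triangle_vector(gm_network(regional_summaries(subj)))
        assert len(vec) == len(meta) == 3003  # 78 * 77 / 2

    def test_round_trip_reconstruction(self, rng):
        w = rng.random((5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        vec, meta = upper_triangle_vector(ConnectivityMatrix("ASL", w))
        rebuilt = np.eye(5)
        for (_, a, b), v in zip(meta, vec):
            rebuilt[a, b] = rebuilt[b, a] = v
        assert np.array_equal(rebuilt, w)

    def test_asymmetric_matrix_rejected(self):
        w = np.eye(3)
        w[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            upper_triangle_vector(ConnectivityMatrix("T1", w))


class TestZScore:
    def test_self_normalization(self, rng):
        x = rng.normal(size=(20, 6))
        z = apply_zscore(x, fit_zscore(x))
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_flagged_and_zeroed(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        norm = fit_zscore(x)
        assert norm.zero_sd.tolist() == [False, True]
        assert np.all(apply_zscore(x, norm)[:, 1] == 0.0)

    def test_train_statistics_applied_to_test(self):
        norm = fit_zscore(np.array([[1.0], [3.0]]))
        z = apply_zscore(np.array([[5.0]]), norm)
        assert z[0, 0] == pytest.approx(3.0 / np.sqrt(2))  # (5-2)/sqrt(2)

    def test_column_count_mismatch(self):
        norm = fit_zscore(np.zeros((3, 2)) + np.arange(3)[:, None])
        with pytest.raises(ValueError, match="columns"):
            apply_zscore(np.zeros((2, 3)), norm)


class TestFusion:
    def test_weighting_and_dimensions(self, rng):
        t1 = rng.normal(size=(4, 3))  # 3 regions -> 3 edges per modality
        asl = rng.normal(size=(4, 3))
        fs = fuse_features(t1, asl, 0.3)
        assert fs.matrix.shape == (4, 6)
        assert np.allclose(fs.matrix[:, :3], 0.3 * t1)
        assert np.allclose(fs.matrix[:, 3:], 0.7 * asl)
        assert {m for m, _, _ in fs.column_meta} == {"T1", "ASL"}
        assert len(set(fs.column_meta)) == 6

    def test_extreme_weight_zeroes_other_block(self, rng):
        t1, asl = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        assert np.all(fuse_features(t1, asl, 1.0).matrix[:, 3:] == 0.0)

    def test_subject_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_features(rng.normal(size=(3, 3)), rng.normal(size=(4, 3)), 0.5)

    def test_study_scale_feature_count(self, small_cohort):
        from brainnetdx import subject_feature_blocks
        x_t1, x_asl, m1, m2 = subject_feature_blocks(small_cohort, q=10)
        fs = fuse_features(x_t1, x_asl, 0.5, m1, m2)
        assert fs.matrix.shape[1] == 2 * (10 * 9 // 2)


class TestRoiExtraction:
    @pytest.fixture()
    def volumes(self, tmp_path):
        import nibabel as nib

        cbf = np.zeros((4, 4, 4))
        lab = np.zeros((4, 4, 4))
        lab[0, 0, 0] = lab[1, 1, 1] = lab[2, 2, 2] = 7
        cbf[0, 0, 0], cbf[1, 1, 1], cbf[2, 2, 2] = 40.0, 50.0, 60.0
        lab[3, 3, 3] = 9
        cbf[3, 3, 3] = 99.0
        p_cbf = tmp_path / "cbf.nii"
        p_lab = tmp_path / "lab.nii"
        nib.save(nib.Nifti1Image(cbf, np.eye(4)), p_cbf)
        nib.save(nib.Nifti1Image(lab, np.eye(4)), p_lab)
        return p_cbf, p_lab

    def test_label_values_extracted(self, volumes):
        p_cbf, p_lab = volumes
        out = extract_roi_samples(p_cbf, p_lab, {0: 7, 1: 9})
        assert sorted(out[0]) == [40.0, 50.0, 60.0]
        assert out[1].tolist() == [99.0]

    def test_absent_label_warns_and_is_empty(self, volumes):
        p_cbf, p_lab = volumes
        with pytest.warns(UserWarning, match="absent"):
            out = extract_roi_samples(p_cbf, p_lab, {0: 123})
        assert out[0].size == 0

    def test_grid_mismatch_rejected(self, volumes, tmp_path):
        import nibabel as nib

        p_cbf, _ = volumes
        bad = tmp_path / "bad.nii"
        nib.save(nib.Nifti1Image(np.zeros((5, 5, 5)), np.eye(4)), bad)
        with pytest.raises(ValueError, match="grids differ"):
            extract_roi_samples(p_cbf, bad, {0: 7})
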