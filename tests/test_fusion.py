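"""Selector weights, fused scores, segmentation maximization, outlier
rejection, and the end-to-end EM pipeline properties."""

import numpy as np
import pytest

from likefusion.fusion import (
    LOG_FLOOR,
    atlas_loglik_field,
    compute_selector,
    fused_label_scores,
    initialize_segmentation,
    maximize_segmentation,
    per_atlas_label_scores,
    remove_outlier_atlases,
    run_fusion,
    single_atlas_map,
    transformation_log_prior,
)
from likefusion.lddmm import KernelParams, VelocityField, geodesic_energy
from likefusion.synthetic import PopulationSpec, generate_population
from tests.conftest import standard_run


class TestSelector:
    def test_identical_atlases_uniform_weights(self):
        rng = np.random.default_rng(0)
        ll = np.repeat(rng.normal(-5, 1, size=(1, 8, 8, 8)), 4, axis=0)
        q = compute_selector(ll)
        assert np.allclose(q, 0.25)

    def test_single_atlas_weight_one(self):
        q = compute_selector(np.full((1, 6, 6, 6), -3.0))
        assert np.allclose(q, 1.0)

    def test_dominance_by_twenty_nats(self):
        ll = np.full((3, 8, 8, 8), -10.0)
        ll[0] += 20.0 / 125  # +20 nats after summing the radius-2 window
        q = compute_selector(ll, radius=2)
        assert q[0, 4, 4, 4] > 0.999

    def test_rows_convex(self):
        rng = np.random.default_rng(1)
        q = compute_selector(rng.normal(-8, 3, size=(5, 8, 8, 8)))
        assert np.all(q >= 0)
        assert np.allclose(q.sum(axis=0), 1.0, atol=1e-12)


class TestFusedScores:
    def test_single_atlas_reduction_and_convexity(self):
        rng = np.random.default_rng(2)
        c = rng.normal(-10, 2, size=(2, 4, 6, 6, 6))
        one = np.ones((1, 6, 6, 6))
        assert np.allclose(fused_label_scores(one, c[:1]), c[0])
        w10 = np.zeros((2, 6, 6, 6))
        w10[0] = 1.0
        assert np.allclose(fused_label_scores(w10, c), c[0])
        w_uniform = np.full((2, 6, 6, 6), 0.5)
        assert np.allclose(fused_label_scores(w_uniform, c), c.mean(axis=0))


class TestMaximize:
    def test_dominant_and_tie_breaks(self):
        scores = np.zeros((3, 2, 2, 2))
        scores[1] = 1.0
        ids = [1, 2, 5]
        assert np.all(maximize_segmentation(scores, ids) == 2)
        tie = np.zeros((2, 1, 1, 1))
        mass = np.zeros((2, 1, 1, 1))
        mass[1] = 0.8
        assert maximize_segmentation(tie, [1, 2], mass)[0, 0, 0] == 2  # larger prior wins
        assert maximize_segmentation(tie, [1, 2])[0, 0, 0] == 1  # lowest id wins

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            maximize_segmentation(np.full((2, 1, 1, 1), np.nan), [1, 2])


class TestInitialize:
    def test_majority_vote(self):
        priors = np.zeros((3, 2, 1, 1, 1))
        priors[0, 0] = priors[1, 0] = 1.0  # two atlases vote label index 0
        priors[2, 1] = 1.0
        out = initialize_segmentation(priors, [4, 9])
        assert out[0, 0, 0] == 4
        with pytest.raises(ValueError):
            initialize_segmentation(np.zeros((0, 2, 1, 1, 1)), [4, 9])


class TestLoglikField:
    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        n_a, n_k, dims = 3, 4, (6, 6, 6)
        scores = rng.normal(-10, 3, size=(n_a, n_k, *dims))
        seg = rng.integers(0, n_k, size=dims)
        fields = atlas_loglik_field(scores, seg)
        for a in range(n_a):
            total = 0.0
            for x in range(dims[0]):
                for y in range(dims[1]):
                    for z in range(dims[2]):
                        total += scores[a, seg[x, y, z], x, y, z]
            assert fields[a].sum() == pytest.approx(total)


class TestTransformationPrior:
    def test_zero_lambda_and_quadratic_scaling(self):
        rng = np.random.default_rng(4)
        v = VelocityField(rng.normal(size=(2, 3, 8, 8, 8)).astype(np.float32) * 0.05)
        k = KernelParams()
        assert transformation_log_prior(v, k, 0.0) == 0.0
        assert transformation_log_prior(None, k, 1.0) == 0.0
        p1 = transformation_log_prior(v, k, 2.0)
        p2 = transformation_log_prior(VelocityField(2 * v.v), k, 2.0)
        assert p1 < 0 and p2 == pytest.approx(4 * p1, rel=1e-4)
        assert p1 == pytest.approx(-2.0 * geodesic_energy(v, k), rel=1e-6)


class TestOutlierRemoval:
    def test_identical_atlases_none_removed(self):
        seg = np.zeros((8, 8, 8), dtype=np.int32)
        seg[2:5, 2:5, 2:5] = 1
        keep, report = remove_outlier_atlases(seg, [seg.copy()] * 4, [1])
        assert keep == [0, 1, 2, 3]
        assert report["retained"].all()

    def test_two_atlases_retention_floor(self):
        seg = np.zeros((8, 8, 8), dtype=np.int32)
        seg[2:5, 2:5, 2:5] = 1
        shifted = np.roll(seg, 4, axis=0)
        keep, _ = remove_outlier_atlases(seg, [seg.copy(), shifted], [1])
        assert len(keep) >= 1

    def test_requires_two(self):
        with pytest.raises(ValueError):
            remove_outlier_atlases(np.zeros((4, 4, 4), dtype=np.int32),
                                   [np.zeros((4, 4, 4), dtype=np.int32)], [1])


class TestPipeline:
    def test_noise_free_self_atlas_reproduces_labels(self, noise_free_mini):
        target, gold = noise_free_mini
        pop = generate_population((target, gold),
                                  PopulationSpec(n_atlases=1, amplitude=0.0,
                                                 jitter_sd=0.0, seed=0))
        res = run_fusion(target, pop)
        sl = res.roi.slices()
        for k in gold.dictionary:
            assert np.array_equal(res.segmentation.labels[sl] == k, gold.labels[sl] == k)
        assert res.n_iterations <= 2

    def test_single_atlas_equals_map_voxelwise(self):
        run = standard_run(0)
        regs = [run.regs[0]]
        fused = run_fusion(run.target, [run.atlases[0]], registrations=regs)
        mapped = single_atlas_map(run.target, run.atlases[0], registration=regs[0])
        assert np.array_equal(fused.segmentation.labels, mapped.segmentation.labels)

    def test_atlas_order_permutation_invariance(self):
        run = standard_run(0)
        rev = run_fusion(run.target, run.atlases[::-1], registrations=run.regs[::-1])
        assert np.array_equal(rev.segmentation.labels, run.fusion.segmentation.labels)

    def test_objective_monotone_and_weights_convex(self):
        run = standard_run(0)
        trace = run.fusion.trace
        obj = trace["objective"].to_numpy()
        assert np.all(np.diff(obj) >= -1e-6 * np.maximum(np.abs(obj[:-1]), 1.0))
        assert (trace["w_sum_err"] <= 1e-8).all()
        assert (trace["w_min"] >= 0).all()

    def test_every_roi_voxel_labeled(self):
        run = standard_run(0)
        sl = run.fusion.roi.slices()
        assert np.all(run.fusion.segmentation.labels[sl] > 0)

    def test_floored_scores_finite(self):
        run = standard_run(0)
        sl = run.fusion.roi.slices()
        scores = per_atlas_label_scores(run.target.values[sl],
                                        run.fusion.registered,
                                        run.fusion.label_ids)
        assert np.all(np.isfinite(scores))
        assert scores.min() >= 2 * LOG_FLOOR
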