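"""The generator's contracts: geometry, schedules, truths, and noise levels."""

import numpy as np
import pytest

import cerebconn as cc
from cerebconn.synthetic_data import _CONDITIONS_PER_TASK


class TestParcelSet:
    @pytest.mark.parametrize("n", [2, 80, 304])
    def test_even_hemisphere_split_and_unit_centers(self, n):
        ps = cc.make_parcel_set(n, seed=1)
        counts = ps.hemisphere_counts()
        assert counts["L"] == counts["R"] == n // 2
        assert np.allclose(np.linalg.norm(ps.centers, axis=1), 1.0, atol=1e-9)
        # hemispheres occupy disjoint half-spaces
        assert (ps.centers[ps.hemisphere == "L", 0] < 0).all()
        assert (ps.centers[ps.hemisphere == "R", 0] > 0).all()

    def test_deterministic_given_seed(self):
        a = cc.make_parcel_set(40, seed=9)
        b = cc.make_parcel_set(40, seed=9)
        assert np.array_equal(a.centers, b.centers)
        assert not np.array_equal(
            a.centers, cc.make_parcel_set(40, seed=10).centers
        )

    @pytest.mark.parametrize("bad", [0, 1, 3, 81])
    def test_rejects_odd_or_tiny_counts(self, bad):
        with pytest.raises(ValueError):
            cc.make_parcel_set(bad)


class TestSchedule:
    def test_task_set_regressor_counts(self):
        # 17 instructions + 29 conditions = 46; + 32 conditions = 49
        a = cc.make_schedule("A", seed=0)
        b = cc.make_schedule("B", seed=0)
        assert a.K == 46 and b.K == 49
        assert sum(k == "instruction" for k in a.kinds) == 17
        assert sum(k == "condition" for k in a.kinds) == 29
        assert sum(k == "condition" for k in b.kinds) == 32
        assert sum(_CONDITIONS_PER_TASK["A"]) == 29
        assert sum(_CONDITIONS_PER_TASK["B"]) == 32

    def test_seeds_permute_block_order_not_regressors(self):
        s1 = cc.make_schedule("A", seed=1)
        s2 = cc.make_schedule("A", seed=2)
        assert s1.labels == s2.labels
        assert s1.block_orders != s2.block_orders

    def test_design_boxcars_cover_blocks(self):
        sched = cc.make_schedule("A", seed=0)
        d = sched.design()
        # non-overlapping boxcars; instructions last 5 s, whole block 35 s
        assert (d.matrix.sum(axis=1) <= 1).all()
        for k, kind in enumerate(d.kinds):
            dur = d.matrix[:, k].sum() * sched.tr
            if kind == "instruction":
                assert dur == pytest.approx(5.0)
        # each task block occupies 35 s of regressor time in total
        for task in set(d.task_ids):
            cols = [k for k, t in enumerate(d.task_ids) if t == task]
            assert d.matrix[:, cols].sum() * sched.tr == pytest.approx(35.0)

    def test_insufficient_timepoints_rejected(self):
        with pytest.raises(ValueError):
            cc.make_schedule("A", timepoints_per_run=100)


class TestGroundTruth:
    def test_one_to_one_has_single_input_per_voxel(self, parcels80):
        t = cc.make_ground_truth(parcels80, 100, "one_to_one", seed=4)
        assert ((t.W_true != 0).sum(axis=0) == 1).all()

    def test_convergent_weight_variance(self, parcels80):
        t = cc.make_ground_truth(parcels80, 2000, "convergent", seed=4)
        assert t.W_true.var() == pytest.approx(0.2, abs=0.005)

    def test_regional_truth_support_counts(self, parcels80):
        rm = cc.make_region_map(40, 2)
        t = cc.make_regional_truth(parcels80, rm, [0.05, 0.10], seed=1)
        nz = (t.W_true != 0).sum(axis=0)
        assert (nz[rm.voxel_regions == 1] == round(0.05 * 80)).all()
        assert (nz[rm.voxel_regions == 2] == round(0.10 * 80)).all()

    def test_one_over_q_fraction_is_one_to_one(self, parcels20):
        rm = cc.make_region_map(10, 1)
        t = cc.make_regional_truth(parcels20, rm, [1 / 20], seed=1)
        assert ((t.W_true != 0).sum(axis=0) == 1).all()

    def test_fraction_yielding_no_parcels_rejected(self, parcels80):
        rm = cc.make_region_map(10, 1)
        with pytest.raises(ValueError):
            cc.make_regional_truth(parcels80, rm, [0.001], seed=1)
        with pytest.raises(ValueError):
            cc.make_regional_truth(parcels80, rm, [0.0], seed=1)

    def test_same_seed_identical_support(self, parcels80):
        rm = cc.make_region_map(20, 2)
        t1 = cc.make_regional_truth(parcels80, rm, [0.05, 0.1], seed=3)
        t2 = cc.make_regional_truth(parcels80, rm, [0.05, 0.1], seed=3)
        assert np.array_equal(t1.W_true, t2.W_true)


class TestSimulate:
    def test_noiseless_limit_reproduces_truth_exactly(self, parcels20):
        truth = cc.GroundTruth(
            W_true=np.ones((20, 5)), scenario="convergent",
            noise_variance=0.0, weight_variance=0.2, seed=0,
        )
        study = cc.simulate_study(
            "A", parcels20, truth, seed=2, cortical_noise_variance=0.0
        )
        for rec in study.sessions:
            Xn = rec.X_betas / rec.residual_sd_cortex
            Yn = rec.Y_betas / rec.residual_sd_cerebellum
            assert np.allclose(Yn, Xn @ truth.W_true, atol=1e-12)

    def test_session_noise_variance_matches_spec(self, parcels20):
        # >= 1e5 cerebellar noise draws: empirical variance 0.25 +/- 0.01
        truth = cc.make_ground_truth(
            parcels20, 2500, "one_to_one", seed=1, noise_variance=0.25
        )
        study = cc.simulate_study("A", parcels20, truth, seed=6)
        rec = study.sessions[0]
        E = (
            rec.Y_betas / rec.residual_sd_cerebellum
            - (rec.X_betas / rec.residual_sd_cortex) @ truth.W_true
        )
        assert E.size >= 1e5
        assert E.var() == pytest.approx(0.25, abs=0.01)

    def test_noise_independent_across_sessions(self, parcels20):
        truth = cc.make_ground_truth(parcels20, 2500, "one_to_one", seed=1)
        study = cc.simulate_study("A", parcels20, truth, seed=6)
        errs = []
        for rec in study.sessions:
            errs.append(
                rec.Y_betas / rec.residual_sd_cerebellum
                - (rec.X_betas / rec.residual_sd_cortex) @ truth.W_true
            )
        r = np.corrcoef(errs[0].ravel(), errs[1].ravel())[0, 1]
        assert abs(r) < 0.01

    def test_split_half_reliability_matches_analytic_value(self, parcels20):
        # corr(Y1, Y2) -> sigma_signal^2 / (sigma_signal^2 + sigma_noise^2),
        # where session noise = cerebellar noise + cortical session noise
        # propagated through the weights
        sv, cnv, nv = 1.0, 0.1, 0.25
        truth = cc.make_ground_truth(
            parcels20, 10_000, "one_to_one", seed=2, noise_variance=nv
        )
        study = cc.simulate_study(
            "A", parcels20, truth, seed=8,
            signal_variance=sv, cortical_noise_variance=cnv,
        )
        y = [
            r.Y_betas / r.residual_sd_cerebellum for r in study.sessions
        ]
        y0 = y[0] - y[0].mean(axis=0)
        y1 = y[1] - y[1].mean(axis=0)
        r = (y0 * y1).sum(axis=0) / np.sqrt(
            (y0**2).sum(axis=0) * (y1**2).sum(axis=0)
        )
        expected = sv / (sv + cnv + nv)
        assert np.mean(r) == pytest.approx(expected, abs=0.02)

    def test_dimension_mismatch_rejected(self, parcels20):
        truth = cc.make_ground_truth(parcels20, 10, "one_to_one", seed=0)
        sched = cc.make_schedule("A", seed=0)
        with pytest.raises(ValueError):
            cc.simulate_dataset([sched], cc.make_parcel_set(10), truth, seed=0)

    def test_reproducible_from_seed(self, parcels20):
        truth = cc.make_ground_truth(parcels20, 10, "convergent", seed=0)
        a = cc.simulate_study("A", parcels20, truth, seed=3)
        b = cc.simulate_study("A", parcels20, truth, seed=3)
        assert np.array_equal(a.sessions[0].Y_betas, b.sessions[0].Y_betas)
        assert np.array_equal(
            a.sessions[1].X_run_betas, b.sessions[1].X_run_betas
        )


def test_generator_round_trip_recovers_weights(parcels20):
    """Noiseless data + unpenalized regression return W_true exactly."""
    from cerebconn.estimators import RidgeConnectivity

    truth = cc.make_ground_truth(parcels20, 15, "convergent", seed=9)
    truth = cc.GroundTruth(
        W_true=truth.W_true, scenario="convergent",
        noise_variance=0.0, weight_variance=0.2, seed=9,
    )
    study = cc.simulate_study("A", parcels20, truth, seed=4)
    fd = cc.reconstruct_session(study.sessions[0], standardize=False)
    est = RidgeConnectivity(log_lambda=-np.inf).fit(fd.X, fd.Y)
    assert np.allclose(est.W_, truth.W_true, atol=1e-8)
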