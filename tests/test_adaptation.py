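"""Aiming axes/angles, spherical baseline removal and stage extraction."""

import numpy as np
import pytest

from quatgeo import adaptation as ad
from quatgeo import quatcore as qc
from quatgeo import reference as ref
from quatgeo import sphstats as ss
from quatgeo import synthgen as sg
from quatgeo.preprocess import NoMovementError, OrientationTrajectory


def trial(axis, q1=None, angle_deg=50.0, noise=0.0, seed=None, frame="extrinsic"):
    spec = sg.TrialSpec(
        q1=qc.IDENTITY if q1 is None else q1,
        target_axis=axis,
        target_angle=np.deg2rad(angle_deg),
        duration=0.5,
        rate=100.0,
        frame=frame,
        noise_axis_sd=noise,
        seed=seed,
    )
    return sg.gen_noisy_trial(spec)


class TestAimingAxis:
    def test_recovers_known_axis(self, rng):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        res = ad.aiming_axis(trial(axis))
        err = np.degrees(np.arccos(np.clip(res.axis @ axis, -1, 1)))
        assert err < 0.5

    def test_initial_orientation_removed_by_prerotation(self, rng):
        """The same intrinsic movement from two starts has the same aiming axis."""
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        res1 = ad.aiming_axis(trial(axis, q1=qc.IDENTITY, frame="intrinsic"))
        res2 = ad.aiming_axis(trial(axis, q1=qc.random_quaternion(rng), frame="intrinsic"))
        np.testing.assert_allclose(res1.axis, res2.axis, atol=1e-6)

    def test_constant_speed_rotation(self):
        """A constant-axis, constant-speed rotation: axis exact, speed = theta/T."""
        h = np.linspace(0, 1, 61)
        q = qc.geodesic(qc.IDENTITY, qc.from_axis_angle([0, 1, 0], 1.0), h)
        traj = OrientationTrajectory(h * 0.6, q, rate=100.0)
        res = ad.aiming_axis(traj)
        np.testing.assert_allclose(res.axis, [0, 1, 0], atol=1e-6)
        assert abs(res.peak_speed - 1.0 / 0.6) < 1e-3

    def test_below_threshold_rejected(self):
        slow = trial([0, 0, 1], angle_deg=np.degrees(0.01))  # peak ~0.04 rad/s
        with pytest.raises(NoMovementError):
            ad.aiming_axis(slow)

    def test_median_recovery_under_noise(self, rng):
        """Median axis error < 2 degrees across noisy synthetic trials."""
        errors = []
        for i in range(300):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            res = ad.aiming_axis(trial(axis, noise=2.0, seed=int(rng.integers(2**31))))
            errors.append(np.degrees(np.arccos(np.clip(res.axis @ axis, -1, 1))))
        assert np.median(errors) < 2.0


class TestBaselineAxis:
    def test_all_equal(self):
        axes = np.tile([0, 0, 1.0], (40, 1))
        np.testing.assert_allclose(ad.baseline_axis(axes, seed=0), [0, 0, 1])

    def test_symmetric_pair_averages_to_bisector(self):
        a = np.deg2rad(10)
        pair = np.array([[np.sin(a), 0, np.cos(a)], [-np.sin(a), 0, np.cos(a)]])
        axes = np.tile(pair, (20, 1))
        # picking the whole pool keeps the +/- pairs balanced
        np.testing.assert_allclose(
            ad.baseline_axis(axes, n_pool=40, n_pick=40, seed=3), [0, 0, 1], atol=1e-9
        )

    def test_vmf_sample_concentrates_near_mu(self):
        """Mean of 20 axes at kappa=50 has tangent sd ~1.8 degrees per component,
        so the error exceeds 5 degrees with Rayleigh probability ~2%."""
        rng = np.random.default_rng(17)
        mu = np.array([0.0, 0.6, 0.8])
        hits = 0
        for _ in range(1000):
            axes = ss.sample_vmf(mu, 50.0, 40, rng)
            base = ad.baseline_axis(axes, seed=int(rng.integers(2**31)))
            hits += np.degrees(np.arccos(np.clip(base @ mu, -1, 1))) < 5.0
        assert hits / 1000 >= 0.95

    def test_requires_pool(self):
        with pytest.raises(ValueError):
            ad.baseline_axis(np.tile([0, 0, 1.0], (10, 1)), seed=0)

    def test_degenerate_cancellation(self):
        axes = np.tile([[0, 0, 1.0], [0, 0, -1.0]], (20, 1))
        with pytest.raises(ad.DegenerateBaselineError):
            ad.baseline_axis(axes, n_pool=40, n_pick=40, seed=0)


class TestRemoveBaseline:
    def test_identity_when_aligned(self, rng):
        axes = ss.sample_vmf([0, 0, 1.0], 20, 30, rng)
        out = ad.remove_baseline(axes, [0, 0, 1.0], [0, 0, 1.0])
        np.testing.assert_allclose(out, axes)

    def test_baseline_maps_onto_ideal(self, rng):
        base = rng.standard_normal(3)
        base /= np.linalg.norm(base)
        ideal = rng.standard_normal(3)
        ideal /= np.linalg.norm(ideal)
        out = ad.remove_baseline(base[None, :], base, ideal)
        np.testing.assert_allclose(out[0], ideal, atol=1e-12)

    def test_isometry_preserves_pairwise_angles(self, rng):
        axes = ss.sample_vmf([0.6, 0.0, 0.8], 10, 25, rng)
        out = ad.remove_baseline(axes, [0.6, 0.0, 0.8], [0, 1.0, 0])

        def pairwise_angles(v):
            dots = v @ v.T
            crosses = np.linalg.norm(v[:, None, :] * 0 + np.cross(v[:, None, :], v[None, :, :]), axis=-1)
            return np.arctan2(crosses, dots)  # stable at small separations

        assert np.max(np.abs(pairwise_angles(axes) - pairwise_angles(out))) < 1e-9

    def test_antipodal_rejected(self):
        with pytest.raises(ad.DegenerateBaselineError):
            ad.remove_baseline(np.eye(3), [0, 0, 1.0], [0, 0, -1.0])


class TestAimingAngle:
    n_r = np.array([1.0, 0, 0])
    n_id = np.array([0.0, -1.0, 1.0]) / np.sqrt(2)

    def test_zero_at_ideal_axis(self):
        assert abs(ad.aiming_angle(self.n_id, self.n_r, self.n_id)) < 1e-12

    def test_plane_normal_gives_right_angle(self):
        normal = np.cross(self.n_r, self.n_id)
        normal /= np.linalg.norm(normal)
        assert abs(ad.aiming_angle(normal, self.n_r, self.n_id) - np.pi / 2) < 1e-12
        assert abs(ad.aiming_angle(-normal, self.n_r, self.n_id) + np.pi / 2) < 1e-12

    def test_bounded_on_fuzz(self, rng):
        for _ in range(2000):
            n_a = rng.standard_normal(3)
            n_a /= np.linalg.norm(n_a)
            angle = ad.aiming_angle(n_a, self.n_r, self.n_id)
            assert -np.pi / 2 <= angle <= np.pi / 2

    def test_antisymmetric_under_reflection(self, rng):
        """Mirroring n_a through the (n_r, n_id) plane flips the sign."""
        normal = np.cross(self.n_r, self.n_id)
        normal /= np.linalg.norm(normal)
        for _ in range(50):
            n_a = rng.standard_normal(3)
            n_a /= np.linalg.norm(n_a)
            mirrored = n_a - 2 * (n_a @ normal) * normal
            a1 = ad.aiming_angle(n_a, self.n_r, self.n_id)
            a2 = ad.aiming_angle(mirrored, self.n_r, self.n_id)
            assert abs(a1 + a2) < 1e-12

    def test_parallel_axes_rejected(self):
        with pytest.raises(ad.DegeneratePlaneError):
            ad.aiming_angle([0, 0, 1.0], [0, 0, 1.0], [0, 0, 1.0])


class TestStagePlan:
    def test_k3_blocks_match_protocol(self):
        plan = ad.make_stage_plan(3)
        assert list(plan.blocks["lateBL1"]) == [118, 119, 120]
        assert list(plan.blocks["lateBL2"]) == [178, 179, 180]
        assert list(plan.blocks["earlyTRN"]) == [181, 182, 183]
        assert list(plan.blocks["lateTRN"]) == [358, 359, 360]
        assert list(plan.blocks["earlyTFR"]) == [361, 362, 363]
        assert list(plan.blocks["lateTFR"]) == [418, 419, 420]

    def test_k1_single_trial(self):
        plan = ad.make_stage_plan(1)
        assert list(plan.blocks["lateBL1"]) == [120]

    def test_stage_average_identical_axes(self):
        plan = ad.make_stage_plan(3)
        results = {
            i: ad.AimingResult(axis=np.array([0.0, 0, 1.0]), peak_speed=3.0, peak_index=10, angle=0.1)
            for block in plan.blocks.values()
            for i in block
        }
        out = ad.stage_average(results, plan)
        np.testing.assert_allclose(out["lateTRN"].axis, [0, 0, 1])
        assert abs(out["lateTRN"].angle - 0.1) < 1e-12

    def test_missing_trials_reported(self):
        plan = ad.make_stage_plan(3)
        results = {
            i: ad.AimingResult(axis=np.array([0.0, 0, 1.0]), peak_speed=3.0, peak_index=10, angle=0.0)
            for block in plan.blocks.values()
            for i in block
        }
        del results[119]
        with pytest.raises(KeyError, match="119"):
            ad.stage_average(results, plan)


class TestCohortPipeline:
    def test_asymptote_recovered_in_stage_averages(self):
        """Cohort-averaged late-TRN aiming angle matches the 40-degree asymptote
        within 1 degree (k = 3; per-participant k-trial noise averages out)."""
        ideal = sg.ideal_axes_for("extrinsic")
        n_r = sg.measurement_perturbation_axis(ref.EXP2_O1)
        late_trn = []
        for p in range(8):
            learner = sg.LearnerSpec(group="extrinsic", seed=1000 + p, motor_noise_sd=2.0)
            trials = sg.simulate_cohort(learner, render_cursors=False)
            _, per_stage = ad.analyze_cohort(trials, ideal, n_r, k=3, seed=500 + p)
            late_trn.append(np.degrees(per_stage["lateTRN"].angle))
        asymptote = np.degrees(sg.LearnerSpec().asymptote)
        assert abs(abs(np.mean(late_trn)) - asymptote) < 1.0
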