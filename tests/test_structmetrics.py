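"""Cylinder fitting, kink classification, hydrogen-bond detection,
observable aggregation and odds ratios."""

import math

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from bridgemsm.features import FeatureTrajectory
from bridgemsm.msm import sample_observable_mcmc
from bridgemsm.structmetrics import (
    HBondCriterion,
    HingeMap,
    KinkHBondTable,
    aggregate_hinges,
    barrier_start_selection,
    detect_hbond,
    detect_hbond_array,
    fit_cylinder,
    kink_profile,
    odds_ratio,
    per_state_observable,
    tic_shift_histogram,
)
from bridgemsm.synthgen import HelixSpec, make_hbond_geometry, make_helix
from bridgemsm.tica import TICAModel

from conftest import model_from_T


class TestCylinderFit:
    def test_exact_cylinder_has_negligible_residual(self):
        t = np.linspace(0, 4 * np.pi, 20)
        pts = np.column_stack([5 * np.cos(t), 5 * np.sin(t), np.linspace(0, 10, 20)])
        fit = fit_cylinder(pts)
        assert fit.residual_rms < 1e-8
        assert fit.radius == pytest.approx(5.0, abs=1e-6)

    def test_helix_window_recovers_axis_and_radius(self):
        coords = make_helix(HelixSpec(n_residues=12), 0)[:6]
        fit = fit_cylinder(coords)
        angle = math.degrees(math.acos(abs(fit.axis_direction @ [0, 0, 1])))
        assert angle < 1.0
        assert abs(fit.radius - 2.3) < 0.05

    def test_axis_oriented_along_residue_order(self):
        coords = make_helix(HelixSpec(n_residues=12), 0)
        assert fit_cylinder(coords).axis_direction @ [0, 0, 1] > 0
        assert fit_cylinder(coords[::-1]).axis_direction @ [0, 0, 1] < 0

    def test_noise_robustness_of_axis(self):
        angles = []
        for seed in range(100):
            coords = make_helix(HelixSpec(n_residues=12, noise_sigma=0.2), seed)
            fit = fit_cylinder(coords[:6])
            angles.append(
                math.degrees(math.acos(np.clip(abs(fit.axis_direction @ [0, 0, 1]), 0, 1)))
            )
        assert np.median(angles) < 5.0

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.zeros(8), np.zeros(8), np.arange(8.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_cylinder(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6 points"):
            fit_cylinder(np.random.default_rng(0).random((5, 3)))


class TestKinkProfile:
    def test_noiseless_ideal_helix_is_straight(self):
        prof = kink_profile(make_helix(HelixSpec(n_residues=30), 0))
        assert prof.max_angle < 3.0
        assert prof.straight
        # support: n - 2*(window-1) positions
        assert len(prof.residues) == 30 - 2 * 5

    @pytest.mark.parametrize("angle,straight", [(20.0, True), (40.0, False)])
    def test_single_kink_round_trip_and_classification(self, angle, straight):
        coords = make_helix(
            HelixSpec(n_residues=30, kinks=[(15, angle, 60.0)]), 0
        )
        prof = kink_profile(coords, threshold=35.0)
        assert abs(prof.max_angle - angle) <= 2.0
        assert abs(prof.max_residue - 15) <= 1
        assert prof.straight is straight

    def test_rigid_motion_invariance(self):
        coords = make_helix(HelixSpec(n_residues=30, kinks=[(14, 30.0, 200.0)]), 0)
        base = kink_profile(coords)
        R = special_ortho_group.rvs(3, random_state=2)
        moved = coords @ R.T + np.array([10.0, -3.0, 7.0])
        prof = kink_profile(moved)
        # convergence-limited: the optimizer leaves ~1e-6 deg of axis error
        np.testing.assert_allclose(prof.kink_angles, base.kink_angles, atol=5e-6)

    def test_threshold_monotonicity_of_straight_fraction(self):
        rng = np.random.default_rng(3)
        profiles = [
            kink_profile(
                make_helix(
                    HelixSpec(
                        n_residues=30,
                        kinks=[(int(rng.integers(10, 20)), float(rng.uniform(10, 60)), 0.0)],
                        noise_sigma=0.05,
                    ),
                    seed,
                )
            )
            for seed in range(20)
        ]
        fractions = [
            np.mean([p.max_angle < th for p in profiles]) for th in (20, 35, 50, 70)
        ]
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_too_short_helix_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            kink_profile(make_helix(HelixSpec(n_residues=8), 0))


class TestHingeAggregation:
    hinge_map = HingeMap({"h14": (12, 15), "h18": (16, 19)})

    def test_straight_ensemble_has_zero_kink_frequencies(self):
        profiles = [
            kink_profile(make_helix(HelixSpec(n_residues=30), s)) for s in range(5)
        ]
        agg = aggregate_hinges(profiles, self.hinge_map)
        assert all(v == 0.0 for v in agg.residue_kink_frequency.values())
        assert all(v == 0.0 for v in agg.hinge_kink_frequency.values())

    def test_kinks_at_single_residue_localized(self):
        profiles = [
            kink_profile(
                make_helix(HelixSpec(n_residues=30, kinks=[(13, 45.0, 0.0)]), s)
            )
            for s in range(5)
        ]
        agg = aggregate_hinges(profiles, self.hinge_map)
        assert agg.hinge_kink_frequency["h14"] == 1.0
        assert agg.hinge_kink_frequency["h18"] == 0.0
        assert agg.residue_kink_frequency[13] == 1.0

    def test_histograms_integrate_to_one(self):
        profiles = [
            kink_profile(make_helix(HelixSpec(n_residues=30), s)) for s in range(3)
        ]
        agg = aggregate_hinges(profiles, self.hinge_map)
        for density, edges in agg.hinge_histograms.values():
            assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-12)

    def test_overlapping_hinges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            HingeMap({"a": (5, 10), "b": (9, 12)})

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_hinges([], self.hinge_map)


class TestHBond:
    criterion = HBondCriterion()

    @pytest.mark.parametrize(
        "d,theta,expected",
        [
            (0.34, 29.0, True),  # interior point: both thresholds satisfied
            (0.36, 10.0, False),  # fails on distance
            (0.30, 31.0, False),  # fails on angle
            (0.35, 0.0, False),  # strict boundary convention
            (0.30, 0.0, True),
        ],
    )
    def test_criterion_truth_table(self, d, theta, expected):
        donor, hydrogen, acceptor = make_hbond_geometry(d, theta)
        assert detect_hbond(donor, hydrogen, acceptor, self.criterion) is expected

    def test_rigid_motion_invariance(self):
        donor, hydrogen, acceptor = make_hbond_geometry(0.34, 20.0)
        R = special_ortho_group.rvs(3, random_state=4)
        shift = np.array([1.0, 2.0, 3.0])
        assert detect_hbond(
            R @ donor + shift, R @ hydrogen + shift, R @ acceptor + shift,
            self.criterion,
        )

    def test_uniform_scaling_breaks_distance_not_angle(self):
        donor, hydrogen, acceptor = make_hbond_geometry(0.30, 10.0)
        assert detect_hbond(donor, hydrogen, acceptor, self.criterion)
        # scaling preserves the angle but pushes the distance over threshold
        assert not detect_hbond(
            1.5 * donor, 1.5 * hydrogen, 1.5 * acceptor, self.criterion
        )

    def test_zero_length_dh_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            detect_hbond(np.zeros(3), np.zeros(3), np.array([0.3, 0, 0]))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(5)
        triples = [
            make_hbond_geometry(float(d), float(t))
            for d, t in zip(rng.uniform(0.2, 0.5, 30), rng.uniform(0, 80, 30))
        ]
        donors, hydrogens, acceptors = map(np.array, zip(*triples))
        flags = detect_hbond_array(donors, hydrogens, acceptors, self.criterion)
        scalar = [detect_hbond(*tr, self.criterion) for tr in triples]
        np.testing.assert_array_equal(flags, scalar)


class TestPerStateObservable:
    def test_constant_observable(self):
        dtrajs = [np.array([0, 1, 2, 0, 1])]
        means, counts = per_state_observable(dtrajs, [np.ones(5)])
        np.testing.assert_allclose(means, 1.0)
        np.testing.assert_array_equal(counts, [2, 2, 1])

    def test_planted_per_state_fraction(self):
        dtrajs = [np.array([0] * 10 + [1] * 10)]
        values = [np.array([1.0] * 3 + [0.0] * 7 + [1.0] * 10)]
        means, _ = per_state_observable(dtrajs, values)
        assert means[0] == pytest.approx(0.30)
        assert means[1] == pytest.approx(1.0)

    def test_msm_weighted_macrostate_percentage(self, two_state_T):
        model = model_from_T(two_state_T)
        res = sample_observable_mcmc(
            model, np.array([0.9, 0.3]), n_chains=10, n_steps=30_000, seed=0
        )
        expected = 0.9 * 2 / 3 + 0.3 * 1 / 3
        se = res["sd"] / math.sqrt(10)
        assert abs(res["mean"] - expected) < 3 * se + 1e-3

    def test_empty_state_flagged(self):
        with pytest.warns(UserWarning, match="no frames"):
            means, _ = per_state_observable(
                [np.array([0, 0, 2])], [np.ones(3)], n_states=3
            )
        assert np.isnan(means[1])

    def test_misaligned_values_rejected(self):
        with pytest.raises(ValueError, match="1:1"):
            per_state_observable([np.array([0, 1])], [np.ones(3)])


class TestOddsRatio:
    def test_direct_arithmetic(self):
        assert odds_ratio(KinkHBondTable(20, 10, 30, 60)) == pytest.approx(4.0)

    def test_null_case(self):
        assert odds_ratio(KinkHBondTable(10, 20, 5, 10)) == pytest.approx(1.0)

    def test_label_swap_inverts(self):
        t = KinkHBondTable(20, 10, 30, 60)
        swapped = KinkHBondTable(t.NB_s, t.NB_k, t.B_s, t.B_k)
        assert odds_ratio(swapped) == pytest.approx(1 / odds_ratio(t))

    def test_zero_cell_named_in_error(self):
        with pytest.raises(ZeroDivisionError, match="NB_k"):
            odds_ratio(KinkHBondTable(1, 1, 1, 0))

    def test_independent_sampling_centers_at_one(self):
        rng = np.random.default_rng(6)
        log_ors = []
        for _ in range(1000):
            kink = rng.random(400) < 0.4
            bond = rng.random(400) < 0.3
            table = KinkHBondTable(
                float((bond & ~kink).sum()) + 0.5,
                float((bond & kink).sum()) + 0.5,
                float((~bond & ~kink).sum()) + 0.5,
                float((~bond & kink).sum()) + 0.5,
            )
            log_ors.append(math.log(odds_ratio(table)))
        se = np.std(log_ors) / math.sqrt(len(log_ors))
        assert abs(np.mean(log_ors)) < 3 * se + 0.01


class TestTicShiftHistogram:
    @staticmethod
    def identity_model(d=2):
        return TICAModel(
            mean=np.zeros(d), C0=np.eye(d), Ctau=np.eye(d), lag=1.0,
            lag_frames=1, frame_interval=1.0, eigenvalues=np.ones(d),
            components=np.eye(d), epsilon=0.0,
            feature_labels=[f"f{i}" for i in range(d)],
        )

    def test_constant_trajectories_give_delta_at_zero(self):
        model = self.identity_model()
        trajs = [FeatureTrajectory(np.ones((10, 2)), 1.0, model.feature_labels)]
        hist, edges = tic_shift_histogram(model, trajs, component=0, bins=5)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert centers[np.argmax(hist)] == pytest.approx(0.0, abs=np.diff(edges)[0])

    def test_drift_recovered_in_mean(self):
        model = self.identity_model()
        drift = np.linspace(0, 2.0, 50)
        vals = np.column_stack([drift, np.zeros(50)])
        trajs = [FeatureTrajectory(vals, 1.0, model.feature_labels)]
        hist, edges = tic_shift_histogram(model, trajs, component=0, bins=20)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean = np.sum(hist * centers * np.diff(edges))
        assert mean == pytest.approx(drift.mean(), abs=0.1)

    def test_unit_area(self):
        model = self.identity_model()
        rng = np.random.default_rng(7)
        trajs = [
            FeatureTrajectory(rng.random((40, 2)), 1.0, model.feature_labels)
            for _ in range(3)
        ]
        hist, edges = tic_shift_histogram(model, trajs, component=1)
        assert np.sum(hist * np.diff(edges)) == pytest.approx(1.0, abs=1e-12)


class TestBarrierStartSelection:
    def test_boundary_microstates_selected_first(self):
        from bridgemsm.kinetics import spectral_lump
        from test_kinetics import two_block_T

        model = model_from_T(two_block_T())
        macro = spectral_lump(model, 2, seed=0)
        picks = barrier_start_selection(model, macro, 0, 1, n=1)
        # microstates 0 and 2 carry the 0.01 inter-block coupling... the
        # coupling pattern of two_block_T links (0<->2) and (1<->3)
        for side, sel in picks.items():
            members = macro.members(side)
            other = macro.members(1 - side)
            scores = model.T[np.ix_(members, other)].sum(axis=1)
            assert model.T[np.ix_(sel, other)].sum(axis=1).min() >= scores.max() - 1e-12

    def test_oversized_request_returns_all_with_warning(self):
        from bridgemsm.kinetics import spectral_lump
        from test_kinetics import two_block_T

        model = model_from_T(two_block_T())
        macro = spectral_lump(model, 2, seed=0)
        with pytest.warns(UserWarning, match="members"):
            picks = barrier_start_selection(model, macro, 0, 1, n=5)
        assert all(len(sel) == 2 for sel in picks.values())

    def test_identical_macrostates_rejected(self):
        from bridgemsm.kinetics import spectral_lump
        from test_kinetics import two_block_T

        model = model_from_T(two_block_T())
        macro = spectral_lump(model, 2, seed=0)
        with pytest.raises(ValueError, match="distinct"):
            barrier_start_selection(model, macro, 1, 1)
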