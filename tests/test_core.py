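"""R² scoring, aggregation, ordination, cluster validation, lifestyles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sisca.chem import RIAGrid, composition_from_peptide, reference_pattern_set
from sisca.core import (
    ConfidenceEllipse,
    LifestyleThresholds,
    MAGTrajectory,
    RIAProfile,
    aggregate_profiles,
    classify_lifestyle,
    ellipses_overlap,
    ordinate,
    overlap_verdicts,
    r_squared,
    ria_profile,
    validate_clusters,
    ward_clusters,
)


class TestRSquared:
    def test_self_comparison_is_exactly_one(self):
        v = [0.2, 0.5, 0.3]
        assert r_squared(v, v) == 1.0

    def test_disjoint_vectors(self):
        assert r_squared([0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5]) == pytest.approx(-3.0)

    def test_two_point_case(self):
        assert r_squared([1, 0], [0.5, 0.5]) == pytest.approx(0.0)

    def test_zero_measured_rejected(self):
        with pytest.raises(ValueError):
            r_squared([0.0, 0.0], [0.5, 0.5])

    def test_unequal_lengths_padded_with_zeros(self):
        assert r_squared([0.5, 0.5], [0.5, 0.5, 0.0]) == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=12),
           st.randoms(use_true_random=False))
    def test_reordering_invariance(self, values, rand):
        """Permuting both vectors identically leaves R² unchanged."""
        m = np.array(values)
        p = np.roll(m, 1) + 0.05
        perm = list(range(len(m)))
        rand.shuffle(perm)
        assert r_squared(m[perm], p[perm]) == pytest.approx(
            r_squared(m, p), rel=1e-9
        )


class TestProfiles:
    def test_profile_length_matches_grid(self):
        comp = composition_from_peptide("PEPTIDEK")
        refs = reference_pattern_set(comp, 2)
        prof = ria_profile(refs[4], refs)
        assert len(prof.r2) == 21

    def test_noise_free_argmax_at_truth(self):
        comp = composition_from_peptide("GLSDGEWQQVLNVWGK")
        grid = RIAGrid.default()
        refs = reference_pattern_set(comp, 2, grid)
        idx_65 = list(grid.values).index(0.65)
        prof = ria_profile(refs[idx_65], refs, grid)
        assert grid.values[int(np.argmax(prof.r2))] == 0.65
        prof0 = ria_profile(refs[0], refs, grid)
        assert int(np.argmax(prof0.r2)) == 0

    def test_length_mismatch_rejected(self):
        comp = composition_from_peptide("GG")
        refs = reference_pattern_set(comp)[:-1]
        with pytest.raises(ValueError):
            ria_profile(refs[0], refs)


class TestAggregation:
    def grid(self):
        return RIAGrid.default(0.5)

    def profile(self, r2, owner="M", tp="T1"):
        return RIAProfile(owner, tp, np.asarray(r2, dtype=float), self.grid())

    def test_identical_profiles_unchanged(self):
        p = self.profile([0.1, 0.2, 0.3])
        (out,) = aggregate_profiles([p, p])
        assert np.allclose(out.r2, p.r2)

    def test_elementwise_mean(self):
        out = aggregate_profiles(
            [self.profile([1, 0, 0]), self.profile([0, 1, 0])]
        )
        assert np.allclose(out[0].r2, [0.5, 0.5, 0.0])

    def test_group_count(self):
        profiles = [
            self.profile([0.1, 0.2, 0.3], owner=f"M{i}", tp=tp)
            for i in range(3)
            for tp in ("T1", "T2", "T3")
            for _ in range(5)
        ]
        assert len(aggregate_profiles(profiles)) == 9

    def test_permutation_invariance(self):
        profiles = [self.profile([x, 1 - x, 0.0]) for x in (0.2, 0.4, 0.9)]
        a = aggregate_profiles(profiles)
        b = aggregate_profiles(profiles[::-1])
        assert np.allclose(a[0].r2, b[0].r2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_profiles([])


def make_trajectory(mag, vectors, grid=None):
    grid = grid or RIAGrid.default()
    tps = tuple(f"T{i + 1}" for i in range(len(vectors)))
    profiles = tuple(
        RIAProfile(mag, tp, np.asarray(v, dtype=float), grid)
        for tp, v in zip(tps, vectors)
    )
    return MAGTrajectory(mag_id=mag, timepoints=tps, profiles=profiles)


class TestOrdination:
    def base_vectors(self, shift=0.0):
        v = np.zeros(21)
        v[5] = 0.8 + shift
        return [v, v, v]

    def test_identical_trajectories_have_identical_scores(self):
        t1 = make_trajectory("A", self.base_vectors())
        t2 = make_trajectory("B", self.base_vectors())
        t3 = make_trajectory("C", self.base_vectors(shift=0.1))
        result = ordinate([t1, t2, t3])
        d = np.linalg.norm(result.scores[0] - result.scores[1])
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_single_coordinate_difference_loads_pc1_fully(self):
        trajectories = [
            make_trajectory(m, self.base_vectors(shift=s))
            for m, s in (("A", 0.0), ("B", 0.0), ("C", 0.2), ("D", 0.2))
        ]
        result = ordinate(trajectories)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_score_matrix_dimensions(self):
        rng = np.random.default_rng(0)
        trajectories = [
            make_trajectory(f"M{i}", list(rng.uniform(size=(3, 21))))
            for i in range(31)
        ]
        result = ordinate(trajectories)
        assert result.scores.shape == (31, min(31 - 1, 63))

    def test_isometry_on_retained_space(self):
        """Score distances equal centered-feature distances."""
        rng = np.random.default_rng(1)
        trajectories = [
            make_trajectory(f"M{i}", list(rng.uniform(size=(2, 21))))
            for i in range(6)
        ]
        result = ordinate(trajectories)
        X = np.stack([t.feature_vector() for t in trajectories])
        Xc = X - X.mean(axis=0)
        for i in range(6):
            for j in range(i):
                assert np.linalg.norm(
                    result.scores[i] - result.scores[j]
                ) == pytest.approx(np.linalg.norm(Xc[i] - Xc[j]), abs=1e-9)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(2)
        trajectories = [
            make_trajectory(f"M{i}", list(rng.uniform(size=(2, 21))))
            for i in range(5)
        ]
        a = ordinate(trajectories)
        b = ordinate(trajectories)
        assert np.allclose(a.scores, b.scores)
        for row in a.loadings:
            assert row[int(np.argmax(np.abs(row)))] > 0

    def test_missing_timepoint_rejected(self):
        t1 = make_trajectory("A", self.base_vectors())
        t2 = make_trajectory("B", self.base_vectors()[:2])
        t3 = make_trajectory("C", self.base_vectors())
        with pytest.raises(ValueError, match="B"):
            ordinate([t1, t2, t3])

    def test_per_mag_time_layout(self):
        trajectories = [
            make_trajectory(m, self.base_vectors()) for m in ("A", "B", "C")
        ]
        result = ordinate(trajectories, layout="per-mag-time")
        assert len(result.mag_ids) == 9  # 3 MAGs x 3 time points


class TestClusterValidation:
    def scattered_result(self, centers, n_per=5, spread=0.05, seed=0):
        rng = np.random.default_rng(seed)
        vectors, labels = [], {}
        mags = []
        for ci, c in enumerate(centers):
            for j in range(n_per):
                v = np.zeros(21)
                v[2 * ci] = c + rng.normal(0, spread)
                v[2 * ci + 1] = rng.normal(0, spread)
                mag = f"C{ci}_M{j}"
                mags.append(mag)
                labels[mag] = f"cluster{ci}"
                vectors.append([v])
        trajectories = [make_trajectory(m, v) for m, v in zip(mags, vectors)]
        result = ordinate(trajectories)
        return validate_clusters(result, labels), labels

    def test_coincident_clusters_overlap(self):
        a = ConfidenceEllipse(np.zeros(2), np.eye(2) * 0.1, 5.99)
        assert ellipses_overlap(a, a)

    def test_distant_tight_clusters_do_not_overlap(self):
        a = ConfidenceEllipse(np.zeros(2), np.eye(2) * 1e-4, 5.99)
        b = ConfidenceEllipse(np.array([10.0, 0.0]), np.eye(2) * 1e-4, 5.99)
        assert not ellipses_overlap(a, b)

    def test_separated_groups_validate_as_distinct(self):
        result, labels = self.scattered_result([1.0, 3.0, 6.0], spread=0.02)
        verdicts = overlap_verdicts(result)
        assert verdicts and not any(verdicts.values())

    def test_singleton_cluster_has_no_ellipse(self):
        result, labels = self.scattered_result([1.0, 3.0], n_per=2)
        solo = {m: ("solo" if m == "C0_M0" else labels[m]) for m in labels}
        validated = validate_clusters(result, solo)
        assert "solo" not in validated.ellipses
        assert "cluster1" in validated.ellipses

    def test_unlabeled_mag_rejected(self):
        result, labels = self.scattered_result([1.0, 3.0])
        labels = dict(labels)
        labels.popitem()
        with pytest.raises(ValueError):
            validate_clusters(result, labels)

    def test_ward_helper_recovers_separated_groups(self):
        result, labels = self.scattered_result([1.0, 4.0, 8.0], spread=0.02)
        assignment = ward_clusters(result, k=3)
        # same partition as the true labels, up to cluster naming
        by_true: dict = {}
        for mag, true in labels.items():
            by_true.setdefault(true, set()).add(assignment[mag])
        assert all(len(v) == 1 for v in by_true.values())


class TestLifestyles:
    @pytest.mark.parametrize(
        "ria, expected",
        [
            ((0.95, 0.95, 0.95), "strict_autotroph"),
            ((0.65, 0.91, 0.91), "switching_mixotroph"),
            ((0.18, 0.53, 0.76), "crossfeeding_incorporator"),
            ((0.06, 0.06, 0.06), "unlabeled_heterotroph"),
        ],
    )
    def test_archetype_trajectories(self, ria, expected):
        label, rule = classify_lifestyle(ria)
        assert label == expected

    def test_grid_snapped_mixotroph_still_called(self):
        """A true 0.91 snapped to the 0.90 grid point keeps its label."""
        assert classify_lifestyle((0.65, 0.90, 0.90))[0] == "switching_mixotroph"

    def test_custom_thresholds(self):
        strict = LifestyleThresholds(high=0.97)
        assert classify_lifestyle((0.95, 0.95, 0.95), strict)[0] != "strict_autotroph"

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            classify_lifestyle((0.95,))

    def test_every_call_reports_a_rule(self):
        label, rule = classify_lifestyle((0.5, 0.3, 0.8))
        assert rule
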