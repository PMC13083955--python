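"""Tests for the groove-occupancy classifier and excess profiles.

The classifier is checked against an independent, deliberately naive
re-implementation of the three geometric tests (explicit loops, its own
PCA via full eigendecomposition of the scatter matrix).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import stigroove as sg
from stigroove.cg_model import ValidationError
from stigroove.groove_analysis import GrooveDefinition, groove_center



def brute_force_classify(frame, interior, exterior, candidate, threshold=1.0):
    """Naive reference implementation of the three groove tests."""
    pts_in = [frame[i] for i in interior]
    pts_ex = [frame[i] for i in exterior]
    c = frame[candidate]

    center = sum(pts_in) / len(pts_in)
    r_max = max(np.sqrt(((p - center) ** 2).sum()) for p in pts_in)
    if not np.sqrt(((c - center) ** 2).sum()) < r_max:
        return False

    d_in = min(np.sqrt(((c - p) ** 2).sum()) for p in pts_in)
    d_ex = min(np.sqrt(((c - p) ** 2).sum()) for p in pts_ex)
    if not d_in < d_ex:
        return False

    scatter = np.zeros((3, 3))
    for p in pts_in:
        rel = p - center
        scatter += np.outer(rel, rel)
    eigval, eigvec = np.linalg.eig(scatter)
    axis = eigvec[:, np.argmax(eigval)]
    axis = axis / np.sqrt((axis ** 2).sum())

    def perp(p):
        rel = p - center
        return np.sqrt(((rel - (rel @ axis) * axis) ** 2).sum())

    return perp(c) <= threshold * max(perp(p) for p in pts_in)


class TestGrooveCenter:
    def test_symmetric_pair(self):
        frame = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert np.allclose(groove_center(frame, [0, 1]), 0.0)

    def test_single_interior_bead(self):
        frame = np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
        assert np.allclose(groove_center(frame, [0]), [1, 2, 3])

    def test_empty_interior_rejected(self):
        with pytest.raises(ValidationError):
            groove_center(np.zeros((3, 3)), [])

    def test_matches_independent_average(self, rng):
        frame = rng.normal(size=(20, 3))
        idx = [2, 5, 7, 11]
        expected = sum(frame[i] for i in idx) / 4
        assert np.allclose(groove_center(frame, idx), expected)


class TestClassifyFrame:
    def test_candidate_at_center_is_occupied(self):
        system = sg.make_toy_groove_system(8, 8, 6.0, seed=1)
        frame = np.vstack([system.frames.xyz[0], system.groove_centroid()])
        flags = sg.classify_frame(frame, system.groove, [16])
        assert flags[0]

    def test_candidate_far_outside_not_occupied(self):
        system = sg.make_toy_groove_system(8, 8, 6.0, seed=1)
        frame = np.vstack([system.frames.xyz[0], system.outside_position()])
        flags = sg.classify_frame(frame, system.groove, [16])
        assert not flags[0]

    def test_too_few_interior_residues_rejected(self):
        with pytest.raises(ValidationError):
            GrooveDefinition(interior=np.arange(3), exterior=np.arange(3, 6))

    def test_matches_brute_force_oracle(self):
        """Vectorised classifier ≡ naive loop oracle on 10^4 random placements."""
        rng = np.random.default_rng(123)
        mismatches = 0
        n_cases = 0
        for trial in range(10):
            system = sg.make_toy_groove_system(
                int(rng.integers(4, 12)), int(rng.integers(1, 12)),
                float(rng.uniform(2.0, 8.0)), seed=int(rng.integers(1e6)))
            base = system.frames.xyz[0]
            scale = 2.5 * system.furthest_interior_radius()
            cands = system.groove_centroid() + rng.uniform(
                -scale, scale, size=(1000, 3))
            frame = np.vstack([base, cands])
            idx = np.arange(len(base), len(base) + 1000)
            got = sg.classify_frame(frame, system.groove, idx)
            for k in range(1000):
                expected = brute_force_classify(
                    frame, system.groove.interior, system.groove.exterior, idx[k])
                mismatches += got[k] != expected
                n_cases += 1
        assert n_cases == 10000
        assert mismatches == 0

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        system = sg.make_toy_groove_system(8, 6, 5.0, seed=seed)
        cands = system.groove_centroid() + rng.uniform(-10, 10, size=(20, 3))
        frame = np.vstack([system.frames.xyz[0], cands])
        idx = np.arange(14, 34)
        before = sg.classify_frame(frame, system.groove, idx)
        rot = Rotation.random(random_state=seed).as_matrix()
        shift = rng.uniform(-50, 50, size=3)
        after = sg.classify_frame(frame @ rot.T + shift, system.groove, idx)
        assert np.array_equal(before, after)


class TestOccupancyProfile:
    def test_planted_full_occupancy(self):
        system = sg.make_toy_groove_system(8, 8, 6.0, seed=2)
        planted = sg.make_planted_occupancy_trajectory(system, [16, 17], 1.0, 100, seed=3)
        prof = sg.occupancy_profile([planted.frames], planted.groove,
                                    planted.probe_indices)
        assert np.all(prof.probability == 1.0)

    def test_planted_zero_occupancy(self):
        system = sg.make_toy_groove_system(8, 8, 6.0, seed=2)
        planted = sg.make_planted_occupancy_trajectory(system, [16], 0.0, 100, seed=3)
        prof = sg.occupancy_profile([planted.frames], planted.groove,
                                    planted.probe_indices)
        assert np.all(prof.probability == 0.0)

    @pytest.mark.parametrize("target", [0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0])
    def test_planted_recovery_within_binomial_error(self, target):
        n_frames = 2000
        system = sg.make_toy_groove_system(8, 8, 6.0, seed=4)
        planted = sg.make_planted_occupancy_trajectory(
            system, [16], target, n_frames, seed=7)
        prof = sg.occupancy_profile([planted.frames], planted.groove,
                                    planted.probe_indices)
        se = np.sqrt(target * (1 - target) / n_frames)
        assert abs(prof.probability[0] - target) <= 3 * se + 1e-12

    def test_profile_matches_planted_truth_exactly(self):
        system = sg.make_toy_groove_system(10, 6, 4.0, seed=5)
        planted = sg.make_planted_occupancy_trajectory(
            system, [16, 17, 18], 0.3, 500, seed=8)
        prof = sg.occupancy_profile([planted.frames], planted.groove,
                                    planted.probe_indices)
        assert np.allclose(prof.probability, planted.truth.mean(axis=1))

    def test_two_replicas_mean_and_spread(self):
        system = sg.make_toy_groove_system(8, 8, 6.0, seed=6)
        a = sg.make_planted_occupancy_trajectory(system, [16], 0.2, 1000, seed=1)
        b = sg.make_planted_occupancy_trajectory(system, [16], 0.4, 1000, seed=2)
        prof = sg.occupancy_profile([a.frames, b.frames], system.groove, [16])
        pa, pb = a.truth.mean(), b.truth.mean()
        assert prof.probability[0] == pytest.approx((pa + pb) / 2)
        assert prof.spread[0] == pytest.approx(abs(pa - pb) / 2)

    def test_empty_trajectory_rejected(self):
        system = sg.make_toy_groove_system(8, 8, 6.0, seed=2)
        with pytest.raises(ValidationError):
            sg.occupancy_profile([], system.groove, [16])


class TestExcessProfile:
    @staticmethod
    def _profile(probs, residues=None):
        probs = np.asarray(probs, dtype=float)
        residues = np.arange(len(probs)) if residues is None else np.asarray(residues)
        return sg.OccupancyProfile(residues=residues, probability=probs,
                                   spread=np.zeros_like(probs),
                                   n_frames=100, n_replicas=1)

    def test_fold_enrichment_arithmetic(self):
        ex = sg.excess_occupancy(self._profile([0.30]), self._profile([0.002]))
        assert ex.enrichment[0] == pytest.approx(150.0)

    def test_identity_everywhere(self):
        p = self._profile([0.1, 0.5, 0.9])
        ex = sg.excess_occupancy(p, p)
        assert np.allclose(ex.enrichment, 1.0)

    def test_zero_over_zero_flagged_undefined(self):
        ex = sg.excess_occupancy(self._profile([0.0, 0.2]), self._profile([0.0, 0.1]))
        assert ex.undefined[0] and not ex.undefined[1]
        assert np.isnan(ex.enrichment[0])

    def test_positive_over_zero_flagged_infinite(self):
        ex = sg.excess_occupancy(self._profile([0.2]), self._profile([0.0]))
        assert ex.infinite[0] and np.isinf(ex.enrichment[0])

    def test_mismatched_residues_rejected(self):
        with pytest.raises(ValidationError):
            sg.excess_occupancy(self._profile([0.1], [0]), self._profile([0.1], [1]))

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_self_ratio_is_one_where_positive(self, probs):
        p = self._profile(probs)
        ex = sg.excess_occupancy(p, p)
        assert np.allclose(ex.enrichment, 1.0)


class TestRegionEnrichment:
    @staticmethod
    def _excess(values, undefined=None):
        values = np.asarray(values, dtype=float)
        n = len(values)
        undef = np.zeros(n, bool) if undefined is None else np.asarray(undefined)
        return sg.ExcessProfile(residues=np.arange(n), enrichment=values,
                                undefined=undef, infinite=np.zeros(n, bool))

    def test_uniform_region(self):
        out = sg.region_enrichment(self._excess([150.0] * 10), {"r": (1, 10)})
        assert out["r"] == pytest.approx(150.0)

    def test_half_and_half(self):
        out = sg.region_enrichment(self._excess([100.0] * 5 + [200.0] * 5),
                                   {"r": (1, 10)})
        assert out["r"] == pytest.approx(150.0)

    def test_undefined_residues_excluded(self):
        out = sg.region_enrichment(
            self._excess([100.0, np.nan, 200.0], undefined=[False, True, False]),
            {"r": (1, 3)})
        assert out["r"] == pytest.approx(150.0)

    def test_span_outside_profile_rejected(self):
        with pytest.raises(ValidationError):
            sg.region_enrichment(self._excess([1.0, 1.0]), {"r": (10, 12)})

    def test_two_population_profile(self, rng):
        lo = rng.uniform(40, 60, size=10)
        hi = rng.uniform(140, 160, size=10)
        ex = self._excess(np.concatenate([lo, hi]))
        out = sg.region_enrichment(ex, {"lo": (1, 10), "hi": (11, 20)})
        assert out["lo"] == pytest.approx(lo.mean())
        assert out["hi"] == pytest.approx(hi.mean())


def test_sticky_segment_enriched_over_excluded_volume(
        toy_chain, trajs_interacting, trajs_ev):
    """The aromatic segment occupies the toy groove more than sterics predict."""
    probe = np.arange(toy_chain.sticky_span[0] - 1, toy_chain.sticky_span[1])
    occ = sg.occupancy_profile(trajs_interacting, toy_chain.groove, probe)
    occ_ev = sg.occupancy_profile(trajs_ev, toy_chain.groove, probe)
    assert occ.probability.mean() > occ_ev.probability.mean()
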