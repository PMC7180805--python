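"""Gaze binning, fixation maps, GIW conservation, reconstruction identity."""

import numpy as np
import pytest

from gazefusion import gaze


def make_recording(samples):
    return gaze.GazeRecording("s00", "img", np.asarray(samples, dtype=float))


class TestBinning:
    def test_single_bin_degenerate(self):
        rec = make_recording([[1, 1, 0.0, 0.5], [2, 2, 0.5, 0.5]])
        bins = gaze.bin_gaze_to_frames(rec, 1)
        assert len(bins) == 1 and len(bins[0]) == 2

    def test_midpoint_assignment(self):
        # midpoints at 0.1 and 0.9 over span [0, 1] with d4=2
        rec = make_recording([[1, 1, 0.0, 0.2], [2, 2, 0.8, 0.2]])
        bins = gaze.bin_gaze_to_frames(rec, 2)
        assert len(bins[0]) == 1 and bins[0][0][0] == 1
        assert len(bins[1]) == 1 and bins[1][0][0] == 2

    def test_boundary_goes_to_later_bin(self):
        # span [0, 1]; the middle sample's midpoint sits exactly at 0.5
        rec = make_recording([[0, 0, 0.0, 0.1], [1, 1, 0.45, 0.1],
                              [2, 2, 0.9, 0.1]])
        bins = gaze.bin_gaze_to_frames(rec, 2)
        assert [row[0] for row in bins[1]] == [1, 2]

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            gaze.GazeRecording("s", "i", np.empty((0, 4)))

    def test_skip_initial_interval(self):
        rec = make_recording([[1, 1, 0.0, 0.2], [2, 2, 0.8, 0.2]])
        bins = gaze.bin_gaze_to_frames(rec, 2, skip_initial_s=0.5)
        assert sum(len(b) for b in bins) == 1


class TestFixationMaps:
    def test_empty_frame_is_constant_epsilon(self):
        fix = gaze.build_fixation_maps([np.empty((0, 4))], (8, 8), sigma=1.0,
                                       epsilon=1e-6)
        assert np.allclose(fix.maps[0], 1e-6)

    def test_single_vote_mass_conserved(self):
        # unit-duration vote; reflect padding conserves total mass
        samples = np.array([[3.0, 4.0, 0.0, 1.0]])
        fix = gaze.build_fixation_maps([samples], (9, 9), sigma=0.5,
                                       epsilon=1e-8)
        assert np.unravel_index(fix.maps[0].argmax(), (9, 9)) == (4, 3)
        assert fix.maps[0].sum() == pytest.approx(1.0 + 1e-8 * 81, rel=1e-10)

    def test_identical_votes_identical_maps(self):
        samples = np.array([[2.0, 2.0, 0.0, 0.3], [5.0, 1.0, 0.3, 0.2]])
        fix = gaze.build_fixation_maps([samples, samples.copy()], (8, 8),
                                       sigma=1.0)
        assert np.array_equal(fix.maps[0], fix.maps[1])

    def test_invalid_sigma_epsilon(self):
        with pytest.raises(ValueError):
            gaze.build_fixation_maps([np.empty((0, 4))], (4, 4), sigma=0.0)
        with pytest.raises(ValueError):
            gaze.build_fixation_maps([np.empty((0, 4))], (4, 4), sigma=1.0,
                                     epsilon=0.0)


class TestGIW:
    def test_uniform_attention_gives_constant_two(self):
        maps = np.full((4, 5, 5), 0.7)
        giw = gaze.compute_giw(gaze.FixationMapStack(maps, 1.0, 1e-6))
        assert np.allclose(giw.weights, 2.0)

    def test_hand_example(self):
        maps = np.array([[[2.0, 1.0]], [[2.0, 3.0]]])  # d4=2, 1x2 maps
        giw = gaze.compute_giw(gaze.FixationMapStack(maps, 1.0, 1e-6))
        assert np.allclose(giw.weights[0], [[2.0, 1.5]])
        assert np.allclose(giw.weights[1], [[2.0, 2.5]])
        assert np.allclose(giw.weights.sum(axis=0), 4.0)

    def test_scale_invariance(self, rng):
        maps = rng.uniform(0.1, 2.0, size=(3, 6, 6))
        w1 = gaze.compute_giw(gaze.FixationMapStack(maps, 1.0, 1e-6)).weights
        w2 = gaze.compute_giw(gaze.FixationMapStack(7.3 * maps, 1.0, 1e-6)).weights
        assert np.allclose(w1, w2, atol=1e-12)

    @pytest.mark.parametrize("d4", [1, 2, 10])
    def test_per_pixel_sum_conservation(self, d4, rng):
        for _ in range(20):
            maps = rng.uniform(1e-6, 1.0, size=(d4, 7, 5))
            giw = gaze.compute_giw(gaze.FixationMapStack(maps, 1.0, 1e-6))
            assert np.abs(giw.weights.sum(axis=0) - 2 * d4).max() < 1e-10


class TestRepresentation:
    def test_uniform_attention_doubles_image(self, rng):
        img = rng.uniform(size=(6, 6, 3))
        maps = np.full((4, 6, 6), 0.3)
        giw = gaze.compute_giw(gaze.FixationMapStack(maps, 1.0, 1e-6))
        rep = gaze.build_representation(img, giw)
        for f in range(4):
            assert np.allclose(rep.tensor[:, :, :, f], 2.0 * img)
        assert np.allclose(gaze.reconstruct_image(rep), img, atol=1e-12)

    def test_zero_image(self):
        maps = np.full((2, 4, 4), 1.0)
        giw = gaze.compute_giw(gaze.FixationMapStack(maps, 1.0, 1e-6))
        rep = gaze.build_representation(np.zeros((4, 4, 3)), giw)
        assert not rep.tensor.any()

    def test_reconstruction_identity_random(self, rng):
        for _ in range(10):
            img = rng.uniform(size=(8, 8, 3))
            maps = rng.uniform(1e-6, 1.0, size=(5, 8, 8))
            giw = gaze.compute_giw(gaze.FixationMapStack(maps, 1.0, 1e-6))
            rep = gaze.build_representation(img, giw)
            assert np.abs(gaze.reconstruct_image(rep) - img).max() < 1e-10

    def test_d4_one_reconstruction_is_half_frame(self, rng):
        img = rng.uniform(size=(4, 4, 3))
        maps = rng.uniform(0.5, 1.0, size=(1, 4, 4))
        giw = gaze.compute_giw(gaze.FixationMapStack(maps, 1.0, 1e-6))
        rep = gaze.build_representation(img, giw)
        assert np.allclose(gaze.reconstruct_image(rep),
                           rep.tensor[:, :, :, 0] / 2.0)

    def test_shape_mismatch(self, rng):
        maps = np.full((2, 4, 4), 1.0)
        giw = gaze.compute_giw(gaze.FixationMapStack(maps, 1.0, 1e-6))
        with pytest.raises(ValueError):
            gaze.build_representation(rng.uniform(size=(5, 5, 3)), giw)


class TestIO:
    def test_gaze_csv_roundtrip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({
            "subject_id": ["a", "a", "b"],
            "image_id": ["i1", "i1", "i1"],
            "x": [1.0, 2.0, 3.0],
            "y": [4.0, 5.0, 6.0],
            "onset_s": [0.0, 0.1, 0.0],
            "duration_s": [0.1, 0.1, 0.2],
        })
        path = tmp_path / "gaze.csv"
        df.to_csv(path, index=False)
        recs = gaze.read_gaze_csv(path)
        assert {(r.subject_id, r.image_id) for r in recs} == {("a", "i1"), ("b", "i1")}
        a = next(r for r in recs if r.subject_id == "a")
        assert a.samples.shape == (2, 4)

    def test_representation_hdf5_roundtrip(self, tmp_path, rng):
        maps = rng.uniform(0.1, 1.0, size=(3, 4, 4))
        giw = gaze.compute_giw(gaze.FixationMapStack(maps, 1.0, 1e-6))
        rep = gaze.build_representation(rng.uniform(size=(4, 4, 3)), giw,
                                        image_id="img7", subject_id="s01")
        path = tmp_path / "reps.h5"
        gaze.save_representations(path, [rep])
        back = gaze.load_representations(path)
        assert len(back) == 1
        assert back[0].source_image_id == "img7"
        assert np.array_equal(back[0].tensor, rep.tensor)
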