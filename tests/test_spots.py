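import numpy as np
import pytest

from hoxfish.simulate import render_spots
from hoxfish.spots import (DetectionParams, Spot, assign_spots_to_rois,
                           count_rna_spots, segment_dna_spots)
from hoxfish.stack_io import ImageStack, ParasegmentROI

VS_XY, VS_Z = 110.0, 500.0


def _rna_stack(centers_nm, shape=(8, 64, 64), amplitude=100.0):
    img = render_spots(shape, np.asarray(centers_nm, dtype=float), VS_XY, VS_Z,
                       sigma_xy_nm=200.0, sigma_z_nm=600.0, amplitude=amplitude)
    return ImageStack(img, VS_XY, VS_Z, "rna")


def _roi(label, x0, x1, y0=2, y1=60):
    return ParasegmentROI(label, [[x0, y0], [x1, y0], [x1, y1], [x0, y1]], VS_XY)


class TestRnaCounting:
    def test_all_zero_stack_counts_zero(self):
        stack = ImageStack(np.zeros((4, 32, 32)), VS_XY, VS_Z)
        counts = count_rna_spots(stack, [_roi("PS0", 2, 30, 2, 30)])
        assert counts.spot_count.tolist() == [0]

    def test_empty_roi_list_is_error(self):
        stack = ImageStack(np.zeros((4, 32, 32)), VS_XY, VS_Z)
        with pytest.raises(ValueError):
            count_rna_spots(stack, [])

    def test_counts_k_spots_in_roi(self, rng):
        k = 7
        # well-separated spots (>= 4 sigma apart) on a jittered grid
        grid = np.array([(10 + 16 * (i % 4), 10 + 16 * (i // 4)) for i in range(k)])
        jitter = rng.uniform(-2, 2, (k, 2))
        centers = np.column_stack([(grid[:, 0] + jitter[:, 0]) * VS_XY,
                                   (grid[:, 1] + jitter[:, 1]) * VS_XY,
                                   np.full(k, 3 * VS_Z)])
        stack = _rna_stack(centers)
        counts = count_rna_spots(stack, [_roi("PS0", 2, 62)],
                                 DetectionParams(maxima_prominence=20.0))
        assert counts.spot_count.tolist() == [k]

    def test_spot_with_maximum_outside_roi_not_counted(self):
        # spot centred at x = 40 px, ROI ends at x = 35: containment rule
        stack = _rna_stack([[40 * VS_XY, 30 * VS_XY, 3 * VS_Z]])
        counts = count_rna_spots(stack, [_roi("PS0", 2, 35)],
                                 DetectionParams(maxima_prominence=20.0))
        assert counts.spot_count.tolist() == [0]

    def test_count_monotone_in_prominence(self, rng):
        centers = np.column_stack([rng.uniform(8, 56, 12) * VS_XY,
                                   rng.uniform(8, 56, 12) * VS_XY,
                                   np.full(12, 3 * VS_Z)])
        amps = rng.uniform(20, 100, 12)
        img = sum(render_spots((8, 64, 64), centers[i:i + 1], VS_XY, VS_Z,
                               200.0, 600.0, amps[i]) for i in range(12))
        stack = ImageStack(img, VS_XY, VS_Z)
        roi = _roi("PS0", 2, 62)
        previous = None
        for prom in (5.0, 20.0, 50.0, 90.0, 200.0):
            count = count_rna_spots(stack, [roi],
                                    DetectionParams(maxima_prominence=prom)
                                    ).spot_count.iloc[0]
            if previous is not None:
                assert count <= previous
            previous = count


class TestDnaSegmentation:
    def test_uniform_image_yields_no_spots(self):
        stack = ImageStack(np.full((6, 32, 32), 7.0), 73.0, 300.0)
        assert segment_dna_spots(stack) == []

    def test_fixed_threshold_above_max_yields_empty(self):
        img = render_spots((10, 48, 48), np.array([[24 * 73.0, 24 * 73.0, 5 * 300.0]]),
                           73.0, 300.0, 150.0, 400.0, 100.0)
        stack = ImageStack(img, 73.0, 300.0)
        params = DetectionParams(threshold_method="fixed", fixed_threshold=1e6)
        assert segment_dna_spots(stack, params) == []

    def test_single_spot_centroid_within_quarter_voxel(self, rng):
        errors = []
        for _ in range(20):
            pos = np.array([rng.uniform(15, 33) * 73.0, rng.uniform(15, 33) * 73.0,
                            rng.uniform(3, 7) * 300.0])
            img = render_spots((10, 48, 48), pos[None], 73.0, 300.0, 150.0, 400.0, 100.0)
            spots = segment_dna_spots(ImageStack(img, 73.0, 300.0))
            assert len(spots) == 1
            errors.append(np.linalg.norm(spots[0].xyz[:2] - pos[:2]))
        rms = np.sqrt(np.mean(np.square(errors)))
        assert rms < 0.25 * 73.0

    def test_well_separated_spots_split_close_spots_merge(self):
        sigma = 150.0
        base = np.array([20 * 73.0, 20 * 73.0, 5 * 300.0])
        far = base + np.array([6 * sigma, 0, 0])
        near = base + np.array([0.8 * sigma, 0, 0])
        img_far = render_spots((10, 64, 64), np.vstack([base, far]),
                               73.0, 300.0, sigma, 400.0, 100.0)
        img_near = render_spots((10, 64, 64), np.vstack([base, near]),
                                73.0, 300.0, sigma, 400.0, 100.0)
        assert len(segment_dna_spots(ImageStack(img_far, 73.0, 300.0))) == 2
        assert len(segment_dna_spots(ImageStack(img_near, 73.0, 300.0))) == 1

    def test_detection_perfect_at_high_snr(self, small_clean_config):
        """Recall and precision are 1.0 on well-separated simulated spots."""
        from hoxfish.config import NoiseModel
        from hoxfish.simulate import simulate_embryo

        hits = total_true = total_found = 0
        for seed in range(4):
            cfg = small_clean_config(
                seed=seed, noise=NoiseModel(photons_per_unit=1.0, background=10.0))
            stacks, truth, _ = simulate_embryo(cfg)
            stack = next(s for s in stacks if s.channel_label == "A555")
            spots = segment_dna_spots(stack)
            true_pos = truth[["b_x_nm", "b_y_nm", "b_z_nm"]].to_numpy()
            total_true += len(true_pos)
            total_found += len(spots)
            for s in spots:
                if np.min(np.linalg.norm(true_pos - s.xyz, axis=1)) < 300.0:
                    hits += 1
        assert hits == total_true == total_found


class TestRoiAssignment:
    def test_spot_at_centroid_is_labeled(self):
        roi = _roi("PS3", 10, 30, 10, 30)
        spot = Spot("A555", (20 * VS_XY, 20 * VS_XY, 0.0), 1.0, 1)
        assert assign_spots_to_rois([spot], [roi])[0].ps_label == "PS3"

    def test_shared_vertex_goes_to_first_roi(self):
        left = _roi("left", 0, 20, 0, 20)
        right = _roi("right", 20, 40, 0, 20)
        spot = Spot("A555", (20 * VS_XY, 10 * VS_XY, 0.0), 1.0, 1)
        assert assign_spots_to_rois([spot], [left, right])[0].ps_label == "left"
        assert assign_spots_to_rois([spot], [right, left])[0].ps_label == "right"

    def test_labels_match_ray_casting_oracle(self, rng):
        def ray_cast(poly, x, y):
            inside = False
            n = len(poly)
            for i in range(n):
                x1, y1 = poly[i]
                x2, y2 = poly[(i + 1) % n]
                if (y1 > y) != (y2 > y):
                    if x < (x2 - x1) * (y - y1) / (y2 - y1) + x1:
                        inside = not inside
            return inside

        poly = np.array([[5, 5], [40, 10], [55, 40], [25, 55], [8, 35]], float)
        roi = ParasegmentROI("PS", poly, VS_XY)
        spots = [Spot("c", (rng.uniform(0, 60) * VS_XY, rng.uniform(0, 60) * VS_XY, 0.0),
                      1.0, 1) for _ in range(300)]
        assign_spots_to_rois(spots, [roi])
        for s in spots:
            expected = ray_cast(poly, s.centroid[0] / VS_XY, s.centroid[1] / VS_XY)
            assert (s.ps_label == "PS") == expected
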