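import math

import numpy as np
import pytest
from scipy import ndimage

from microcalc import (
    ConfigError,
    FilterConfig,
    GrayImage,
    SegmentationConfig,
    build_kernel,
    convolve,
    log_value,
    segment_response,
)

from conftest import disk_image


def random_configs(n, seed=7):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        r1 = rng.uniform(1.0, 4.0)
        r2 = r1 + rng.uniform(0.0, 6.0)
        out.append(FilterConfig(r1=r1, r2=r2))
    return out


class TestLogValue:
    def test_origin_value_closed_form(self):
        # substituting x = y = 0 at sigma = 1 gives 1/pi
        assert log_value(0, 0, 1.0) == pytest.approx(1.0 / math.pi, rel=1e-12)
        assert log_value(0, 0, 2.0) == pytest.approx(1.0 / (math.pi * 16), rel=1e-12)

    def test_zero_crossing_on_circle(self):
        sigma = 1.7
        r = math.sqrt(2) * sigma
        assert log_value(r, 0, sigma) == pytest.approx(0.0, abs=1e-12)
        assert log_value(r / math.sqrt(2), r / math.sqrt(2), sigma) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(50):
            x, y = rng.uniform(-5, 5, 2)
            s = rng.uniform(0.5, 3)
            assert log_value(x, y, s) == log_value(y, x, s) == log_value(-x, -y, s)

    def test_sigma_validation(self):
        with pytest.raises(ConfigError):
            log_value(0, 0, 0.0)


class TestKernel:
    @pytest.mark.parametrize("cfg", random_configs(20))
    def test_null_sum(self, cfg):
        k = build_kernel(cfg)
        assert abs(k.weights.sum()) <= 1e-6 * k.positive_sum

    def test_three_region_structure(self):
        cfg = FilterConfig(r1=2, r2=6)
        k = build_kernel(cfg)
        hw = cfg.kernel_halfwidth
        idx = np.arange(-hw, hw + 1)
        dx, dy = np.meshgrid(idx, idx)
        r = np.hypot(dx, dy)
        assert np.all(k.weights[r < cfg.r1] > 0)
        assert np.all(k.weights[(r >= cfg.r1) & (r <= cfg.r2)] == 0)
        assert np.all(k.weights[r > cfg.r2] <= 0)

    def test_rotational_symmetry_exact_for_mirrored_offsets(self):
        k = build_kernel(FilterConfig(r1=2, r2=5)).weights
        assert np.array_equal(k, k.T)
        assert np.array_equal(k, k[::-1, :])
        assert np.array_equal(k, k[:, ::-1])

    def test_zero_gap_reduces_to_truncated_log(self):
        cfg = FilterConfig(r1=3, r2=3)
        k = build_kernel(cfg)
        hw = cfg.kernel_halfwidth
        idx = np.arange(-hw, hw + 1, dtype=float)
        dx, dy = np.meshgrid(idx, idx)
        r = np.hypot(dx, dy)
        plain = log_value(dx, dy, cfg.sigma)
        # core matches the LoG exactly, tail is the renormalized LoG tail
        np.testing.assert_allclose(k.weights[r < 3], plain[r < 3], rtol=1e-12)
        tail = r > 3
        np.testing.assert_allclose(
            k.weights[tail],
            k.alpha * log_value(r[tail], 0.0, cfg.sigma),
            rtol=1e-9, atol=1e-15,
        )

    def test_translated_tail_shrinks_alpha_below_one(self):
        # the tail is spread over a larger circumference, so each weight
        # must shrink for the sums to balance
        cfg = FilterConfig(r1=2, r2=6, sigma=2 / math.sqrt(2))
        k = build_kernel(cfg)
        assert 0 < k.alpha < 1

    def test_kernel_text_round_trip(self, tmp_path):
        cfg = FilterConfig(r1=2, r2=4)
        k = build_kernel(cfg)
        path = tmp_path / "kernel.txt"
        k.save_txt(path)
        from microcalc.form_filter import FormKernel

        back = FormKernel.load_txt(path, cfg)
        np.testing.assert_allclose(back.weights, k.weights, rtol=1e-12)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=25, deadline=None)
@given(r1=st.floats(1.0, 4.0), dr=st.floats(0.0, 6.0))
def test_null_sum_holds_for_any_geometry(r1, dr):
    k = build_kernel(FilterConfig(r1=r1, r2=r1 + dr))
    assert abs(k.weights.sum()) <= 1e-6 * k.positive_sum


class TestConvolve:
    kernel = build_kernel(FilterConfig(r1=2, r2=6))

    def test_constant_image_annihilated(self, flat_image):
        resp = convolve(flat_image, self.kernel)
        assert np.abs(resp).max() < 1e-6 * 100.0

    def test_impulse_response_reproduces_kernel(self):
        size = 2 * self.kernel.config.kernel_halfwidth + 11
        arr = np.zeros((size, size))
        c = size // 2
        arr[c, c] = 7.0
        resp = convolve(GrayImage(arr), self.kernel)
        hw = self.kernel.config.kernel_halfwidth
        got = resp[c - hw:c + hw + 1, c - hw:c + hw + 1]
        np.testing.assert_allclose(got, 7.0 * self.kernel.weights, atol=1e-12)

    def test_linearity(self, rng):
        a, b = 2.5, -1.25
        i1 = rng.uniform(0, 50, (40, 40))
        i2 = rng.uniform(0, 50, (40, 40))
        lhs = ndimage.correlate(a * i1 + b * i2, self.kernel.weights, mode="reflect")
        rhs = a * ndimage.correlate(i1, self.kernel.weights, mode="reflect") \
            + b * ndimage.correlate(i2, self.kernel.weights, mode="reflect")
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_peak_response_flat_over_target_radii(self):
        peaks = []
        for radius in (2, 3, 4, 5):
            resp = convolve(GrayImage(disk_image(radius)), self.kernel)
            peaks.append(resp.max())
        assert max(peaks) / min(peaks) <= 1.10

    def test_kernel_larger_than_image_rejected(self):
        from microcalc import InputError

        with pytest.raises(InputError):
            convolve(GrayImage(np.ones((5, 5))), self.kernel)


class TestSegmentResponse:
    seg = SegmentationConfig(threshold_mode="absolute", threshold_value=10.0)

    def test_all_below_threshold_gives_empty(self):
        resp = np.zeros((20, 20))
        assert segment_response(resp, np.ones((20, 20), bool), self.seg) == []

    def test_two_disjoint_blobs(self):
        resp = np.zeros((30, 30))
        resp[5:8, 5:8] = 20.0
        resp[20:23, 20:24] = 30.0
        objs = segment_response(resp, np.ones((30, 30), bool), self.seg)
        assert len(objs) == 2
        sets = [set(map(tuple, o.pixels)) for o in objs]
        assert sets[0].isdisjoint(sets[1])

    def test_area_band_filters_components(self):
        resp = np.zeros((30, 30))
        resp[2, 2] = 20.0           # area 1
        resp[10:12, 10:12] = 20.0   # area 4
        resp[20:25, 20:25] = 20.0   # area 25
        seg = SegmentationConfig(threshold_mode="absolute", threshold_value=10.0,
                                 min_area_px=2, max_area_px=10)
        objs = segment_response(resp, np.ones((30, 30), bool), seg)
        assert [o.area for o in objs] == [4]

    def test_mask_excludes_outside_pixels(self):
        resp = np.full((10, 10), 100.0)
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        objs = segment_response(resp, mask, self.seg)
        assert all((o.pixels[:, 0] < 5).all() for o in objs)

    def test_connectivity_choice_changes_grouping(self):
        resp = np.zeros((10, 10))
        resp[2, 2] = 20.0
        resp[3, 3] = 20.0  # diagonal neighbours
        eight = SegmentationConfig(threshold_mode="absolute", threshold_value=10.0, connectivity=8)
        four = SegmentationConfig(threshold_mode="absolute", threshold_value=10.0, connectivity=4)
        assert len(segment_response(resp, np.ones((10, 10), bool), eight)) == 1
        assert len(segment_response(resp, np.ones((10, 10), bool), four)) == 2

    def test_objects_carry_original_intensities(self):
        resp = np.zeros((10, 10))
        resp[4:6, 4:6] = 20.0
        img = np.arange(100, dtype=float).reshape(10, 10)
        (obj,) = segment_response(resp, np.ones((10, 10), bool), self.seg, image=img)
        for (r, c), v in zip(obj.pixels, obj.intensities):
            assert v == img[r, c]


def test_injected_micros_recovered_end_to_end():
    """Segmenting an injected synthetic image recovers the injected spots."""
    from scipy.spatial.distance import cdist

    from microcalc import (
        SegmentationConfig,
        generate_background,
        generate_mother_cluster,
        inject_cluster,
        segment_image,
    )

    recovered_ok = 0
    for seed in range(6):
        img, mask = generate_background(512, 512, seed=seed)
        mother = generate_mother_cluster(M=12, spread_px=45.0, seed=seed + 100)
        injected, record = inject_cluster(img, mask, mother, seed=seed + 200)
        objs = segment_image(injected, mask,
                             FilterConfig.from_spacing(0.07),
                             SegmentationConfig(min_area_px=2))
        cents = np.array([[o.centroid_row, o.centroid_col] for o in objs])
        d = cdist(record.positions, cents).min(axis=1)
        n_hit = int((d <= 1.5).sum())
        if n_hit >= record.n_injected - 2:
            recovered_ok += 1
    assert recovered_ok >= 5
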