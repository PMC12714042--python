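"""Tests for the synthetic checkerboard DBSI generator."""

import numpy as np
import pytest

from dsfa_spri import (
    DEFAULT_DIP,
    NoiseModel,
    RIProtocol,
    SceneOptics,
    Segment,
    build_mosaic,
    evaluate_protocol,
    gamma_value,
    render_frame,
    render_sequence,
    staircase_protocol,
)
from dsfa_spri.simulate import DEFAULT_RI_LEVELS, _boundary_mask


class TestBuildMosaic:
    def test_parity_rule_and_pixel_map(self):
        geom = build_mosaic(4, 4, 4, parity=0)
        tiles = geom.tile_class_map()
        assert geom.shape == (16, 16)
        assert tiles[0, 0] and not tiles[0, 1] and tiles[1, 1]
        pixels = geom.pixel_class_map()
        assert pixels[:4, :4].all() and not pixels[:4, 4:8].any()

    def test_single_tile_mosaic(self):
        geom = build_mosaic(1, 1, 10, parity=0)
        assert geom.pixel_class_map().all()

    def test_zero_tile_px_rejected(self):
        with pytest.raises(ValueError):
            build_mosaic(2, 2, 0, 0)


class TestProtocol:
    def test_single_step_is_constant(self):
        protocol = RIProtocol((Segment("step", 10.0, n=1.333),))
        assert np.allclose(protocol.evaluate([0, 5, 10]), 1.333)

    def test_langmuir_association_closed_form(self):
        k, dn = 0.2, 0.005
        protocol = RIProtocol((Segment("langmuir", 200.0, delta_n_max=dn, k_obs=k),),
                              n_start=1.333)
        at_tau = protocol.evaluate(1.0 / k)
        assert at_tau == pytest.approx(1.333 + dn * (1 - np.exp(-1)))
        # approaches the saturation asymptote at long times
        assert protocol.evaluate(200.0) == pytest.approx(1.333 + dn, abs=1e-8)

    def test_wash_relaxes_toward_residual(self):
        protocol = RIProtocol((
            Segment("step", 10.0, n=1.3430),
            Segment("wash", 500.0, k_obs=0.05, residual_fraction=0.2),
        ), n_start=1.333)
        end = protocol.evaluate(510.0)
        residual = 1.333 + 0.2 * (1.3430 - 1.333)
        assert end == pytest.approx(residual, abs=1e-6)

    def test_time_outside_span_rejected(self):
        protocol = staircase_protocol(dwell_s=10.0)
        with pytest.raises(ValueError, match="within"):
            evaluate_protocol(protocol, [200.0])

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            RIProtocol((Segment("step", 5.0, n=1.45),))


class TestRenderFrame:
    def test_a_tiles_darker_than_ab_tiles(self, small_geometry, optics):
        frame = render_frame(small_geometry, 1.333, optics, artifact_width=0)
        classes = small_geometry.pixel_class_map()
        assert frame.data[classes].max() < frame.data[~classes].min()

    def test_same_seed_reproduces_frame_bitwise(self, small_geometry, optics):
        noise = NoiseModel(read_noise_sigma=10.0, shot_noise=True, seed=7)
        f1 = render_frame(small_geometry, 1.333, optics, noise=noise)
        f2 = render_frame(small_geometry, 1.333, optics, noise=noise)
        assert np.array_equal(f1.data, f2.data)

    def test_tile_values_match_band_intensity_oracle(self, small_geometry, optics):
        """Noiseless tile counts must equal gain x band-integrated intensities."""
        n = 1.341
        frame = render_frame(small_geometry, n, optics, artifact_width=0)
        ba = optics.band_values(n)
        classes = small_geometry.pixel_class_map()
        assert np.allclose(frame.data[classes], optics.gain * ba.i_a, rtol=1e-12)
        assert np.allclose(frame.data[~classes], optics.gain * ba.i_ab, rtol=1e-12)

    def test_boundary_artifact_mixes_tile_values(self, small_geometry, optics):
        frame = render_frame(small_geometry, 1.333, optics,
                             artifact_fraction=0.5, artifact_width=1)
        mask = _boundary_mask(small_geometry, 1)
        ba = optics.band_values(1.333)
        mixed = 0.5 * optics.gain * (ba.i_a + ba.i_ab)
        assert np.allclose(frame.data[mask], mixed, rtol=1e-12)

    def test_per_tile_index_map_renders_spatial_structure(self, optics):
        geom = build_mosaic(4, 4, 4)
        n_map = np.full((4, 4), 1.333)
        n_map[:, 2:] = 1.3495
        frame = render_frame(geom, n_map, optics, artifact_width=0)
        left = frame.data[:, :8][geom.pixel_class_map()[:, :8]]
        right = frame.data[:, 8:][geom.pixel_class_map()[:, 8:]]
        assert left.mean() != pytest.approx(right.mean())

    def test_non_nested_filters_rejected(self):
        from dsfa_spri import PassbandFilter

        with pytest.raises(ValueError, match="nested"):
            SceneOptics(filter_a=PassbandFilter(560, 600),
                        filter_ab=PassbandFilter(562, 598))


class TestRenderSequence:
    def test_constant_protocol_noiseless_frames_identical(self, small_geometry, optics):
        protocol = RIProtocol((Segment("step", 5.0, n=1.333),))
        stack, truth = render_sequence(small_geometry, protocol, 1.0, optics,
                                       artifact_width=0)
        assert len(stack) == 5
        assert np.array_equal(stack.data[0], stack.data[-1])
        assert np.allclose(truth["n"], 1.333)

    def test_two_step_protocol_switches_at_step_time(self, small_geometry, optics):
        protocol = RIProtocol((Segment("step", 3.0, n=1.333),
                               Segment("step", 3.0, n=1.3495)))
        stack, truth = render_sequence(small_geometry, protocol, 1.0, optics,
                                       artifact_width=0)
        values = [np.unique(frame).size for frame in stack.data]
        assert np.array_equal(stack.data[0], stack.data[2])
        assert not np.array_equal(stack.data[2], stack.data[3])
        assert truth["n"].tolist() == [1.333] * 3 + [1.3495] * 3
        assert all(v == 2 for v in values)  # two tile classes, no noise

    def test_ground_truth_gamma_is_self_consistent(self, small_geometry, optics):
        stack, truth = render_sequence(small_geometry, staircase_protocol(dwell_s=2.0),
                                       1.0, optics)
        recomputed = gamma_value(truth["i_a"].to_numpy(), truth["i_ab"].to_numpy())
        assert np.allclose(truth["gamma"], recomputed, atol=1e-12)

    def test_noiseless_gamma_non_decreasing_along_staircase(self, small_geometry, optics):
        _, truth = render_sequence(small_geometry, staircase_protocol(dwell_s=2.0),
                                   1.0, optics)
        assert np.all(np.diff(truth["gamma"]) >= 0)

    def test_zero_frames_rejected(self, small_geometry, optics):
        protocol = RIProtocol((Segment("step", 0.5, n=1.333),))
        with pytest.raises(ValueError, match="zero frames"):
            render_sequence(small_geometry, protocol, 1.0, optics)


class TestNoiseAveraging:
    def test_tile_mean_gamma_noise_scales_inversely_with_tile_px(self, optics):
        """Averaging a tile's pixels shrinks gamma noise like 1/tile_px."""
        from dsfa_spri import demosaic_frame, gamma_map

        sds = {}
        for tile_px in (4, 8):
            geom = build_mosaic(6, 6, tile_px)
            noise = NoiseModel(read_noise_sigma=10.0, shot_noise=True, seed=11)
            protocol = RIProtocol((Segment("step", 40.0, n=1.333),))
            stack, _ = render_sequence(geom, protocol, 1.0, optics,
                                       artifact_width=0, noise=noise)
            tile_means = []
            for k in range(len(stack)):
                bands = demosaic_frame(stack.frame(k))
                frame = gamma_map(bands)
                # first full tile of the cropped output
                tile_means.append(frame.values[:tile_px, :tile_px].mean())
            sds[tile_px] = np.std(tile_means, ddof=1)
        ratio = sds[8] / sds[4]
        assert 0.3 < ratio < 0.75  # ideal 0.5 under 1/sqrt(pixels) scaling
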