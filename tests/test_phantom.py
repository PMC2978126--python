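import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy import stats

from spectravasc.phantom import (
    CohortSpec,
    GroundTruth,
    PhantomSpec,
    VesselNetwork,
    VesselSegment,
    generate_cohort,
    generate_vessel_network,
    make_ground_truth,
    mvd_analog_count,
    rasterize_network,
    render_channel,
)
from spectravasc.spectral_model import (
    AbsorptionSpectrum,
    ChannelSpec,
    TissueOptics,
    effective_attenuation,
)

PITCH = 0.0075


def brute_force_capsule(net, width, height, pitch):
    """Exhaustive per-pixel oracle for the capsule rasterization rule."""
    mask = np.zeros((height, width), dtype=bool)
    for row in range(height):
        for col in range(width):
            cx, cy = (col + 0.5) * pitch, (row + 0.5) * pitch
            for seg in net.segments:
                (x0, y0), (x1, y1) = seg.p0, seg.p1
                dx, dy = x1 - x0, y1 - y0
                t = ((cx - x0) * dx + (cy - y0) * dy) / (dx * dx + dy * dy)
                t = min(max(t, 0.0), 1.0)
                d = np.hypot(cx - (x0 + t * dx), cy - (y0 + t * dy))
                if d <= seg.radius_mm:
                    mask[row, col] = True
                    break
    return mask


class TestGrowth:
    def test_zero_trees_gives_empty_network(self):
        spec = PhantomSpec(n_trees=0)
        assert len(generate_vessel_network(spec)) == 0

    def test_same_seed_reproduces_segments(self):
        spec = PhantomSpec(vessel_area_target=0.05, seed=3)
        a = generate_vessel_network(spec)
        b = generate_vessel_network(spec)
        assert a.segments == b.segments

    def test_area_target_reached_without_overshoot(self):
        spec = PhantomSpec(
            width_px=512, height_px=512, vessel_area_target=0.10, seed=17
        )
        net = generate_vessel_network(spec)
        mask, _ = rasterize_network(net, 512, 512, spec.pixel_pitch_mm)
        assert 0.10 <= mask.mean() <= 0.13

    def test_fixed_tree_count_respected(self):
        spec = PhantomSpec(n_trees=3, seed=8)
        net = generate_vessel_network(spec)
        mask, _ = rasterize_network(
            net, spec.width_px, spec.height_px, spec.pixel_pitch_mm
        )
        _, n = ndi.label(mask, structure=np.ones((3, 3), int))
        assert n == 3

    def test_trees_stay_spatially_distinct(self):
        # rejection placement must keep separately grown vessels disconnected
        spec = PhantomSpec(vessel_area_target=0.15, seed=5)
        net = generate_vessel_network(spec)
        mask, _ = rasterize_network(
            net, spec.width_px, spec.height_px, spec.pixel_pitch_mm
        )
        _, n = ndi.label(mask, structure=np.ones((3, 3), int))
        assert n > 10


class TestRasterize:
    def test_empty_network_rasterizes_to_zero(self):
        mask, thick = rasterize_network(VesselNetwork(), 32, 32, PITCH)
        assert not mask.any() and not thick.any()

    def test_pixel_counts_match_brute_force_oracle(self):
        seg_h = VesselSegment((0.0, 0.12), (0.24, 0.12), 3 * PITCH)
        seg_d = VesselSegment((0.02, 0.02), (0.2, 0.21), 1.7 * PITCH)
        net = VesselNetwork((seg_h, seg_d))
        mask, _ = rasterize_network(net, 32, 32, PITCH)
        oracle = brute_force_capsule(net, 32, 32, PITCH)
        assert np.array_equal(mask, oracle)

    def test_centerline_thickness_is_vessel_diameter(self):
        r = 4 * PITCH
        y = 16.5 * PITCH  # a pixel-center row
        net = VesselNetwork((VesselSegment((0.0, y), (0.24, y), r),))
        _, thick = rasterize_network(net, 32, 32, PITCH)
        assert thick[16].max() == pytest.approx(2 * r)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            rasterize_network(VesselNetwork(), 0, 32, PITCH)


class TestRender:
    def setup_method(self):
        y = 16.5 * PITCH
        net = VesselNetwork((VesselSegment((0.0, y), (0.24, y), 0.025),))
        mask, thick = rasterize_network(net, 32, 32, PITCH)
        self.truth = GroundTruth(mask, thick, PITCH, float(mask.sum()) * PITCH**2)

    def test_no_vessels_renders_uniform_background(self):
        empty = GroundTruth(
            np.zeros((8, 8), bool), np.zeros((8, 8)), PITCH, 0.0
        )
        optics = TissueOptics()
        img = render_channel(empty, ChannelSpec.parse("ex488_em550"), optics)
        assert np.allclose(img, optics.autofluorescence_yield)
        img_none = render_channel(empty, ChannelSpec.parse("ex635_emnone"), optics)
        assert np.allclose(img_none, optics.reflectance_background)

    def test_on_vessel_pixel_follows_beer_lambert(self):
        ch = ChannelSpec.parse("ex488_em550")
        optics = TissueOptics()
        blood = AbsorptionSpectrum((488.0, 550.0), (10.0, 20.0))
        img = render_channel(self.truth, ch, optics, blood)
        mu = effective_attenuation(ch, blood)
        d = self.truth.thickness_map[16, 10]
        assert img[16, 10] == pytest.approx(
            optics.autofluorescence_yield * np.exp(-mu * d)
        )

    def test_noise_is_seed_deterministic(self):
        ch = ChannelSpec.parse("ex488_em550")
        a = render_channel(self.truth, ch, noise_sd=0.05, seed=4)
        b = render_channel(self.truth, ch, noise_sd=0.05, seed=4)
        c = render_channel(self.truth, ch, noise_sd=0.05, seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_vessel_pixels_strictly_darker_than_background(self):
        optics = TissueOptics()
        for ch in ("ex488_em550", "ex488_emnone", "ex590_emnone", "ex635_emnone"):
            img = render_channel(self.truth, ChannelSpec.parse(ch), optics)
            bg = optics.background_for(ChannelSpec.parse(ch))
            assert (img[self.truth.mask] < bg).all()

    def test_true_area_unchanged_by_rendering(self):
        before = self.truth.true_area_mm2
        render_channel(self.truth, ChannelSpec.parse("ex488_em550"), noise_sd=0.1)
        assert self.truth.true_area_mm2 == before

    def test_measured_contrast_increases_with_absorption(self):
        optics = TissueOptics()
        ch = ChannelSpec.parse("ex488_em550")
        deficits = []
        for scale in (0.2, 1.0, 5.0):
            blood = AbsorptionSpectrum((488.0, 550.0), (10.0 * scale, 20.0 * scale))
            img = render_channel(self.truth, ch, optics, blood)
            deficits.append(
                optics.autofluorescence_yield - img[self.truth.mask].mean()
            )
        assert deficits == sorted(deficits)


class TestMvdAnalog:
    def make_truth(self, mask):
        return GroundTruth(mask, np.zeros_like(mask, float), PITCH, 0.0)

    def test_empty_mask_counts_zero(self):
        truth = self.make_truth(np.zeros((64, 64), bool))
        assert mvd_analog_count(truth, n_fields=3, field_px=32, seed=0) == 0

    def test_single_component_everywhere_counts_one(self):
        mask = np.zeros((64, 64), bool)
        mask[30:34, :] = True  # a band crossing every possible subfield
        truth = self.make_truth(mask)
        assert mvd_analog_count(truth, n_fields=4, field_px=64, seed=0) == 1

    def test_three_disjoint_blobs_full_field(self):
        mask = np.zeros((64, 64), bool)
        mask[5:10, 5:10] = mask[30:35, 30:35] = mask[50:55, 50:60] = True
        truth = self.make_truth(mask)
        assert mvd_analog_count(truth, n_fields=3, field_px=64, seed=1) == 3

    def test_field_count_and_size_validated(self):
        truth = self.make_truth(np.zeros((64, 64), bool))
        with pytest.raises(ValueError):
            mvd_analog_count(truth, n_fields=2, field_px=32)
        with pytest.raises(ValueError):
            mvd_analog_count(truth, n_fields=4, field_px=128)

    def test_count_increases_with_tree_count(self):
        counts = []
        trees = [2, 6, 12, 20]
        for n in trees:
            spec = PhantomSpec(n_trees=n, seed=21)
            truth = make_ground_truth(generate_vessel_network(spec), spec)
            counts.append(mvd_analog_count(truth, n_fields=5, field_px=192, seed=2))
        rho = stats.spearmanr(trees, counts).statistic
        assert rho > 0


class TestCohort:
    def small_cohort(self, **kw):
        template = PhantomSpec(
            width_px=128, height_px=128, vessel_area_target=0.05, noise_sd=0.0
        )
        return CohortSpec(template=template, **kw)

    def test_subject_count_and_labels(self):
        cs = self.small_cohort(n_control=3, n_tumor=13, seed=1)
        subjects = generate_cohort(cs)
        labels = [label for _, _, label in subjects]
        assert len(subjects) == 16
        assert labels == ["control"] * 3 + ["tumor"] * 13

    def test_cohort_is_seed_deterministic(self):
        cs = self.small_cohort(n_control=1, n_tumor=2, seed=9)
        a = generate_cohort(cs)
        b = generate_cohort(cs)
        for (lib_a, tr_a, _), (lib_b, tr_b, _) in zip(a, b):
            assert np.array_equal(tr_a.mask, tr_b.mask)
            assert tr_a.mvd_analog == tr_b.mvd_analog
            for ch in lib_a.channels:
                assert np.array_equal(lib_a[ch], lib_b[ch])

    def test_tumor_group_grows_larger_areas(self):
        cs = self.small_cohort(n_control=4, n_tumor=4, tumor_area_multiplier=3.0, seed=2)
        subjects = generate_cohort(cs)
        areas = {"control": [], "tumor": []}
        for _, truth, label in subjects:
            areas[label].append(truth.true_area_mm2)
        assert np.mean(areas["tumor"]) > 2.0 * np.mean(areas["control"])

    def test_validation_rejects_degenerate_specs(self):
        with pytest.raises(ValueError):
            self.small_cohort(n_control=0, seed=0)
        with pytest.raises(ValueError):
            self.small_cohort(tumor_area_multiplier=1.0, seed=0)
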