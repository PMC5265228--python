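import numpy as np
import pytest

from datspect_normdb import (
    CountVolume,
    QuantificationError,
    ReconstructionModel,
    ValidationError,
    VOICode,
    VOISet,
    build_large_voi_set,
    build_small_voi_set,
    large_voi_sbr,
    render_phantom,
    small_voi_sbr,
)

from conftest import identity_recon, uniform_phantom


def nominal_volumes(geometry):
    return {side: geometry.structure_volume_ml(side, "striatum")
            for side in ("left", "right")}


def toy_voi_set():
    """Hand-built 6x6x6 label volume with per-side targets and a reference."""
    labels = np.zeros((6, 6, 6), dtype=np.int16)
    labels[4, 1:3, 1:5] = 1  # left caudate (x high = left by convention here)
    labels[1, 1:3, 1:5] = 2  # right caudate
    labels[4, 3:5, 1:5] = 3  # left putamen
    labels[1, 3:5, 1:5] = 4  # right putamen
    labels[2:4, 1:5, 1:5] = 9  # reference slab between them
    codes = {
        1: VOICode("left", "caudate", "target"),
        2: VOICode("right", "caudate", "target"),
        3: VOICode("left", "putamen", "target"),
        4: VOICode("right", "putamen", "target"),
        9: VOICode(None, "reference", "reference"),
    }
    return VOISet(labels=labels, codes=codes, voxel_size_mm=2.0)


class TestSmallVoiSbr:
    def test_uniform_volume_gives_zero_everywhere(self):
        vois = toy_voi_set()
        volume = CountVolume(np.full((6, 6, 6), 37.0), 2.0)
        for record in small_voi_sbr(volume, vois):
            assert record.measured_sbr == pytest.approx(0.0)

    def test_three_to_one_ratio_gives_two(self):
        vois = toy_voi_set()
        data = np.full((6, 6, 6), 10.0)
        data[vois.labels > 0] = 10.0
        data[(vois.labels >= 1) & (vois.labels <= 4)] = 30.0
        for record in small_voi_sbr(CountVolume(data, 2.0), vois):
            assert record.measured_sbr == pytest.approx(2.0)

    def test_matches_brute_force_voxel_sums(self):
        vois = toy_voi_set()
        data = np.random.default_rng(0).poisson(40.0, (6, 6, 6)).astype(float)
        records = {(r.side, r.structure): r.measured_sbr
                   for r in small_voi_sbr(CountVolume(data, 2.0), vois)}
        ref = data[vois.labels == 9].mean()
        for side, codes in (("left", (1, 3)), ("right", (2, 4))):
            caudate = data[vois.labels == codes[0]].mean()
            putamen = data[vois.labels == codes[1]].mean()
            union = data[(vois.labels == codes[0]) | (vois.labels == codes[1])].mean()
            assert records[side, "caudate"] == pytest.approx((caudate - ref) / ref)
            assert records[side, "putamen"] == pytest.approx((putamen - ref) / ref)
            assert records[side, "striatum"] == pytest.approx((union - ref) / ref)

    def test_zero_reference_is_error(self):
        vois = toy_voi_set()
        with pytest.raises(QuantificationError, match="reference"):
            small_voi_sbr(CountVolume(np.zeros((6, 6, 6)), 2.0), vois)

    def test_misaligned_volume_rejected(self):
        vois = toy_voi_set()
        with pytest.raises(ValidationError, match="aligned"):
            small_voi_sbr(CountVolume(np.ones((5, 5, 5)), 2.0), vois)

    def test_partial_volume_loss_on_rendered_phantom(self, big_geometry):
        spec = uniform_phantom(big_geometry, sbr=5.0)
        recon = ReconstructionModel(mode="ACSC", psf_fwhm=10.0,
                                    butterworth_cutoff=None)
        volume = render_phantom(spec, recon, seed=0, poisson=False)
        vois = build_small_voi_set(big_geometry)
        for record in small_voi_sbr(volume, vois):
            assert record.measured_sbr < 5.0


class TestLargeVoiSbr:
    def test_unblurred_phantom_recovers_true_sbr_exactly(self, tiny_geometry):
        spec = uniform_phantom(tiny_geometry, sbr=5.0)
        volume = render_phantom(spec, identity_recon(), seed=0, poisson=False)
        vois = build_large_voi_set(tiny_geometry, margin_mm=6.0, edge_margin_mm=6.0)
        for record in large_voi_sbr(volume, vois, nominal_volumes(tiny_geometry)):
            assert record.measured_sbr == pytest.approx(5.0, abs=1e-6)

    def test_blurred_phantom_within_five_percent(self, big_geometry):
        spec = uniform_phantom(big_geometry, sbr=5.0)
        recon = ReconstructionModel(mode="ACSC", psf_fwhm=12.0,
                                    butterworth_cutoff=None)
        volume = render_phantom(spec, recon, seed=0, poisson=False)
        vois = build_large_voi_set(big_geometry, margin_mm=36.0)
        for record in large_voi_sbr(volume, vois, nominal_volumes(big_geometry)):
            assert record.measured_sbr == pytest.approx(5.0, rel=0.05)

    def test_zero_reference_is_error(self, tiny_geometry):
        vois = build_large_voi_set(tiny_geometry, margin_mm=6.0)
        volume = CountVolume(np.zeros(tiny_geometry.grid_shape), 3.0)
        with pytest.raises(QuantificationError):
            large_voi_sbr(volume, vois, nominal_volumes(tiny_geometry))

    def test_slab_equals_full_3d_for_prism_vois(self, tiny_geometry):
        spec = uniform_phantom(tiny_geometry, sbr=4.0)
        volume = render_phantom(spec, identity_recon(), seed=0, poisson=False)
        vois = build_large_voi_set(tiny_geometry, margin_mm=6.0, edge_margin_mm=6.0)
        nominal = nominal_volumes(tiny_geometry)
        slab = {r.side: r.measured_sbr
                for r in large_voi_sbr(volume, vois, nominal, use_slab=True)}
        full = {r.side: r.measured_sbr
                for r in large_voi_sbr(volume, vois, nominal, use_slab=False)}
        for side in ("left", "right"):
            assert slab[side] == pytest.approx(full[side], abs=1e-9)

    def test_matches_brute_force_on_toy_volume(self):
        labels = np.zeros((6, 6, 6), dtype=np.int16)
        labels[3:6, 1:4, :] = 1  # left large VOI, full-z prism
        labels[0:3, 1:4, :] = 2
        labels[:, 4:6, :] = 9  # reference
        codes = {
            1: VOICode("left", "large_striatal", "target"),
            2: VOICode("right", "large_striatal", "target"),
            9: VOICode(None, "reference", "reference"),
        }
        vois = VOISet(labels=labels, codes=codes, voxel_size_mm=2.0)
        data = np.random.default_rng(1).poisson(30.0, (6, 6, 6)).astype(float)
        nominal_ml = 10 * (2.0**3) / 1000.0  # 10 voxels
        with pytest.warns(UserWarning, match="boundary"):  # toy VOI spans the grid
            records = {r.side: r.measured_sbr
                       for r in large_voi_sbr(CountVolume(data, 2.0), vois, nominal_ml)}
        ref = data[labels == 9].mean()
        for side, code in (("left", 1), ("right", 2)):
            voi = labels == code
            expected = (data[voi].sum() - ref * voi.sum()) / (ref * 10)
            assert records[side] == pytest.approx(expected)

    def test_boundary_voi_warns(self):
        labels = np.zeros((6, 6, 6), dtype=np.int16)
        labels[0:2, :, :] = 1  # touches x boundary
        labels[4:6, :, :] = 2
        labels[2:4, :, :] = 9
        codes = {
            1: VOICode("left", "large_striatal", "target"),
            2: VOICode("right", "large_striatal", "target"),
            9: VOICode(None, "reference", "reference"),
        }
        vois = VOISet(labels=labels, codes=codes, voxel_size_mm=2.0)
        volume = CountVolume(np.full((6, 6, 6), 10.0), 2.0)
        with pytest.warns(UserWarning, match="boundary"):
            large_voi_sbr(volume, vois, 0.08)


class TestQuantifierProperties:
    def test_both_quantifiers_increase_with_contrast(self, tiny_geometry):
        vois_small = build_small_voi_set(tiny_geometry)
        vois_large = build_large_voi_set(tiny_geometry, margin_mm=8.0)
        nominal = nominal_volumes(tiny_geometry)
        recon = ReconstructionModel(mode="ACSC", psf_fwhm=6.0,
                                    butterworth_cutoff=None)
        small_values, large_values = [], []
        for sbr in (1.0, 3.0, 6.0):
            volume = render_phantom(uniform_phantom(tiny_geometry, sbr=sbr),
                                    recon, seed=0, poisson=False)
            small_values.append(small_voi_sbr(volume, vois_small)[0].measured_sbr)
            large_values.append(
                large_voi_sbr(volume, vois_large, nominal)[0].measured_sbr
            )
        assert small_values == sorted(small_values)
        assert large_values == sorted(large_values)
        assert small_values[0] < small_values[1] < small_values[2]

    def test_small_voi_decreases_with_fwhm_large_voi_stable(self, big_geometry):
        fwhm_grid = (4.0, 6.0, 8.0, 10.0)
        vois_small = build_small_voi_set(big_geometry)
        vois_large = build_large_voi_set(big_geometry, margin_mm=2 * max(fwhm_grid))
        nominal = nominal_volumes(big_geometry)
        small_values, large_values = [], []
        for fwhm in fwhm_grid:
            recon = ReconstructionModel(mode="ACSC", psf_fwhm=fwhm,
                                        butterworth_cutoff=None)
            volume = render_phantom(uniform_phantom(big_geometry, sbr=5.0),
                                    recon, seed=0, poisson=False)
            records = {r.structure: r.measured_sbr
                       for r in small_voi_sbr(volume, vois_small) if r.side == "left"}
            small_values.append(records["striatum"])
            large_values.append(
                large_voi_sbr(volume, vois_large, nominal)[0].measured_sbr
            )
        assert all(a > b for a, b in zip(small_values, small_values[1:]))
        spread = (max(large_values) - min(large_values)) / max(large_values)
        assert spread < 0.05

    def test_large_voi_size_invariance(self, big_geometry):
        fwhm = 8.0
        recon = ReconstructionModel(mode="ACSC", psf_fwhm=fwhm,
                                    butterworth_cutoff=None)
        volume = render_phantom(uniform_phantom(big_geometry, sbr=5.0),
                                recon, seed=0, poisson=False)
        nominal = nominal_volumes(big_geometry)
        values = []
        for factor in (2.0, 2.5, 3.0):
            vois = build_large_voi_set(big_geometry, margin_mm=factor * fwhm)
            values.append(large_voi_sbr(volume, vois, nominal)[0].measured_sbr)
        assert (max(values) - min(values)) / max(values) < 0.01

    def test_reference_cavity_shifts_large_voi_only(self, big_geometry):
        # a zero-activity cavity (dilated-ventricle analogue) in the
        # large-VOI reference but away from the tight VOIs and occipital ref
        volume = render_phantom(uniform_phantom(big_geometry, sbr=5.0),
                                identity_recon(), seed=0, poisson=False)
        cx, cy, cz = big_geometry.brain_center
        xs, ys, zs = big_geometry.coordinate_grids()
        cavity = ((xs - cx) ** 2 + (ys - (cy + 55.0)) ** 2 + (zs - cz) ** 2) <= 15.0**2
        data = volume.data.copy()
        data[cavity] = 0.0
        holed = CountVolume(data, volume.voxel_size_mm)

        vois_small = build_small_voi_set(big_geometry)
        vois_large = build_large_voi_set(big_geometry, margin_mm=12.0)
        assert not (cavity & (vois_small.labels > 0)).any()
        assert not (cavity & ((vois_large.labels == 1) | (vois_large.labels == 2))).any()

        nominal = nominal_volumes(big_geometry)
        small_before = [r.measured_sbr for r in small_voi_sbr(volume, vois_small)]
        small_after = [r.measured_sbr for r in small_voi_sbr(holed, vois_small)]
        assert small_before == pytest.approx(small_after, abs=1e-12)
        large_before = large_voi_sbr(volume, vois_large, nominal)[0].measured_sbr
        large_after = large_voi_sbr(holed, vois_large, nominal)[0].measured_sbr
        assert abs(large_after - large_before) > 0.05


class TestVOISetValidation:
    def test_unlisted_label_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[0, 0, 0] = 7
        with pytest.raises(ValidationError, match="code table"):
            VOISet(labels=labels, codes={}, voxel_size_mm=2.0)

    def test_labels_outside_brain_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[0, 0, 0] = 1
        codes = {1: VOICode("left", "caudate", "target")}
        with pytest.raises(ValidationError, match="brain"):
            VOISet(labels=labels, codes=codes, voxel_size_mm=2.0,
                   brain_mask=np.zeros((4, 4, 4), dtype=bool))

    def test_small_voi_targets_inside_brain(self, tiny_geometry):
        vois = build_small_voi_set(tiny_geometry)
        assert ((vois.labels > 0) & ~tiny_geometry.brain_mask()).sum() == 0

    def test_reference_and_targets_disjoint(self, tiny_geometry):
        vois = build_small_voi_set(tiny_geometry)
        reference = vois.reference_mask()
        for side in ("left", "right"):
            for structure in ("caudate", "putamen"):
                assert not (vois.mask(side, structure) & reference).any()

    def test_over_erosion_rejected(self, tiny_geometry):
        with pytest.raises(ValidationError, match="erosion"):
            build_small_voi_set(tiny_geometry, erosion_voxels=10)
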