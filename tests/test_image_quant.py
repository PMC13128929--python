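"""Flatmount quantification: masks, nuclei, classes, markers, puncta, areas."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi
from skimage import draw

from hyaloquant import (
    aggregate_replicates,
    area_report,
    build_vessel_mask,
    classify_cells,
    detect_tunel_puncta,
    positive_area,
    quantify_membrane_marker,
    quantify_nuclear_marker,
    segment_nuclei,
)
from hyaloquant.types import (
    ENDOTHELIAL,
    OTHER_NON_ENDOTHELIAL,
    PERICYTE,
    FlatmountImage,
    NucleusRecord,
    QuantParams,
    VesselMask,
)


def _image(channels, px=1.0):
    return FlatmountImage(channels=channels, pixel_size=px)


def _disc_image(radius=10, value=200.0, bg=5.0, shape=(64, 64), center=None):
    arr = np.full(shape, bg)
    rr, cc = draw.disk(center or (shape[0] // 2, shape[1] // 2), radius)
    arr[rr, cc] = value
    return arr


class TestVesselMask:
    def test_recovers_tube_footprint_area(self, noisefree_flatmount):
        image, gt = noisefree_flatmount
        mask = build_vessel_mask(image, "CD31")
        assert mask.fill_state
        assert mask.area_um2 == pytest.approx(
            gt.footprint_px * image.pixel_size**2, rel=0.02
        )

    def test_all_zero_channel_gives_empty_mask_with_warning(self):
        img = _image({"CD31": np.zeros((32, 32))})
        with pytest.warns(UserWarning, match="all-zero"):
            mask = build_vessel_mask(img, "CD31")
        assert mask.area_um2 == 0.0 and mask.fill_state

    def test_unknown_channel_is_an_input_error(self):
        img = _image({"CD31": np.zeros((8, 8))})
        with pytest.raises(KeyError, match="GPR124"):
            build_vessel_mask(img, "GPR124")

    def test_hollow_ring_lumen_is_filled(self):
        # flood-fill oracle: every lumen pixel is enclosed, so the solid
        # mask must contain the full outer disc
        ring = _disc_image(radius=40, shape=(128, 128), bg=0.0)
        rr, cc = draw.disk((64, 64), 25)
        ring[rr, cc] = 0.0
        mask = build_vessel_mask(_image({"CD31": ring}), "CD31")
        outer = np.zeros((128, 128), bool)
        rr, cc = draw.disk((64, 64), 40)
        outer[rr, cc] = True
        filled_oracle = ndi.binary_fill_holes(ring > 100)
        assert mask.mask[64, 64]
        assert (mask.mask & outer).sum() >= 0.98 * filled_oracle.sum()


class TestSegmentNuclei:
    def test_counts_disjoint_bright_ellipses(self):
        rng = np.random.default_rng(7)
        arr = np.full((512, 512), 5.0)
        centers = []
        while len(centers) < 20:
            c = rng.uniform(30, 482, 2)
            if all(np.hypot(*(c - q)) > 40 for q in centers):
                centers.append(c)
        for c in centers:
            rr, cc = draw.ellipse(c[0], c[1], 6, 4, rotation=rng.uniform(0, np.pi))
            arr[rr, cc] = 205.0
        records = segment_nuclei(_image({"DAPI": arr}))
        assert len(records) == 20

    def test_blank_channel_yields_no_records(self):
        assert segment_nuclei(_image({"DAPI": np.zeros((64, 64))})) == []

    def test_watershed_splits_dumbbell_into_two(self):
        # oracle: the two distance-transform maxima of two overlapping
        # equal discs are their centers
        arr = np.full((96, 96), 5.0)
        for c in ((48, 36), (48, 60)):
            rr, cc = draw.disk(c, 9)
            arr[rr, cc] = 205.0
        records = segment_nuclei(_image({"DAPI": arr}))
        assert len(records) == 2

    def test_disc_circularity_is_near_one(self):
        records = segment_nuclei(_image({"DAPI": _disc_image(radius=10)}))
        assert len(records) == 1
        assert 0.9 <= records[0].circularity <= 1.0

    def test_areas_scale_with_pixel_size(self):
        arr = _disc_image(radius=10)
        a1 = segment_nuclei(_image({"DAPI": arr}, px=1.0))[0].area_um2
        a2 = segment_nuclei(_image({"DAPI": arr}, px=0.5))[0].area_um2
        assert a1 == pytest.approx(4 * a2)


def _nucleus(nid, centroid, circ, coords=None):
    coords = coords if coords is not None else np.array([[int(centroid[0]), int(centroid[1])]])
    return NucleusRecord(
        nucleus_id=nid,
        coords=coords,
        centroid=centroid,
        area_um2=10.0,
        perimeter_um=12.0,
        circularity=circ,
    )


class TestClassifyCells:
    @pytest.fixture()
    def mask(self):
        m = np.zeros((64, 64), bool)
        m[:, :32] = True
        return VesselMask(m, "CD31", 1.0, fill_state=True)

    @pytest.mark.parametrize(
        "centroid,circ,expected",
        [
            ((10.0, 10.0), 0.9, ENDOTHELIAL),  # inside mask
            ((10.0, 50.0), 0.5, PERICYTE),  # outside, elongated
            ((10.0, 50.0), 0.61, OTHER_NON_ENDOTHELIAL),  # just above cutoff
            ((10.0, 50.0), 0.6, PERICYTE),  # boundary: rule is inclusive
            ((10.0, 10.0), 0.2, ENDOTHELIAL),  # mask membership wins
        ],
    )
    def test_rule_table(self, mask, centroid, circ, expected):
        (nuc,) = classify_cells([_nucleus(0, centroid, circ)], mask)
        assert nuc.cell_class == expected

    def test_unfilled_mask_rejected(self, mask):
        mask.fill_state = False
        with pytest.raises(ValueError, match="solid"):
            classify_cells([], mask)

    def test_class_partition_covers_all_nuclei(self, noisefree_pipeline):
        _, nuclei, *_ = noisefree_pipeline
        classes = [n.cell_class for n in nuclei]
        assert all(
            c in (ENDOTHELIAL, PERICYTE, OTHER_NON_ENDOTHELIAL) for c in classes
        )
        assert len(classes) == len(nuclei)


class TestNuclearMarker:
    def _setup(self, signal=30.0, bg=12.0):
        lef1 = np.full((64, 64), bg)
        mask = np.zeros((64, 64), bool)
        mask[:, :40] = True
        rr, cc = draw.disk((20, 20), 5)
        lef1[rr, cc] += signal
        nuc = _nucleus(0, (20.0, 20.0), 0.9, coords=np.stack([rr, cc], axis=1))
        nuc.cell_class = ENDOTHELIAL
        return _image({"LEF1": lef1}), [nuc], VesselMask(mask, "CD31", 1.0, True)

    def test_uniform_channel_gives_zero_corrected_intensity(self):
        img, nuclei, mask = self._setup(signal=0.0)
        nuclei, _ = quantify_nuclear_marker(img, "LEF1", nuclei, mask)
        assert nuclei[0].marker_intensities["LEF1"] == pytest.approx(0.0, abs=1e-9)

    def test_known_added_signal_recovered(self):
        # direct arithmetic oracle: corrected integral = S * n_pixels
        img, nuclei, mask = self._setup(signal=30.0)
        nuclei, _ = quantify_nuclear_marker(img, "LEF1", nuclei, mask)
        n_pix = len(nuclei[0].coords)
        assert nuclei[0].marker_intensities["LEF1"] == pytest.approx(
            30.0 * n_pix, rel=1e-9
        )

    def test_background_correction_matches_formula(self, noisefree_flatmount):
        image, _ = noisefree_flatmount
        mask = build_vessel_mask(image, "CD31")
        nuclei = classify_cells(segment_nuclei(image), mask)
        raster = image.channel("CD31")
        nuclei, _ = quantify_nuclear_marker(image, "CD31", nuclei, mask)
        bg_region = mask.mask.copy()
        for n in nuclei:
            bg_region[tuple(n.coords.T)] = False
        bg = raster[bg_region].mean()
        for n in nuclei[:10]:
            pix = raster[tuple(n.coords.T)]
            assert n.marker_intensities["CD31"] == pytest.approx(
                pix.sum() - bg * pix.size, abs=1e-9
            )

    def test_flatmount_summary_is_class_median(self):
        img, nuclei, mask = self._setup()
        extra = _nucleus(1, (50.0, 10.0), 0.9, coords=np.array([[50, 10]]))
        extra.cell_class = ENDOTHELIAL
        nuclei = nuclei + [extra]
        updated, summary = quantify_nuclear_marker(img, "LEF1", nuclei, mask)
        vals = [
            n.marker_intensities["LEF1"] for n in updated if n.cell_class == ENDOTHELIAL
        ]
        assert summary == pytest.approx(np.median(vals))

    def test_empty_background_region_is_an_error(self):
        img, nuclei, mask = self._setup()
        mask.mask[:] = False
        mask.mask[tuple(nuclei[0].coords.T)] = True
        with pytest.raises(ValueError, match="background region"):
            quantify_nuclear_marker(img, "LEF1", nuclei, mask)


class TestMembraneMarker:
    def test_constant_channel_gives_zero(self):
        mask = VesselMask(np.eye(32, dtype=bool), "CD31", 1.0, True)
        img = _image({"VEcad": np.full((32, 32), 7.5)})
        assert quantify_membrane_marker(img, "VEcad", mask) == pytest.approx(0.0)

    def test_step_signal_recovered_exactly(self):
        m = np.zeros((32, 32), bool)
        m[:, :16] = True
        arr = np.where(m, 12.0 + 4.5, 12.0)
        val = quantify_membrane_marker(
            _image({"VEcad": arr}), "VEcad", VesselMask(m, "CD31", 1.0, True)
        )
        assert val == pytest.approx(4.5, abs=1e-12)

    def test_noisy_estimate_within_propagated_error(self):
        # noise-propagation oracle: SE of the difference of two means of
        # n/2 pixels each is sigma * sqrt(2/(n/2)); allow 3 SE
        rng = np.random.default_rng(11)
        m = np.zeros((128, 128), bool)
        m[:, :64] = True
        sigma, s = 5.0, 8.0
        arr = np.where(m, 20.0 + s, 20.0) + rng.normal(0, sigma, (128, 128))
        val = quantify_membrane_marker(
            _image({"VEcad": arr}), "VEcad", VesselMask(m, "CD31", 1.0, True)
        )
        se = sigma * np.sqrt(1 / m.sum() + 1 / (~m).sum())
        assert abs(val - s) < 3 * se

    def test_degenerate_mask_is_an_error(self):
        img = _image({"VEcad": np.ones((16, 16))})
        with pytest.raises(ValueError, match="degenerate"):
            quantify_membrane_marker(
                img, "VEcad", VesselMask(np.ones((16, 16), bool), "CD31", 1.0, True)
            )


class TestTunelPuncta:
    def test_counts_disjoint_gaussian_spots(self):
        rng = np.random.default_rng(3)
        arr = np.full((256, 256), 5.0)
        rows = np.arange(256)[:, None]
        cols = np.arange(256)[None, :]
        centers = []
        while len(centers) < 12:
            c = rng.uniform(20, 236, 2)
            if all(np.hypot(*(c - q)) > 15 for q in centers):
                centers.append(c)
        for r0, c0 in centers:
            arr += 150.0 * np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * 1.5**2))
        assert len(detect_tunel_puncta(_image({"TUNEL": arr}), "TUNEL")) == 12

    def test_blank_channel_yields_none(self):
        assert detect_tunel_puncta(_image({"TUNEL": np.zeros((64, 64))}), "TUNEL") == []

    def test_touching_spots_with_two_maxima_split(self):
        # maxima-count oracle: two intensity maxima 8 px apart
        arr = np.full((64, 64), 5.0)
        rows = np.arange(64)[:, None]
        cols = np.arange(64)[None, :]
        for c0 in (28.0, 36.0):
            arr += 150.0 * np.exp(-((rows - 32.0) ** 2 + (cols - c0) ** 2) / (2 * 1.5**2))
        assert len(detect_tunel_puncta(_image({"TUNEL": arr}), "TUNEL")) == 2


class TestPositiveArea:
    def test_area_arithmetic_at_half_micron_pixels(self):
        arr = np.zeros((50, 50))
        arr.ravel()[:1000] = 10.0
        img = _image({"GPR124": arr}, px=0.5)
        assert positive_area(img, "GPR124", threshold=5.0) == pytest.approx(250.0)

    def test_identical_channels_have_unit_ratio(self, noisefree_flatmount):
        image, _ = noisefree_flatmount
        img = _image({"A": image.channel("CD31"), "B": image.channel("CD31")})
        report = area_report(img, ["A", "B"], ratios={"A_over_B": ("A", "B")})
        assert report.ratios["A_over_B"] == pytest.approx(1.0)

    def test_percent_of_control_arithmetic(self):
        img = _image({"GPR124": _disc_image(5, bg=0.0), "CD31": _disc_image(16, bg=0.0)})
        report = area_report(img, ["GPR124", "CD31"], ratios={"r": ("GPR124", "CD31")})
        pct = report.add_percent_of_control("r", control_mean=report.ratios["r"] * 5)
        assert pct == pytest.approx(20.0)

    def test_zero_denominator_is_an_error(self):
        img = _image({"A": _disc_image(5, bg=0.0), "B": np.zeros((64, 64))})
        with pytest.raises(ValueError, match="zero positive area"):
            area_report(img, ["A", "B"], ratios={"r": ("A", "B")})

    @given(
        st.integers(min_value=0, max_value=200),
        st.integers(min_value=0, max_value=200),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_positive_pixels(self, n1, n2):
        # adding positive pixels never decreases the area
        arr = np.zeros((40, 40))
        arr.ravel()[: min(n1, n2)] = 10.0
        small = positive_area(_image({"X": arr}), "X", threshold=5.0)
        arr.ravel()[: max(n1, n2)] = 10.0
        large = positive_area(_image({"X": arr}), "X", threshold=5.0)
        assert large >= small


class TestAggregateReplicates:
    def test_mean_of_technical_replicates(self):
        out = aggregate_replicates([1.0, 2.0, 3.0], ["m1", "m1", "m1"])
        assert out["m1"] == pytest.approx(2.0)

    def test_single_value_per_animal_is_identity(self):
        out = aggregate_replicates([4.0, 9.0], ["a", "b"])
        assert out.to_dict() == {"a": 4.0, "b": 9.0}

    def test_recovers_planted_animal_means_within_sem(self):
        rng = np.random.default_rng(5)
        true_means = {f"m{i}": rng.uniform(10, 20) for i in range(6)}
        values, animals = [], []
        n_fields, sigma = 8, 1.0
        for a, mu in true_means.items():
            values.extend(rng.normal(mu, sigma, n_fields))
            animals.extend([a] * n_fields)
        out = aggregate_replicates(values, animals)
        sem = sigma / np.sqrt(n_fields)
        for a, mu in true_means.items():
            assert abs(out[a] - mu) < 4 * sem


class TestGeometricInvariance:
    def test_summaries_invariant_to_rotation_and_translation(self, noisefree_flatmount):
        image, _ = noisefree_flatmount
        rotated = FlatmountImage(
            {k: np.rot90(v).copy() for k, v in image.channels.items()},
            image.pixel_size,
        )
        shifted = FlatmountImage(
            {k: np.roll(v, (7, -5), axis=(0, 1)) for k, v in image.channels.items()},
            image.pixel_size,
        )
        base = {
            "n_nuclei": len(segment_nuclei(image)),
            "mask_area": build_vessel_mask(image, "CD31").area_um2,
            "n_puncta": len(detect_tunel_puncta(image, "TUNEL")),
        }
        for variant in (rotated, shifted):
            assert len(segment_nuclei(variant)) == base["n_nuclei"]
            assert build_vessel_mask(variant, "CD31").area_um2 == pytest.approx(
                base["mask_area"], rel=0.01
            )
            assert len(detect_tunel_puncta(variant, "TUNEL")) == base["n_puncta"]

    def test_segmented_pixel_sets_are_disjoint(self, noisefree_pipeline):
        _, nuclei, puncta, *_ = noisefree_pipeline
        seen = set()
        for n in nuclei:
            pix = set(map(tuple, n.coords))
            assert not pix & seen
            seen |= pix
        seen = set()
        for p in puncta:
            pix = set(map(tuple, p.coords))
            assert not pix & seen
            seen |= pix
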