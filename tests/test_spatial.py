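import numpy as np
import pytest
from scipy import ndimage as ndi

from mucoscape import masks, phantom, spatial
from mucoscape.errors import (
    EmptyCompartmentError,
    ParameterError,
    UndefinedStatisticError,
)
from mucoscape.imagio import BinaryMask, MultichannelImage
from mucoscape.masks import EdgeContour, SegmentationParams, mask_edges_um
from mucoscape.spatial import (
    DensityEstimate,
    SpotParams,
    bacterial_density,
    epithelial_band,
    inner_mucus_thickness,
    mean_intensity,
)

from conftest import make_flat_spec


def brute_force_min_distances(samples_px, targets_px, pixel_size_um):
    """Independent oracle: exhaustive all-pairs minimum, pixel centers."""
    out = []
    for p in np.asarray(samples_px, float):
        d = np.sqrt(((np.asarray(targets_px, float) - p) ** 2).sum(axis=1))
        out.append(d.min() * pixel_size_um)
    return np.array(out)


def segment_phantom(spec):
    img, truth = phantom.generate_phantom(spec)
    params = SegmentationParams()
    muc = masks.mucosal_mask(img, params)
    lum = masks.luminal_mask(img, muc, params)
    return img, truth, muc, lum


class TestMeanIntensity:
    def test_constant_channel(self):
        img = MultichannelImage(
            channels={"Eub": np.full((5, 5), 7.0)}, pixel_size_um=1.0
        )
        mask = BinaryMask(np.tri(5, 5, 0, bool), label="luminal")
        assert mean_intensity(img, "Eub", mask) == 7.0

    def test_hand_arithmetic(self):
        img = MultichannelImage(
            channels={"Eub": np.array([[1.0, 3.0], [5.0, 7.0]])}, pixel_size_um=1.0
        )
        left = BinaryMask(np.array([[True, False], [True, False]]), label="other")
        assert mean_intensity(img, "Eub", left) == 3.0

    def test_empty_mask_is_error_not_zero(self):
        img = MultichannelImage(channels={"Eub": np.zeros((3, 3))}, pixel_size_um=1.0)
        with pytest.raises(UndefinedStatisticError):
            mean_intensity(img, "Eub", BinaryMask(np.zeros((3, 3), bool)))

    def test_density_contrast_between_phantoms(self):
        # same geometry/noise seed, different luminal density
        hi = make_flat_spec(bacterial_density_per_ml=1e11, seed=33)
        lo = make_flat_spec(bacterial_density_per_ml=1e9, seed=33)
        means = []
        for spec in (hi, lo):
            img, truth = phantom.generate_phantom(spec)
            mask = BinaryMask(truth.luminal_mask_true, label="luminal")
            means.append(mean_intensity(img, "Eub", mask))
        assert means[0] > means[1]


class TestThickness:
    def test_parallel_edges(self):
        px = 0.5
        muc = EdgeContour(np.column_stack([np.full(60, 50), np.arange(60)]), px)
        lum = EdgeContour(np.column_stack([np.full(60, 10), np.arange(60)]), px)
        est = inner_mucus_thickness(muc, lum, n_points=100, seed=0)
        assert est.n_points == 60  # edge shorter than requested points
        np.testing.assert_allclose(est.per_point_distances_um, 20.0)
        assert est.mean_um == pytest.approx(20.0)
        assert est.median_um == pytest.approx(20.0)

    def test_square_annulus_matches_brute_force(self):
        # luminal square boundary, mucosal ring boundary g px away
        g = 6
        lum_pts, muc_pts = [], []
        lo, hi = 20, 30
        for i in range(lo, hi + 1):
            lum_pts += [(lo, i), (hi, i), (i, lo), (i, hi)]
        mlo, mhi = lo - g, hi + g
        for i in range(mlo, mhi + 1):
            muc_pts += [(mlo, i), (mhi, i), (i, mlo), (i, mhi)]
        px = 0.5
        muc = EdgeContour(np.unique(muc_pts, axis=0), px)
        lum = EdgeContour(np.unique(lum_pts, axis=0), px)
        est = inner_mucus_thickness(muc, lum, n_points=100, seed=3)
        oracle = brute_force_min_distances(est.sampled_points, muc.points, px)
        np.testing.assert_allclose(est.per_point_distances_um, oracle)
        np.testing.assert_allclose(est.per_point_distances_um, g * px)

    def test_oracle_equivalence_on_phantom(self, segmented_flat_phantom):
        spec, img, _, muc, lum = segmented_flat_phantom
        me, le = mask_edges_um(muc, lum, img.pixel_size_um)
        est = inner_mucus_thickness(me, le, n_points=100, seed=5)
        oracle = brute_force_min_distances(
            est.sampled_points, me.points, img.pixel_size_um
        )
        np.testing.assert_array_equal(est.per_point_distances_um, oracle)

    def test_flat_phantom_recovery(self, segmented_flat_phantom):
        spec, img, _, muc, lum = segmented_flat_phantom
        me, le = mask_edges_um(muc, lum, img.pixel_size_um)
        est = inner_mucus_thickness(me, le, n_points=100, seed=1)
        assert est.mean_um == pytest.approx(30.0, abs=2 * img.pixel_size_um)

    def test_sampling_consistency(self, segmented_flat_phantom):
        spec, img, _, muc, lum = segmented_flat_phantom
        me, le = mask_edges_um(muc, lum, img.pixel_size_um)
        full = inner_mucus_thickness(me, le, n_points=len(le), seed=0)
        for seed in range(5):
            sub = inner_mucus_thickness(me, le, n_points=100, seed=seed)
            assert abs(sub.mean_um - full.mean_um) <= 0.1 * full.mean_um

    def test_determinism(self, segmented_flat_phantom):
        spec, img, _, muc, lum = segmented_flat_phantom
        me, le = mask_edges_um(muc, lum, img.pixel_size_um)
        a = inner_mucus_thickness(me, le, seed=9)
        b = inner_mucus_thickness(me, le, seed=9)
        np.testing.assert_array_equal(a.per_point_distances_um, b.per_point_distances_um)
        assert a.mean_um == b.mean_um

    def test_dss_scenario_contrast(self):
        # thinned inner layer phantom pair: estimates ordered, IQRs disjoint
        ests = {}
        for t in (30.0, 10.0):
            img, truth, muc, lum = segment_phantom(
                make_flat_spec(inner_mucus_thickness_um=t, seed=13)
            )
            me, le = mask_edges_um(muc, lum, img.pixel_size_um)
            ests[t] = inner_mucus_thickness(me, le, seed=2)
        assert ests[30.0].mean_um > ests[10.0].mean_um
        q1_thick = np.percentile(ests[30.0].per_point_distances_um, 25)
        q3_thin = np.percentile(ests[10.0].per_point_distances_um, 75)
        assert q3_thin < q1_thick

    def test_bad_n_points(self):
        e = EdgeContour(np.array([[0, 0]]), 1.0)
        with pytest.raises(ParameterError):
            inner_mucus_thickness(e, e, n_points=0, seed=0)

    def test_empty_contour(self):
        e = EdgeContour(np.empty((0, 2)), 1.0)
        full = EdgeContour(np.array([[0, 0]]), 1.0)
        with pytest.raises(EmptyCompartmentError):
            inner_mucus_thickness(e, full, seed=0)


def spot_image(centers, shape=(40, 100), px=0.5, amplitude=200.0):
    """Noiseless image with point-like spots at the given pixel centers."""
    eub = np.zeros(shape)
    for r, c in centers:
        eub[r, c] = amplitude
    eub = ndi.gaussian_filter(eub, 0.6)
    eub *= amplitude / eub.max() if eub.max() > 0 else 1.0
    return MultichannelImage(
        channels={"Eub": eub}, pixel_size_um=px, section_thickness_um=5.0
    )


class TestDensity:
    def test_zero_bacteria_phantom(self):
        spec = make_flat_spec(bacterial_density_per_ml=0.0, seed=8)
        img, truth = phantom.generate_phantom(spec)
        est = bacterial_density(
            img, BinaryMask(truth.luminal_mask_true, label="luminal")
        )
        assert est.bacterium_count == 0
        assert est.density_per_ml == 0.0

    def test_hand_conversion_10_in_2000um2(self):
        # 10 spots in an 80x100 px region at 0.5 um/px = 2000 um^2;
        # 5 um section -> exactly 1e9 per ml
        rng = np.random.default_rng(4)
        centers = np.column_stack(
            [rng.choice(70, 10, replace=False) + 5, rng.choice(90, 10, replace=False) + 5]
        )
        img = spot_image(centers, shape=(80, 100))
        region = BinaryMask(np.ones((80, 100), bool), label="luminal")
        est = bacterial_density(
            img, region, SpotParams(threshold_abs=50.0, bacterium_radius_um=0.5)
        )
        assert est.bacterium_count == 10
        assert est.area_um2 == pytest.approx(2000.0)
        assert est.volume_ml == pytest.approx(1e-8)
        assert est.density_per_ml == pytest.approx(1e9)

    def test_density_estimate_invariants(self):
        est = DensityEstimate.from_count(10, 2000.0, 5.0)
        assert est.volume_ml == pytest.approx(2000.0 * 5.0 * 1e-12)
        assert est.density_per_ml == pytest.approx(10 / est.volume_ml)

    def test_phantom_poisson_recovery(self):
        spec = make_flat_spec(
            image_height_px=768,
            image_width_px=768,
            bacterial_density_per_ml=1e9,
            seed=17,
        )
        img, truth = phantom.generate_phantom(spec)
        region = BinaryMask(truth.luminal_mask_true, label="luminal")
        assert region.area_px() * spec.pixel_size_um**2 >= 1e5
        est = bacterial_density(img, region)
        lam = phantom.expected_count(
            1e9, est.area_um2, spec.section_thickness_um
        )
        sd = np.sqrt(lam)
        assert abs(est.bacterium_count - lam) <= 3 * sd
        assert abs(est.density_per_ml - 1e9) <= 3 * sd / (est.volume_ml * lam) * lam

    def test_debris_filter_excludes_large_objects(self):
        centers = [(10, 10), (10, 40), (30, 70)]
        img = spot_image(centers)
        # add a bright disc much larger than a bacterium
        yy, xx = np.ogrid[:40, :100]
        disc = (yy - 25) ** 2 + (xx - 20) ** 2 <= 6**2
        eub = img.channels["Eub"].copy()
        eub[disc] = 180.0
        img2 = MultichannelImage(
            channels={"Eub": eub}, pixel_size_um=0.5, section_thickness_um=5.0
        )
        region = BinaryMask(np.ones((40, 100), bool), label="luminal")
        params = SpotParams(threshold_abs=50.0)
        est = bacterial_density(img2, region, params)
        assert est.bacterium_count == 3

    def test_empty_region(self):
        img = spot_image([(5, 5)])
        with pytest.raises(UndefinedStatisticError):
            bacterial_density(img, BinaryMask(np.zeros((40, 100), bool)))


class TestEpithelialBand:
    def straight_edge(self, px=0.5, row=20, width=30):
        return EdgeContour(np.column_stack([np.full(width, row), np.arange(width)]), px)

    def mucosa_below(self, row=20, shape=(40, 30)):
        grid = np.zeros(shape, bool)
        grid[row:, :] = True
        return BinaryMask(grid, label="mucosal")

    def test_band_two_pixels_deep(self):
        edge = self.straight_edge()
        band = epithelial_band(
            edge, 1.0, image_shape=(40, 30), mucosal_mask=self.mucosa_below()
        )
        rows = np.unique(np.nonzero(band.grid)[0])
        np.testing.assert_array_equal(rows, [18, 19])

    def test_monotone_nesting(self):
        edge = self.straight_edge()
        muc = self.mucosa_below()
        b1 = epithelial_band(edge, 1.0, image_shape=(40, 30), mucosal_mask=muc)
        b2 = epithelial_band(edge, 2.5, image_shape=(40, 30), mucosal_mask=muc)
        assert not (b1.grid & ~b2.grid).any()

    def test_exact_distance_bound(self):
        edge = self.straight_edge()
        muc = self.mucosa_below()
        w = 1.7
        band = epithelial_band(edge, w, image_shape=(40, 30), mucosal_mask=muc)
        pts = np.column_stack(np.nonzero(band.grid))
        dists = brute_force_min_distances(pts, edge.points, edge.pixel_size_um)
        assert (dists <= w + 1e-9).all()

    def test_bad_width(self):
        with pytest.raises(ParameterError):
            epithelial_band(self.straight_edge(), 0.0, image_shape=(40, 30))
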