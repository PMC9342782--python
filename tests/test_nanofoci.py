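"""Nanofocus segmentation, shape features, DxRy classification, QC filters."""

import numpy as np
import pytest

from conftest import make_table
from meiostorm import nanofoci
from meiostorm.nanofoci import Configuration, Nanofocus
from meiostorm.roidetect import ROI


def _cluster(center, n, sigma, rng):
    return rng.normal(center, sigma, (n, 2))


def _roi(center=(0.0, 0.0)):
    return ROI("roi_t", "n0", center)


def _table(channel_points: dict, precision=15.0):
    xs, chans = [], []
    for ch, pts in channel_points.items():
        xs.append(np.asarray(pts, float))
        chans += [ch] * len(pts)
    return make_table(np.vstack(xs), precision=precision, channel=chans)


def _nf(pixels, pixel_size=5.0, origin=(0.0, 0.0)):
    nf = Nanofocus("roi_t", "RAD51", np.asarray(pixels), pixel_size, origin)
    return nanofoci.compute_shape_features(nf)


class TestSegmentation:
    def test_single_cluster_single_nanofocus_with_predicted_area(self):
        # threshold-crossing area of a Gaussian cluster:
        # A = 2 pi S^2 ln(N / (2 pi S^2 t)), S^2 = spread^2 + precision^2
        rng = np.random.default_rng(0)
        n, spread, prec = 3000, 40.0, 15.0
        table = _table({"RAD51": _cluster((0, 0), n, spread, rng)}, precision=prec)
        nfs = nanofoci.segment_nanofoci(_roi(), table)
        assert len(nfs) == 1
        S2 = spread**2 + prec**2
        area_pred = 2 * np.pi * S2 * np.log(n / (2 * np.pi * S2 * 0.15))
        assert nfs[0].area >= 1_250.0
        assert nfs[0].area == pytest.approx(area_pred, rel=0.15)
        # localizations are assigned to the component containing them
        assert 0.4 * n < nfs[0].n_localizations <= n

    def test_two_clusters_300nm_apart_give_two_nanofoci(self):
        rng = np.random.default_rng(1)
        table = _table({
            "DMC1": np.vstack([
                _cluster((-150, 0), 3000, 30.0, rng),
                _cluster((150, 0), 3000, 30.0, rng),
            ])
        })
        nfs = nanofoci.segment_nanofoci(_roi(), table)
        assert len(nfs) == 2
        coms = sorted(nf.center_of_mass[0] for nf in nfs)
        assert coms[0] == pytest.approx(-150, abs=15)
        assert coms[1] == pytest.approx(150, abs=15)

    def test_component_below_min_area_excluded(self):
        # sparse cluster: crosses threshold only over a tiny region
        rng = np.random.default_rng(2)
        table = _table({"RAD51": _cluster((0, 0), 450, 15.0, rng)}, precision=12.0)
        nfs_all = nanofoci.segment_nanofoci(_roi(), table, min_area=0.0)
        nfs = nanofoci.segment_nanofoci(_roi(), table)  # default floor 1250
        assert any(nf.area < 1_250 for nf in nfs_all)
        assert all(nf.area >= 1_250 for nf in nfs)
        assert len(nfs) < len(nfs_all) or not nfs

    def test_localizations_outside_circle_ignored(self):
        rng = np.random.default_rng(3)
        inside = _cluster((0, 0), 2500, 30.0, rng)
        outside = _cluster((600, 0), 2500, 30.0, rng)  # beyond the 375-nm radius
        table = _table({"RAD51": np.vstack([inside, outside])})
        nfs = nanofoci.segment_nanofoci(_roi(), table)
        assert len(nfs) == 1
        assert abs(nfs[0].center_of_mass[0]) < 30

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        pts = _cluster((0, 0), 2500, 35.0, rng)
        shift = np.array([40_000.0, -25_000.0])
        t1 = _table({"RAD51": pts})
        t2 = _table({"RAD51": pts + shift})
        nf1 = nanofoci.segment_nanofoci(_roi((0, 0)), t1)[0]
        nf2 = nanofoci.segment_nanofoci(_roi(tuple(shift)), t2)[0]
        np.testing.assert_allclose(
            np.asarray(nf2.center_of_mass) - np.asarray(nf1.center_of_mass),
            shift, atol=1e-6,
        )
        assert nf1.area == nf2.area

    def test_empty_roi_warns_and_returns_empty(self):
        table = _table({"RAD51": [(10_000.0, 10_000.0)]})
        with pytest.warns(UserWarning, match="no localizations"):
            out = nanofoci.segment_nanofoci(_roi((0, 0)), table)
        assert out == []

    def test_area_monotone_in_localization_count(self):
        rng = np.random.default_rng(5)
        areas = []
        for n in (2000, 4000, 8000):
            table = _table({"RAD51": _cluster((0, 0), n, 40.0, rng)})
            areas.append(nanofoci.segment_nanofoci(_roi(), table)[0].area)
        assert areas[0] < areas[1] < areas[2]


class TestShapeFeatures:
    def test_disc_eccentricity_near_zero(self):
        yy, xx = np.mgrid[-20:21, -20:21]
        pix = np.argwhere(yy**2 + xx**2 <= 400)
        nf = _nf(pix)
        assert nf.eccentricity < 0.05

    def test_rectangle_eccentricity_closed_form(self):
        # 5 x 100 pixels: lam ratio = (5^2-... ) via uniform second moments
        pix = np.argwhere(np.ones((5, 100), bool))
        nf = _nf(pix)
        # variances of discrete uniform over m points: (m^2 - 1) / 12
        lam1 = (100**2 - 1) / 12
        lam2 = (5**2 - 1) / 12
        assert nf.eccentricity == pytest.approx(np.sqrt(1 - lam2 / lam1), abs=1e-9)
        assert nf.eccentricity > 0.99

    def test_area_is_pixel_count_times_pixel_area(self):
        pix = np.argwhere(np.ones((8, 10), bool))
        nf = _nf(pix)
        assert nf.area == 80 * 25.0

    def test_center_of_mass_world_coordinates(self):
        nf = _nf([(0, 0), (0, 2)], origin=(100.0, 200.0))
        assert nf.center_of_mass == (105.0, 200.0)


class TestClassification:
    def _config(self, x, y):
        nfs = [
            Nanofocus("r", "DMC1", [(0, 0)], 5.0, (0, 0)) for _ in range(x)
        ] + [
            Nanofocus("r", "RAD51", [(0, 0)], 5.0, (0, 0)) for _ in range(y)
        ]
        return nanofoci.classify_configuration(nfs)

    @pytest.mark.parametrize("x,y,label", [(1, 1, "D1R1"), (2, 1, "D2R1"),
                                           (1, 3, "D1R3"), (0, 2, "D0R2")])
    def test_label_from_counts(self, x, y, label):
        assert self._config(x, y).label == label

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            nanofoci.classify_configuration([])

    def test_mixed_roi_ids_raise(self):
        nfs = [Nanofocus("a", "DMC1", [(0, 0)], 5.0, (0, 0)),
               Nanofocus("b", "RAD51", [(0, 0)], 5.0, (0, 0))]
        with pytest.raises(ValueError):
            nanofoci.classify_configuration(nfs)


class TestFarClose:
    def _d2r1(self, d_offsets):
        nfs = [Nanofocus("r", "RAD51", [(0, 0)], 5.0, (0.0, 0.0))]
        for dx in d_offsets:
            nfs.append(Nanofocus("r", "DMC1", [(0, 0)], 5.0, (dx, 0.0)))
        for nf in nfs:
            nanofoci.compute_shape_features(nf)
        return nanofoci.classify_configuration(nfs)

    def test_nearer_nanofocus_is_close(self):
        cfg = nanofoci.assign_far_close(self._d2r1([50.0, 300.0]))
        roles = {nf.center_of_mass[0]: nf.role for nf in cfg.of_channel("DMC1")}
        assert roles[50.0] == "close"
        assert roles[300.0] == "far"

    def test_d1r1_roles_stay_single(self):
        nfs = [Nanofocus("r", "RAD51", [(0, 0)], 5.0, (0, 0)),
               Nanofocus("r", "DMC1", [(0, 0)], 5.0, (50, 0))]
        for nf in nfs:
            nanofoci.compute_shape_features(nf)
        cfg = nanofoci.assign_far_close(nanofoci.classify_configuration(nfs))
        assert all(nf.role == "single" for nf in cfg.nanofoci)

    def test_exact_tie_resolved_by_index_with_warning(self):
        with pytest.warns(UserWarning, match="equidistant"):
            cfg = nanofoci.assign_far_close(self._d2r1([100.0, -100.0]))
        assert cfg.of_channel("DMC1")[0].role == "close"


class TestFilterRois:
    def _cfg(self, x, y, largest_px):
        nfs = []
        for i in range(x):
            npx = largest_px if (i == 0 and y == 0) else 60
            nfs.append(Nanofocus("r", "DMC1", [(0, j) for j in range(npx)], 5.0, (0, 0)))
        for i in range(y):
            npx = largest_px if i == 0 else 60
            nfs.append(Nanofocus("r", "RAD51", [(1, j) for j in range(npx)], 5.0, (0, 0)))
        for nf in nfs:
            nanofoci.compute_shape_features(nf)
        return nanofoci.classify_configuration(nfs)

    def test_largest_nanofocus_floor(self):
        small = self._cfg(1, 1, 400)   # 400 px = 10,000 nm^2 <= 12,500
        big = self._cfg(1, 1, 600)     # 600 px = 15,000 nm^2
        assert nanofoci.filter_rois([small, big]) == [big]

    def test_single_protein_rois_dropped_by_default_kept_in_s4_mode(self):
        d1r0 = self._cfg(1, 0, 600)
        assert nanofoci.filter_rois([d1r0]) == []
        kept = nanofoci.filter_rois([d1r0], require_both_channels=False)
        assert kept == [d1r0] and d1r0.label == "D1R0"

    def test_passing_roi_unchanged(self):
        good = self._cfg(2, 1, 700)
        assert nanofoci.filter_rois([good]) == [good]


def test_far_smaller_than_close_on_generator_asymmetry(segmented_sites):
    """Feature pipeline consistency: generated far foci are smaller."""
    _, configs = segmented_sites
    far, close = [], []
    for cfg in configs.values():
        if cfg.label in ("D2R1", "D1R2"):
            for nf in cfg.nanofoci:
                if nf.role == "far":
                    far.append(nf.area)
                elif nf.role == "close":
                    close.append(nf.area)
    assert len(far) >= 3
    assert np.median(far) < np.median(close)


def test_configuration_recovery_on_simulated_sites(sim_nucleus, segmented_sites):
    """>= 95% of ground-truth sites are relabeled with their generating DxRy."""
    _, _, truth = sim_nucleus
    _, configs = segmented_sites
    hits = sum(
        1 for s in truth.sites
        if s.site_id in configs and configs[s.site_id].label == s.label
    )
    assert hits / len(truth.sites) >= 0.95
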