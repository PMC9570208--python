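"""LC-domain thresholding and morphometry.

The Feret oracle here is deliberately independent of the implementation:
brute-force maximum over all pairs of pixel-corner points, no convex hull,
no calipers.
"""

import numpy as np
import pytest

from laurdangp.domains import (
    ReferenceDistribution,
    build_reference_distribution,
    derive_threshold,
    extract_domains,
    feret_diameter,
    measure_domains,
    per_cell_domain_stats,
)
from laurdangp.gp import GPMap


def brute_force_feret(mask: np.ndarray) -> float:
    """All-pairs max distance over pixel-corner points (oracle)."""
    rr, cc = np.nonzero(mask)
    pts = np.concatenate(
        [np.stack([rr + dr, cc + dc], 1) for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)]
    ).astype(float)
    pts = np.unique(pts, axis=0)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def random_blob(rng, max_px=400) -> np.ndarray:
    """Connected random-walk blob with at most ``max_px`` pixels."""
    n_steps = int(rng.integers(1, max_px))
    steps = rng.integers(-1, 2, size=(n_steps, 2))
    path = np.cumsum(steps, axis=0)
    path -= path.min(axis=0)
    h, w = path.max(axis=0) + 1
    mask = np.zeros((h, w), dtype=bool)
    mask[path[:, 0], path[:, 1]] = True
    return mask


def _gp_map(gp: np.ndarray, defined=None) -> GPMap:
    defined = np.isfinite(gp) if defined is None else defined
    return GPMap(gp=np.where(defined, gp, np.nan), defined=defined, G=1.0,
                 pixel_size_um=1.0)


class TestReferenceDistribution:
    def _maps_and_masks(self, n_images=4, cells_per_image=6, px_per_cell=100):
        rng = np.random.default_rng(0)
        maps, masks = [], []
        side = int(np.sqrt(px_per_cell))
        for _ in range(n_images):
            gp = np.full((side, side * cells_per_image), np.nan)
            labels = np.zeros_like(gp, dtype=np.int32)
            for c in range(cells_per_image):
                sl = slice(side * c, side * (c + 1))
                gp[:, sl] = rng.uniform(0, 1, (side, side))
                labels[:, sl] = c + 1
            maps.append(_gp_map(gp))
            masks.append(labels)
        return maps, masks

    def test_pixel_count_conservation(self):
        maps, masks = self._maps_and_masks()
        ref = build_reference_distribution(maps, masks, n_cells=20, seed=0)
        assert ref.gp_values.size == 20 * 100

    def test_seed_determinism(self):
        maps, masks = self._maps_and_masks()
        a = build_reference_distribution(maps, masks, n_cells=20, seed=5)
        b = build_reference_distribution(maps, masks, n_cells=20, seed=5)
        assert a.cells == b.cells
        assert np.array_equal(a.gp_values, b.gp_values)

    def test_insufficient_cells_raise(self):
        maps, masks = self._maps_and_masks(n_images=1, cells_per_image=5)
        with pytest.raises(ValueError, match="reference stack"):
            build_reference_distribution(maps, masks, n_cells=20, seed=0)


class TestDeriveThreshold:
    def test_exact_percentile_of_even_grid(self):
        ref = ReferenceDistribution(np.linspace(0, 1, 1001), n_cells=1, source_group="DM")
        thr = derive_threshold(ref, percentile=75)
        assert thr.gp_star == pytest.approx(0.750, abs=1e-12)

    def test_constant_distribution(self):
        ref = ReferenceDistribution(np.full(100, 0.3), n_cells=1, source_group="DM")
        thr = derive_threshold(ref, percentile=75)
        assert thr.gp_star == pytest.approx(0.3)
        assert (ref.gp_values > thr.gp_star).sum() == 0

    def test_strict_exceedance_bound(self, rng):
        # fraction strictly above gp* is at most (100-p)% plus one-value slack
        for _ in range(20):
            n = int(rng.integers(3, 500))
            vals = rng.uniform(-1, 1, n)
            p = float(rng.uniform(5, 95))
            thr = derive_threshold(
                ReferenceDistribution(vals, n_cells=1, source_group="x"), percentile=p
            )
            frac = (vals > thr.gp_star).mean()
            assert frac <= (100 - p) / 100 + 1.0 / n + 1e-12

    def test_empty_distribution_raises(self):
        ref = ReferenceDistribution(np.array([]), n_cells=1, source_group="DM")
        with pytest.raises(ValueError, match="empty"):
            derive_threshold(ref)

    @pytest.mark.parametrize("p", [0, 100, -5])
    def test_invalid_percentile(self, p):
        ref = ReferenceDistribution(np.linspace(0, 1, 10), n_cells=1, source_group="DM")
        with pytest.raises(ValueError, match="percentile"):
            derive_threshold(ref, percentile=p)


class TestExtractDomains:
    def _thr(self, gp_star):
        from laurdangp.domains import DomainThreshold

        return DomainThreshold(gp_star=gp_star, percentile=75)

    def test_subthreshold_cell_has_no_domains(self):
        gp = np.full((16, 16), 0.4)
        labels = np.ones((16, 16), dtype=np.int32)
        dom = extract_domains(_gp_map(gp), labels, self._thr(0.5))
        assert dom.max() == 0

    def test_single_square_domain(self):
        gp = np.full((16, 16), 0.3)
        gp[4:9, 4:9] = 0.9
        labels = np.ones((16, 16), dtype=np.int32)
        dom = extract_domains(_gp_map(gp), labels, self._thr(0.5), min_px=2)
        assert dom.max() == 1
        assert (dom == 1).sum() == 25

    def test_threshold_is_strict(self):
        gp = np.full((8, 8), 0.5)
        labels = np.ones((8, 8), dtype=np.int32)
        assert extract_domains(_gp_map(gp), labels, self._thr(0.5)).max() == 0

    def test_min_px_filter(self):
        gp = np.full((16, 16), 0.0)
        gp[2, 2] = 0.9  # single pixel: shot-noise scale
        gp[8:10, 8:10] = 0.9
        labels = np.ones((16, 16), dtype=np.int32)
        dom = extract_domains(_gp_map(gp), labels, self._thr(0.5), min_px=2)
        assert dom.max() == 1
        assert not dom[2, 2]

    def test_domains_confined_to_cells(self):
        gp = np.full((16, 16), 0.9)
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4:12, 4:12] = 1
        dom = extract_domains(_gp_map(gp), labels, self._thr(0.5))
        assert not ((dom > 0) & (labels == 0)).any()

    def test_ground_truth_domain_count_recovered(self, dm_scene):
        # noise-free rendering with gp_fluid < gp* < gp_lc: exactly the
        # planted components must be found
        truth, gpm = dm_scene["truth"], dm_scene["gp_map"]
        dom = extract_domains(gpm, truth.cell_labels, self._thr(0.6), min_px=2)
        assert dom.max() == truth.domain_labels.max()
        assert np.array_equal(dom > 0, truth.domain_labels > 0)


class TestMeasureDomains:
    def test_square_matches_closed_form(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        (rec,) = measure_domains(labels, pixel_size_um=1.0)
        assert rec.area_um2 == pytest.approx(100.0)
        assert rec.perimeter_um == pytest.approx(40.0)
        assert rec.circularity == pytest.approx(np.pi / 4, abs=1e-9)
        assert rec.feret_um == pytest.approx(10 * np.sqrt(2), abs=1e-9)

    def test_bar_is_elongated(self):
        labels = np.zeros((8, 40), dtype=np.int32)
        labels[4, 5:35] = 1
        (rec,) = measure_domains(labels, pixel_size_um=1.0)
        assert rec.feret_um == pytest.approx(np.sqrt(30**2 + 1), abs=1e-9)
        assert rec.circularity < 0.2

    @pytest.mark.parametrize("radius", [20, 30, 40])
    def test_digitized_disc_circularity_near_one(self, radius):
        n = 2 * radius + 9
        yy, xx = np.mgrid[:n, :n]
        labels = (((yy - n // 2) ** 2 + (xx - n // 2) ** 2) <= radius**2).astype(np.int32)
        (rec,) = measure_domains(labels, pixel_size_um=1.0)
        assert rec.circularity == pytest.approx(1.0, abs=0.05)
        assert rec.feret_um == pytest.approx(2 * radius, abs=2.0)

    def test_disc_circularity_converges_monotonically(self):
        circs = []
        for radius in (5, 10, 20, 40):
            n = 2 * radius + 9
            yy, xx = np.mgrid[:n, :n]
            labels = (((yy - n // 2) ** 2 + (xx - n // 2) ** 2) <= radius**2).astype(
                np.int32
            )
            (rec,) = measure_domains(labels, pixel_size_um=1.0)
            circs.append(rec.circularity)
        assert np.all(np.diff(circs) > 0)
        assert circs[-1] <= 1.0

    def test_single_pixel_has_diagonal_feret(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[2, 2] = 1
        (rec,) = measure_domains(labels, pixel_size_um=0.05)
        assert rec.feret_um == pytest.approx(np.sqrt(2) * 0.05)

    def test_pixel_size_scales_lengths(self):
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[4:8, 4:8] = 1
        (r1,) = measure_domains(labels, pixel_size_um=1.0)
        (r2,) = measure_domains(labels, pixel_size_um=0.05)
        assert r2.feret_um == pytest.approx(r1.feret_um * 0.05)
        assert r2.area_um2 == pytest.approx(r1.area_um2 * 0.05**2)

    def test_empty_labels_empty_list(self):
        assert measure_domains(np.zeros((8, 8), dtype=np.int32), 1.0) == []

    def test_parent_cell_assignment(self):
        cells = np.zeros((16, 16), dtype=np.int32)
        cells[:, :8] = 1
        cells[:, 8:] = 2
        domains = np.zeros_like(cells)
        domains[4:6, 2:4] = 1
        domains[10:12, 10:12] = 2
        recs = measure_domains(domains, 1.0, cell_labels=cells)
        assert [r.cell_id for r in recs] == [1, 2]

    def test_isodiametric_inequality_on_random_blobs(self, rng):
        for _ in range(50):
            mask = random_blob(rng, max_px=200)
            recs = measure_domains(mask.astype(np.int32), pixel_size_um=1.0)
            for r in recs:
                assert r.feret_um + 1e-9 >= np.sqrt(4 * r.area_um2 / np.pi)


class TestFeretOracle:
    def test_calipers_equals_bruteforce_on_random_blobs(self, rng):
        for _ in range(60):
            mask = random_blob(rng, max_px=400)
            assert feret_diameter(mask) == pytest.approx(brute_force_feret(mask), abs=1e-9)

    @pytest.mark.parametrize(
        "builder",
        [
            pytest.param(lambda: np.ones((1, 1), bool), id="pixel"),
            pytest.param(lambda: np.ones((1, 17), bool), id="row"),
            pytest.param(lambda: np.ones((17, 1), bool), id="column"),
            pytest.param(lambda: np.eye(9, dtype=bool), id="diagonal"),
            pytest.param(lambda: np.ones((7, 13), bool), id="rectangle"),
        ],
    )
    def test_degenerate_shapes(self, builder):
        mask = builder()
        assert feret_diameter(mask) == pytest.approx(brute_force_feret(mask), abs=1e-9)


class TestPerCellStats:
    def test_counts_and_flags(self):
        cells = np.zeros((16, 24), dtype=np.int32)
        for c in range(3):
            cells[:, 8 * c : 8 * (c + 1)] = c + 1
        domains = np.zeros_like(cells)
        domains[2:5, 2:5] = 1   # cell 1
        domains[8:10, 2:4] = 2  # cell 1
        domains[4:7, 10:13] = 3  # cell 2
        recs = measure_domains(domains, 1.0, cell_labels=cells)
        stats = per_cell_domain_stats(recs, cells)
        assert stats["n_domains"].tolist() == [2, 1, 0]
        assert not stats.loc[2, "has_domains"]
        assert np.isnan(stats.loc[2, "mean_feret_um"])
        assert stats["n_domains"].sum() == len(recs)
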