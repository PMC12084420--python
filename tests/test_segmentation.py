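"""Nucleus/cell/droplet segmentation and NE-LD classification."""

import heapq

import numpy as np
import pytest
import scipy.ndimage as ndi

import srslipid as sl
from srslipid.segmentation import assign_droplets_to_cells, atrous_planes


def draw_ellipse(shape, center, axes, value=1000.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    mask = ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1
    img[mask] = value
    return img


class TestSegmentNuclei:
    def test_two_disjoint_ellipses_give_two_labels(self):
        img = draw_ellipse((80, 80), (20, 20), (10, 7)) + draw_ellipse(
            (80, 80), (55, 55), (9, 12)
        )
        labels = sl.segment_nuclei(img, min_area_px=30)
        assert labels.max() == 2

    def test_blank_image_gives_no_labels(self):
        assert sl.segment_nuclei(np.zeros((50, 50))).max() == 0

    def test_touching_ellipses_split_by_watershed(self):
        # two ellipses joined by a thin neck; centers must fall in
        # different labels after the distance-transform split
        img = draw_ellipse((80, 120), (40, 35), (16, 14)) + draw_ellipse(
            (80, 120), (40, 80), (16, 14)
        )
        img[38:43, 45:72] = 1000.0  # neck
        labels = sl.segment_nuclei(img, min_area_px=100, min_sep_px=12)
        assert labels.max() == 2
        assert labels[40, 35] != labels[40, 80]
        assert labels[40, 35] > 0 and labels[40, 80] > 0

    def test_small_objects_removed(self):
        img = draw_ellipse((60, 60), (30, 30), (10, 10))
        img[5, 5] = 1000.0
        labels = sl.segment_nuclei(img, min_area_px=50)
        assert labels.max() == 1


def dijkstra_label_oracle(nuclei, intensity, lam):
    """Small-grid shortest-path oracle, independent of the implementation's
    data structures: plain Dijkstra expanded per seed pixel."""
    h, w = nuclei.shape
    dist = np.full((h, w), np.inf)
    lab = np.zeros((h, w), dtype=int)
    heap = []
    for r in range(h):
        for c in range(w):
            if nuclei[r, c]:
                dist[r, c] = 0
                lab[r, c] = nuclei[r, c]
                heap.append((0.0, r, c, int(nuclei[r, c])))
    heapq.heapify(heap)
    while heap:
        d, r, c, l = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w) or nuclei[nr, nc]:
                continue
            nd = d + lam + abs(intensity[r, c] - intensity[nr, nc])
            if nd < dist[nr, nc]:
                dist[nr, nc] = nd
                lab[nr, nc] = l
                heapq.heappush(heap, (nd, nr, nc, l))
    return lab


class TestPropagateCells:
    def test_uniform_intensity_gives_voronoi_like_split(self):
        nuclei = np.zeros((21, 41), dtype=int)
        nuclei[10, 5] = 1
        nuclei[10, 35] = 2
        intensity = np.ones((21, 41))
        cells = sl.propagate_cells(nuclei, intensity, regularization=1.0,
                                   foreground=np.ones((21, 41), bool))
        # pixels clearly nearer one seed take its label
        assert cells[10, 10] == 1 and cells[10, 30] == 2
        assert np.all(cells > 0)

    def test_single_seed_claims_whole_foreground(self):
        nuclei = np.zeros((15, 15), dtype=int)
        nuclei[7, 7] = 1
        fg = np.ones((15, 15), bool)
        cells = sl.propagate_cells(nuclei, np.ones((15, 15)), foreground=fg)
        assert np.all(cells == 1)

    def test_no_nuclei_gives_background(self):
        out = sl.propagate_cells(np.zeros((10, 10), int), np.ones((10, 10)))
        assert np.all(out == 0)

    def test_boundary_follows_dark_ridge_and_matches_oracle(self):
        # bright field with a dark ridge off-center: crossing the ridge is
        # expensive, so the boundary snaps to it rather than the midline
        h, w = 15, 31
        intensity = np.full((h, w), 10.0)
        intensity[:, 20] = 0.0
        nuclei = np.zeros((h, w), dtype=int)
        nuclei[7, 3] = 1
        nuclei[7, 27] = 2
        fg = np.ones((h, w), bool)
        lam = 0.05
        cells = sl.propagate_cells(nuclei, intensity, regularization=lam, foreground=fg)
        oracle = dijkstra_label_oracle(nuclei, intensity, lam)
        assert np.array_equal(cells, oracle)
        assert np.all(cells[:, 15:20] == 1)  # seed 1 claims up to the ridge

    def test_every_nucleus_pixel_keeps_its_label(self):
        nuclei = np.zeros((20, 20), dtype=int)
        nuclei[2:5, 2:5] = 1
        nuclei[14:17, 14:17] = 2
        rng = np.random.default_rng(0)
        cells = sl.propagate_cells(nuclei, rng.uniform(0, 1, (20, 20)),
                                   foreground=np.ones((20, 20), bool))
        assert np.array_equal(cells[nuclei > 0], nuclei[nuclei > 0])


class TestDetectDropletsAtrous:
    def test_blank_image_no_droplets(self):
        assert sl.detect_droplets_atrous(np.zeros((64, 64))).max() == 0

    def test_single_gaussian_blob_detected_at_center(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0, 1.0, (64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        img += 10.0 * np.exp(-((rr - 30) ** 2 + (cc - 33) ** 2) / (2 * 2.0**2))
        labels = sl.detect_droplets_atrous(img)
        assert labels.max() == 1
        assert labels[30, 33] == 1

    def test_grid_of_disks_all_found_with_accurate_centroids(self):
        img = np.zeros((100, 100))
        centers = [(20 + 30 * i, 20 + 30 * j) for i in range(3) for j in range(3)]
        rr, cc = np.mgrid[0:100, 0:100]
        for r, c in centers:
            img[(rr - r) ** 2 + (cc - c) ** 2 <= 9] = 50.0
        labels = sl.detect_droplets_atrous(img)
        assert labels.max() == 9
        cents = ndi.center_of_mass(labels > 0, labels, index=range(1, 10))
        found = sorted((round(a), round(b)) for a, b in cents)
        for (fr, fc), (tr, tc) in zip(found, sorted(centers)):
            assert abs(fr - tr) <= 1 and abs(fc - tc) <= 1

    def test_translation_equivariance_in_interior(self):
        rng = np.random.default_rng(1)
        base = np.zeros((80, 80))
        rr, cc = np.mgrid[0:80, 0:80]
        base[(rr - 35) ** 2 + (cc - 35) ** 2 <= 9] = 30.0
        noise = rng.normal(0, 0.5, (80, 80))
        lab_a = sl.detect_droplets_atrous(base + noise)
        shifted = np.roll(np.roll(base, 7, axis=0), 5, axis=1) + noise
        lab_b = sl.detect_droplets_atrous(shifted)
        ca = ndi.center_of_mass(lab_a > 0)
        cb = ndi.center_of_mass(lab_b > 0)
        assert abs(cb[0] - ca[0] - 7) <= 1 and abs(cb[1] - ca[1] - 5) <= 1

    def test_wavelet_planes_reconstruct_image(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 5, (32, 32))
        levels = 4
        planes = atrous_planes(img, levels)
        # planes + final smooth = original (the transform is a decomposition)
        smooth = img - planes.sum(axis=0)
        assert np.allclose(planes.sum(axis=0) + smooth, img)
        assert smooth.std() < img.std()


class TestClassifyNeDroplets:
    def _masks(self):
        nuclei = np.zeros((20, 20), dtype=int)
        nuclei[5:15, 5:15] = 1
        droplets = np.zeros((20, 20), dtype=int)
        droplets[7:9, 7:9] = 1   # fully inside nucleus
        droplets[14:17, 10:12] = 2  # 1-row overlap at nucleus edge
        droplets[17:19, 2:4] = 3  # adjacent-but-outside
        return droplets, nuclei

    def test_overlap_rules(self):
        droplets, nuclei = self._masks()
        flags = sl.classify_ne_droplets(droplets, nuclei)
        assert flags == {1: True, 2: True, 3: False}

    def test_dilating_nucleus_is_monotone(self):
        droplets, nuclei = self._masks()
        before = sl.classify_ne_droplets(droplets, nuclei)
        grown = ndi.grey_dilation(nuclei, size=(5, 5))
        after = sl.classify_ne_droplets(droplets, grown)
        for lab, was_ne in before.items():
            if was_ne:
                assert after[lab]


class TestFilterSmallCells:
    def _disk_label(self, radius_px, shape=(200, 200)):
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        labels = np.zeros(shape, dtype=int)
        labels[(rr - 100) ** 2 + (cc - 100) ** 2 <= radius_px**2] = 1
        return labels

    def test_large_cell_kept(self):
        # radius 15 um at 1 um/px -> diameter 30 um >= 20 um threshold
        labels = self._disk_label(15)
        assert sl.filter_small_cells(labels, 20.0, 1.0).max() == 1

    def test_small_cell_removed(self):
        labels = self._disk_label(5)  # diameter ~10 um < 20 um
        assert sl.filter_small_cells(labels, 20.0, 1.0).max() == 0

    def test_empty_input(self):
        assert sl.filter_small_cells(np.zeros((10, 10), int), 20.0, 1.0).max() == 0


class TestDropletCellAssignment:
    def test_majority_overlap_and_orphan_rescue(self):
        cells = np.zeros((20, 20), dtype=int)
        cells[:, :10] = 1
        cells[:, 12:] = 2
        droplets = np.zeros((20, 20), dtype=int)
        droplets[5, 3:8] = 1  # inside cell 1
        droplets[10, 8:14] = 2  # straddles: 2 px in cell 1, 2 px in cell 2, 2 in gap
        droplets[15, 10:12] = 3  # entirely in the 2 px gap -> nearest cell
        assignment = assign_droplets_to_cells(droplets, cells)
        assert assignment[1] == 1
        assert assignment[2] in (1, 2)
        assert 3 in assignment

    def test_far_orphan_dropped(self):
        cells = np.zeros((30, 30), dtype=int)
        cells[0:5, 0:5] = 1
        droplets = np.zeros((30, 30), dtype=int)
        droplets[25:27, 25:27] = 1
        assert assign_droplets_to_cells(droplets, cells, max_dist_px=5.0) == {}


def test_label_partition_property(default_scene):
    """Cell labels partition the claimed foreground: label areas sum to the
    labeled area and do not leak into each other."""
    _, truth = default_scene
    cells = truth.cells
    areas = np.bincount(cells.ravel())
    assert areas[1:].sum() == np.count_nonzero(cells)
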