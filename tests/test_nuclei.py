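"""Nuclei morphometry: filters, clustering, shape, fusion, summaries."""

import math

import numpy as np
import pytest

from conftest import (
    brute_area_filter,
    brute_cluster_components,
    disk_mask,
    ellipse_mask,
    mask_from_blocks,
)
from myotubekit import nuclei as nuc
from myotubekit import synthetic as syn
from myotubekit.masks import LabeledMask, MaskError
from myotubekit.nuclei import UndefinedMetricError


def square_blocks(areas_px, gap=5):
    """Square blobs of the given pixel areas laid out on one row."""
    blocks, col = [], 2
    for i, area in enumerate(areas_px):
        side = int(round(math.sqrt(area)))
        blocks.append((i + 1, slice(2, 2 + side), slice(col, col + side)))
        col += side + gap
    h = 4 + max(int(round(math.sqrt(a))) for a in areas_px)
    return mask_from_blocks(blocks, shape=(h, col + 2), pixel_size=1.0)


# ----------------------------------------------------------------------
# area filter
# ----------------------------------------------------------------------

def test_area_filter_closed_interval():
    # areas 30..250 μm² with pixel_size 1: bounds 40 and 200 are retained
    mask = square_blocks([30, 40, 121, 196, 250])
    # adjust exact pixel counts: squares give 30? sqrt(30)=5.48 -> 5x5=25.
    # Build explicitly instead with rectangles of exact area.
    blocks = [
        (1, slice(0, 5), slice(0, 6)),     # 30 px²
        (2, slice(0, 5), slice(10, 18)),   # 40
        (3, slice(0, 10), slice(22, 34)),  # 120
        (4, slice(0, 10), slice(38, 58)),  # 200
        (5, slice(0, 10), slice(62, 87)),  # 250
    ]
    mask = mask_from_blocks(blocks, shape=(12, 90), pixel_size=1.0)
    kept = nuc.filter_nuclei_by_area(mask, 40, 200)
    assert sorted(r.label for r in kept) == [2, 3, 4]
    assert sorted(r.area for r in kept) == [40, 120, 200]


def test_area_filter_empty_mask():
    mask = LabeledMask(labels=np.zeros((10, 10), dtype=np.int64), pixel_size=1.0)
    assert nuc.filter_nuclei_by_area(mask) == []


def test_area_filter_matches_brute_force(rng):
    # random rectangular blobs, random calibration
    labels = np.zeros((120, 120), dtype=np.int64)
    lab = 0
    for _ in range(60):
        h, w = rng.integers(2, 9, size=2)
        r, c = rng.integers(0, 110, size=2)
        if np.any(labels[r : r + h, c : c + w]):
            continue
        lab += 1
        labels[r : r + h, c : c + w] = lab
    mask = LabeledMask(labels=labels, pixel_size=1.7)
    kept = {r.label for r in nuc.filter_nuclei_by_area(mask, 40, 200)}
    assert kept == brute_area_filter(labels, 1.7, 40, 200)


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

def test_two_distant_nuclei_are_isolated():
    # 1-px gap of 5 μm (pixel_size 1, 5 empty columns border-to-border)
    m = mask_from_blocks(
        [(1, slice(2, 6), slice(2, 6)), (2, slice(2, 6), slice(11, 15))],
        shape=(10, 20),
    )
    recs = nuc.cluster_nuclei(nuc.measure_nuclei(m), m, max_gap=3.0)
    assert all(r.is_isolated for r in recs)
    assert len({r.cluster_id for r in recs}) == 2


def test_single_linkage_chain():
    # A-B gap 2, B-C gap 2, A-C gap far: one cluster {A,B,C}
    m = mask_from_blocks(
        [
            (1, slice(2, 6), slice(2, 6)),
            (2, slice(2, 6), slice(7, 11)),   # boundary distance 2 μm to A
            (3, slice(2, 6), slice(12, 16)),  # 2 μm to B, 7 μm to A
        ],
        shape=(10, 22),
    )
    recs = nuc.cluster_nuclei(nuc.measure_nuclei(m), m, max_gap=3.0)
    assert len({r.cluster_id for r in recs}) == 1
    assert not any(r.is_isolated for r in recs)


def test_strict_inequality_at_threshold():
    # boundary rows 3 and 6: gap exactly 3.0 μm, "below 3 μm" -> NOT clustered
    m3 = mask_from_blocks(
        [(1, slice(0, 4), slice(0, 4)), (2, slice(6, 10), slice(0, 4))],
        shape=(12, 6),
    )
    recs = nuc.cluster_nuclei(nuc.measure_nuclei(m3), m3, max_gap=3.0)
    assert all(r.is_isolated for r in recs)
    # just below: rows 3 and 5 -> 2 μm
    m4 = mask_from_blocks(
        [(1, slice(0, 4), slice(0, 4)), (2, slice(5, 9), slice(0, 4))],
        shape=(12, 6),
    )
    recs = nuc.cluster_nuclei(nuc.measure_nuclei(m4), m4, max_gap=3.0)
    assert len({r.cluster_id for r in recs}) == 1


def test_single_nucleus_is_isolated_cluster():
    m = mask_from_blocks([(1, slice(2, 6), slice(2, 6))], shape=(8, 8))
    recs = nuc.cluster_nuclei(nuc.measure_nuclei(m), m)
    assert recs[0].is_isolated and recs[0].cluster_id == 0


def test_missing_label_raises():
    m = mask_from_blocks([(1, slice(2, 6), slice(2, 6))], shape=(8, 8))
    recs = nuc.measure_nuclei(m)
    bad = mask_from_blocks([(2, slice(2, 6), slice(2, 6))], shape=(8, 8))
    with pytest.raises(MaskError):
        nuc.cluster_nuclei(recs, bad)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clustering_matches_brute_force_on_synthetic_fields(seed):
    mask, truth = syn.generate_nuclei_field(
        syn.NucleiFieldParams(field_size=(384, 384), n_nuclei=25, seed=seed)
    )
    recs = nuc.cluster_nuclei(nuc.measure_nuclei(mask), mask, max_gap=3.0)
    got = {}
    for r in recs:
        got.setdefault(r.cluster_id, set()).add(r.label)
    got_sets = sorted(frozenset(s) for s in got.values())
    want_sets = sorted(
        brute_cluster_components(mask, [r.label for r in recs], 3.0)
    )
    assert got_sets == want_sets
    # and both recover the generator's planted clusters
    planted = sorted(
        frozenset(g.label) for _, g in truth.groupby("cluster_id")
    )
    assert got_sets == planted


def test_scale_consistency():
    """Same pixel grid, doubled pixel_size: areas ×4, topology preserved
    when the gap threshold is scaled identically."""
    mask, _ = syn.generate_nuclei_field(
        syn.NucleiFieldParams(field_size=(384, 384), n_nuclei=15, seed=7)
    )
    big = LabeledMask(labels=mask.labels, pixel_size=mask.pixel_size * 2)
    r1 = nuc.measure_nuclei(mask)
    r2 = nuc.measure_nuclei(big)
    assert np.allclose([x.area for x in r2], [4 * x.area for x in r1])
    c1 = nuc.cluster_nuclei(r1, mask, max_gap=3.0)
    c2 = nuc.cluster_nuclei(r2, big, max_gap=6.0)
    assert [x.cluster_id for x in c1] == [y.cluster_id for y in c2]


# ----------------------------------------------------------------------
# shape metrics
# ----------------------------------------------------------------------

def test_disk_eccentricity_near_zero():
    for radius in (10, 15, 25):
        m = disk_mask(radius)
        ecc, theta, degen = nuc.shape_metrics(m, 1)
        assert not degen
        assert ecc <= 0.05


def test_two_to_one_ellipse_eccentricity_and_orientation():
    m = ellipse_mask(a_px=24, b_px=12, theta_deg=0.0)
    ecc, theta, _ = nuc.shape_metrics(m, 1)
    assert ecc == pytest.approx(math.sqrt(3) / 2, abs=0.02)
    assert abs(theta) < 1.0


@pytest.mark.parametrize("angle", [-60.0, -30.0, 30.0, 45.0, 60.0])
def test_orientation_rotation_equivariance(angle):
    m = ellipse_mask(a_px=25, b_px=10, theta_deg=angle)
    _, theta, _ = nuc.shape_metrics(m, 1)
    assert theta == pytest.approx(angle, abs=1.0)


def test_eccentricity_matches_skimage():
    """Moment eccentricity agrees with the regionprops implementation."""
    from skimage.measure import regionprops

    for a, b, ang in [(20, 10, 30.0), (18, 16, -45.0), (25, 6, 75.0)]:
        m = ellipse_mask(a, b, ang)
        ecc, _, _ = nuc.shape_metrics(m, 1)
        rp = regionprops(m.labels)[0]
        assert ecc == pytest.approx(rp.eccentricity, abs=1e-6)


def test_single_pixel_degenerate():
    m = mask_from_blocks([(1, slice(3, 4), slice(3, 4))], shape=(8, 8))
    ecc, theta, degen = nuc.shape_metrics(m, 1)
    assert (ecc, theta, degen) == (0.0, 0.0, True)


def test_shape_invariance_translation_and_label():
    m1 = ellipse_mask(20, 8, 25.0)
    labels2 = np.zeros((80, 90), dtype=np.int64)
    rr, cc = np.nonzero(m1.labels)
    labels2[rr + 10, cc + 20] = 7
    m2 = LabeledMask(labels=labels2, pixel_size=1.0)
    assert nuc.shape_metrics(m1, 1) == pytest.approx(nuc.shape_metrics(m2, 7))


# ----------------------------------------------------------------------
# fusion index and marker fraction
# ----------------------------------------------------------------------

def _nuclei_grid(n, shape=(60, 60)):
    blocks = []
    for i in range(n):
        r, c = 5 + 10 * (i // 5), 5 + 10 * (i % 5)
        blocks.append((i + 1, slice(r, r + 4), slice(c, c + 4)))
    return mask_from_blocks(blocks, shape=shape)


def test_fusion_index_extremes_and_partial():
    nmask = _nuclei_grid(10)
    empty = LabeledMask(labels=np.zeros((60, 60), dtype=np.int64), pixel_size=1.0)
    assert nuc.fusion_index(nmask, empty) == 0.0
    full = LabeledMask(labels=np.ones((60, 60), dtype=np.int64), pixel_size=1.0)
    assert nuc.fusion_index(nmask, full) == 1.0
    # myotube covering the first 6 nuclei's centroids (rows 0..17 covers
    # first row of 5 plus one more at (15..19, 5..9))
    tube = np.zeros((60, 60), dtype=np.int64)
    tube[0:12, :] = 1
    tube[12:20, 0:12] = 2
    partial = LabeledMask(labels=tube, pixel_size=1.0)
    assert nuc.fusion_index(nmask, partial) == pytest.approx(0.6)


def test_fusion_index_zero_nuclei_signaled():
    empty = LabeledMask(labels=np.zeros((10, 10), dtype=np.int64), pixel_size=1.0)
    with pytest.raises(UndefinedMetricError):
        nuc.fusion_index(empty, empty)


def test_marker_fraction_counts():
    recs = nuc.measure_nuclei(_nuclei_grid(20))
    flags = [i < 7 for i in range(20)]
    assert nuc.marker_fraction(recs, flags) == pytest.approx(0.35)
    assert nuc.marker_fraction(recs, [True] * 20) == 1.0
    assert nuc.marker_fraction(recs, [False] * 20) == 0.0
    with pytest.raises(UndefinedMetricError):
        nuc.marker_fraction([], [])


# ----------------------------------------------------------------------
# field summary
# ----------------------------------------------------------------------

def _clustered(mask):
    return nuc.cluster_nuclei(nuc.measure_nuclei(mask), mask)


def test_summary_median_cluster_size_with_singletons():
    # sizes {1,1,3,5}: median over all clusters = 2
    blocks = []
    lab = 1
    col = 2
    for size in (1, 1, 3, 5):
        for _ in range(size):
            blocks.append((lab, slice(2, 6), slice(col, col + 4)))
            lab += 1
            col += 5  # boundary-centre distance 2 μm inside a cluster
        col += 5  # extra space: distance 7 μm to the next cluster
    mask = mask_from_blocks(blocks, shape=(10, col + 2))
    recs = _clustered(mask)
    summ = nuc.summarize_field(recs)
    assert summ.n_clusters == 4
    assert summ.median_cluster_size == 2.0
    summ2 = nuc.summarize_field(recs, include_singleton_clusters=False)
    assert summ2.median_cluster_size == 4.0


def test_summary_all_isolated():
    mask = _nuclei_grid(6)
    summ = nuc.summarize_field(_clustered(mask))
    assert summ.median_cluster_size == 1.0
    assert summ.n_clusters == 6


def test_summary_median_eccentricity_of_isolated():
    recs = _clustered(_nuclei_grid(3))
    for r, e in zip(recs, (0.2, 0.8, 0.9)):
        r.eccentricity = e
    summ = nuc.summarize_field(recs)
    assert summ.median_eccentricity == pytest.approx(0.8)


def test_orientation_histogram_concentrates_for_aligned_fields():
    mask, _ = syn.generate_nuclei_field(
        syn.NucleiFieldParams(n_nuclei=40, orientation_concentration=30.0, seed=5)
    )
    summ = nuc.summarize_field(_clustered(mask))
    counts, edges = summ.orientation_histogram
    centers = 0.5 * (edges[:-1] + edges[1:])
    assert counts[np.abs(centers) < 20].sum() >= 0.8 * counts.sum()


def test_singleton_only_generator_gives_all_isolated():
    mask, _ = syn.generate_nuclei_field(
        syn.NucleiFieldParams(
            n_nuclei=20, cluster_size_distribution={1: 1.0}, seed=11
        )
    )
    recs = _clustered(mask)
    assert all(r.is_isolated for r in recs)
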