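"""Nuclei-arrangement morphometry on segmentation label masks.

Given a calibrated nuclei label mask (e.g. exported from a Cellpose
segmentation), this module reproduces the quantities used to compare
nuclei organisation between culture substrates:

* per-nucleus area filtering (default 40–200 μm², closed interval),
* single-linkage clustering of nuclei whose border-to-border distance
  is below a gap threshold (default 3 μm),
* eccentricity and in-plane orientation of isolated nuclei from the
  central second moments of their pixel sets,
* fusion index (fraction of nuclei whose centroid lies inside a
  myotube mask) and marker-positive fractions,
* per-field summaries (median cluster size, median eccentricity of
  isolated nuclei, orientation histogram) that serve as the
  statistical observation unit downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .masks import LabeledMask, MaskError

#: Area filter bounds in μm² (closed interval).
DEFAULT_MIN_AREA = 40.0
DEFAULT_MAX_AREA = 200.0
#: Border-to-border clustering threshold in μm (strict inequality).
DEFAULT_MAX_GAP = 3.0


class UndefinedMetricError(ValueError):
    """A summary metric is undefined for the given population (e.g. n=0)."""


@dataclass
class NucleusRecord:
    """Morphometric record for one nucleus."""

    label: int
    area: float  # μm²
    centroid: tuple[float, float]  # (x, y) in μm
    eccentricity: float
    orientation: float  # degrees in [-90, 90), from +x axis, CCW positive
    degenerate_shape: bool = False  # single pixel: orientation undefined
    cluster_id: int | None = None
    is_isolated: bool | None = None
    marker_positive: bool | None = None


@dataclass
class FieldSummary:
    """Per-field aggregation: one such summary is one statistical unit."""

    n_nuclei_retained: int
    n_clusters: int
    median_cluster_size: float
    median_eccentricity: float | None  # over isolated nuclei only
    orientation_histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges deg)
    fusion_index: float | None = None
    marker_fraction: float | None = None


# ----------------------------------------------------------------------
# shape metrics
# ----------------------------------------------------------------------

def shape_metrics(mask: LabeledMask, label: int) -> tuple[float, float, bool]:
    """Eccentricity and orientation of one object's pixel set.

    The ellipse is matched to the central second moments of the pixel
    centres.  Eccentricity is ``sqrt(1 − λ_minor/λ_major)`` of the
    moment eigenvalues (0 for a disk, →1 for a line).  Orientation is
    the major-axis angle versus the image x axis, degrees in [−90, 90),
    counterclockwise positive with y up.

    Returns
    -------
    (eccentricity, orientation_deg, degenerate) — ``degenerate`` is True
    for single-pixel objects, which are reported as (0, 0, True).
    """
    coords = np.argwhere(mask.labels == label)
    if coords.size == 0:
        raise MaskError(f"label {label} absent from mask")
    if len(coords) == 1:
        return 0.0, 0.0, True
    x = coords[:, 1].astype(float)
    y = -coords[:, 0].astype(float)  # y up
    mu20 = np.var(x)
    mu02 = np.var(y)
    mu11 = np.mean((x - x.mean()) * (y - y.mean()))
    # eigenvalues of [[mu20, mu11], [mu11, mu02]]
    tr = mu20 + mu02
    det = mu20 * mu02 - mu11**2
    disc = max(tr * tr / 4 - det, 0.0)
    lam_major = tr / 2 + math.sqrt(disc)
    lam_minor = tr / 2 - math.sqrt(disc)
    if lam_major <= 0:
        return 0.0, 0.0, True
    ecc = math.sqrt(max(0.0, 1.0 - lam_minor / lam_major))
    theta = 0.5 * math.degrees(math.atan2(2 * mu11, mu20 - mu02))
    if theta >= 90.0:
        theta -= 180.0
    return ecc, theta, False


def measure_nuclei(mask: LabeledMask) -> list[NucleusRecord]:
    """Measure area, centroid and shape for every object in the mask."""
    records = []
    for label in mask.present_labels():
        coords = np.argwhere(mask.labels == label)
        area = len(coords) * mask.pixel_area
        cx = float(coords[:, 1].mean()) * mask.pixel_size
        cy = float(coords[:, 0].mean()) * mask.pixel_size
        ecc, theta, degen = shape_metrics(mask, int(label))
        records.append(
            NucleusRecord(
                label=int(label),
                area=area,
                centroid=(cx, cy),
                eccentricity=ecc,
                orientation=theta,
                degenerate_shape=degen,
            )
        )
    return records


def filter_nuclei_by_area(
    mask: LabeledMask,
    min_area: float = DEFAULT_MIN_AREA,
    max_area: float = DEFAULT_MAX_AREA,
) -> list[NucleusRecord]:
    """Retain nuclei with ``min_area ≤ area ≤ max_area`` (μm², closed).

    An empty mask yields an empty list, not an error.
    """
    if not (min_area < max_area):
        raise ValueError(f"min_area must be < max_area, got {min_area}, {max_area}")
    return [r for r in measure_nuclei(mask) if min_area <= r.area <= max_area]


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

def cluster_nuclei(
    records: Sequence[NucleusRecord],
    mask: LabeledMask,
    max_gap: float = DEFAULT_MAX_GAP,
) -> list[NucleusRecord]:
    """Single-linkage clustering on border-to-border distances.

    Two nuclei are linked iff the minimal Euclidean distance between
    their boundary pixel centres is strictly below ``max_gap`` (μm);
    clusters are the connected components of that graph, so a cluster
    may span more than ``max_gap`` end to end.  Singletons are flagged
    ``is_isolated``.

    Returns a new list of records with ``cluster_id`` (0-based, ordered
    by smallest member label) and ``is_isolated`` filled in.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be ≥ 0")
    present = set(int(v) for v in mask.present_labels())
    for r in records:
        if r.label not in present:
            raise MaskError(f"record label {r.label} absent from mask")
    n = len(records)
    if n == 0:
        return []

    # one KD-tree over all boundary pixels, tagged with the record index
    pts = []
    owner = []
    for i, r in enumerate(records):
        b = mask.boundary_pixels_um(r.label)
        pts.append(b)
        owner.append(np.full(len(b), i))
    pts_arr = np.concatenate(pts)
    owner_arr = np.concatenate(owner)
    tree = cKDTree(pts_arr)
    pairs = tree.query_pairs(r=max_gap, output_type="ndarray")
    edges = set()
    if len(pairs):
        d = np.linalg.norm(pts_arr[pairs[:, 0]] - pts_arr[pairs[:, 1]], axis=1)
        keep = d < max_gap  # strict: "below 3 μm"
        for a, b in pairs[keep]:
            ia, ib = int(owner_arr[a]), int(owner_arr[b])
            if ia != ib:
                edges.add((min(ia, ib), max(ia, ib)))
    if edges:
        rows, cols = zip(*edges)
        graph = coo_matrix(
            (np.ones(len(edges)), (rows, cols)), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    _, comp = connected_components(graph, directed=False)

    # relabel components by smallest member label for determinism
    order: dict[int, int] = {}
    for i in np.argsort([r.label for r in records]):
        c = int(comp[i])
        if c not in order:
            order[c] = len(order)
    sizes = np.bincount(comp)
    out = []
    for i, r in enumerate(records):
        c = int(comp[i])
        out.append(
            replace(r, cluster_id=order[c], is_isolated=bool(sizes[c] == 1))
        )
    return out


def cluster_sizes(records: Sequence[NucleusRecord]) -> np.ndarray:
    """Number of nuclei in each cluster (ordered by cluster id)."""
    ids = [r.cluster_id for r in records]
    if any(c is None for c in ids):
        raise ValueError("records are not clustered yet")
    return np.bincount(np.asarray(ids, dtype=int))


# ----------------------------------------------------------------------
# fractions
# ----------------------------------------------------------------------

def _centroid_label(mask: LabeledMask, centroid_um: tuple[float, float]) -> int:
    """Mask label at the pixel nearest to a (x, y) μm centroid."""
    cx, cy = centroid_um
    col = int(round(cx / mask.pixel_size))
    row = int(round(cy / mask.pixel_size))
    row = min(max(row, 0), mask.shape[0] - 1)
    col = min(max(col, 0), mask.shape[1] - 1)
    return int(mask.labels[row, col])


def fusion_index(
    nuclei_mask: LabeledMask,
    myotube_mask: LabeledMask,
    records: Sequence[NucleusRecord] | None = None,
) -> float:
    """Fraction of nuclei whose centroid lies inside any myotube object.

    The membership test is centroid-in-mask; nuclei straddling a myotube
    edge count by where their centre of mass falls.
    """
    if nuclei_mask.shape != myotube_mask.shape:
        raise MaskError("nuclei and myotube masks must share shape")
    if not np.isclose(nuclei_mask.pixel_size, myotube_mask.pixel_size):
        raise MaskError("nuclei and myotube masks must share pixel_size")
    if records is None:
        records = measure_nuclei(nuclei_mask)
    if len(records) == 0:
        raise UndefinedMetricError("fusion index undefined with zero nuclei")
    inside = sum(
        1 for r in records if _centroid_label(myotube_mask, r.centroid) > 0
    )
    return inside / len(records)


def marker_fraction(
    records: Sequence[NucleusRecord],
    flags: Mapping[int, bool] | Iterable[bool] | None = None,
) -> float:
    """Fraction of retained nuclei positive for a nuclear marker.

    ``flags`` maps nucleus label → bool, or is a sequence aligned with
    ``records``; if omitted, the records' ``marker_positive`` field is
    used (all must be set).
    """
    if len(records) == 0:
        raise UndefinedMetricError("marker fraction undefined with zero nuclei")
    if flags is None:
        vals = [r.marker_positive for r in records]
        if any(v is None for v in vals):
            raise ValueError("marker_positive not set on all records")
    elif isinstance(flags, Mapping):
        vals = [bool(flags[r.label]) for r in records]
    else:
        vals = [bool(v) for v in flags]
        if len(vals) != len(records):
            raise ValueError("one flag per retained nucleus required")
    return sum(vals) / len(records)


# ----------------------------------------------------------------------
# field summary
# ----------------------------------------------------------------------

def summarize_field(
    records: Sequence[NucleusRecord],
    include_singleton_clusters: bool = True,
    orientation_bins: int = 18,
    fusion: float | None = None,
    marker: float | None = None,
) -> FieldSummary:
    """Aggregate clustered records into one per-field summary.

    Median cluster size is computed over all clusters including
    singletons by default (set ``include_singleton_clusters=False`` to
    restrict to multi-nucleus aggregates).  Median eccentricity is
    computed over isolated nuclei only; it is ``None`` (and flagged by
    raising downstream if requested) when no nucleus is isolated.
    """
    if any(r.cluster_id is None for r in records):
        raise ValueError("run cluster_nuclei before summarize_field")
    sizes = cluster_sizes(records) if len(records) else np.array([], dtype=int)
    pop = sizes if include_singleton_clusters else sizes[sizes >= 2]
    if len(pop) == 0:
        raise UndefinedMetricError("no clusters in the selected population")
    iso_ecc = [
        r.eccentricity for r in records if r.is_isolated and not r.degenerate_shape
    ]
    med_ecc = float(np.median(iso_ecc)) if iso_ecc else None
    orients = [r.orientation for r in records if not r.degenerate_shape]
    hist = np.histogram(orients, bins=orientation_bins, range=(-90.0, 90.0))
    return FieldSummary(
        n_nuclei_retained=len(records),
        n_clusters=int(len(sizes)),
        median_cluster_size=float(np.median(pop)),
        median_eccentricity=med_ecc,
        orientation_histogram=hist,
        fusion_index=fusion,
        marker_fraction=marker,
    )
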