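"""Ground-truth-annotated synthetic inputs for every pipeline stage.

Real acquisitions behind the quantities this package computes (nuclei
masks, Ca²⁺ recordings, α-BTX masks, striation line profiles, Ct
tables) are not publicly deposited, so every analysis stage ships with
a generator that emulates the statistical structure the comparisons
assume and emits machine-readable ground truth alongside the data:

* nuclei fields — non-overlapping rasterized ellipses placed in
  spatial clusters with controlled border-to-border gaps, eccentricity
  and orientation anisotropy (uniform orientations on a "flat"-like
  substrate, concentrated near 0° on a "nanopattern"-like one);
* fluorescence traces — burst-locked transients with an instantaneous
  rise at each burst onset (the ~3.3 Hz acquisition cannot resolve the
  rise), monoexponential decay, log-linear run-down and Gaussian noise;
* AChR blob fields — non-overlapping disks with prescribed areas;
* striation profiles — Gaussian peak trains with exact peak spacing;
* Ct tables — per-gene baseline Ct shifted by log-efficiency of the
  true fold change, with ≥ 2 housekeeping genes held at fold 1.

All generators are pure functions of their parameters including the
seed.  Masks use rasterized area (pixel count × pixel_size²) as ground
truth, matching what the morphometry measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import vonmises

from .calcium import RESPONDER_THRESHOLD, StimulationProtocol
from .masks import LabeledMask

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


class PlacementError(RuntimeError):
    """Field too small/crowded to place objects without overlap."""


# ======================================================================
# nuclei fields
# ======================================================================

@dataclass(frozen=True)
class NucleiFieldParams:
    """Parameters of a synthetic nuclei field.

    ``cluster_size_distribution`` is a probability mapping over cluster
    sizes {1..max}.  ``orientation_concentration`` is the von Mises
    concentration of the (axial) orientation distribution: 0 means
    uniform in [−90, 90), large values align nuclei with the x axis.
    ``intra_cluster_gap`` is the target border-to-border gap (μm)
    between a cluster member and its nearest already-placed clustermate
    and must stay below the 3 μm clustering threshold; members of
    different clusters are kept at least ``min_intercluster_gap`` apart.
    """

    field_size: tuple[int, int] = (512, 512)  # (rows, cols) px
    pixel_size: float = 0.32  # μm/px (20× widefield)
    n_nuclei: int = 60
    cluster_size_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.05, 6: 0.05}
    )
    mean_eccentricity: float = 0.70
    eccentricity_sd: float = 0.10
    orientation_concentration: float = 0.0
    intra_cluster_gap: float = 1.0  # μm, target
    min_intercluster_gap: float = 8.0  # μm
    area_range: tuple[float, float] = (60.0, 150.0)  # μm²
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be ≥ 0")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        if not (0 <= self.mean_eccentricity < 1):
            raise ValueError("mean_eccentricity must be in [0, 1)")
        if self.orientation_concentration < 0:
            raise ValueError("orientation_concentration must be ≥ 0")
        probs = np.array(list(self.cluster_size_distribution.values()), float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("cluster_size_distribution must be a probability map")


def _draw_orientation(rng: np.random.Generator, kappa: float) -> float:
    """Axial orientation in degrees, [−90, 90): uniform at kappa=0,
    concentrated near 0° (x axis) for large kappa."""
    if kappa == 0:
        return float(rng.uniform(-90.0, 90.0))
    # axial data: von Mises on the doubled angle
    two_theta = vonmises.rvs(kappa, loc=0.0, random_state=rng)
    theta = math.degrees(two_theta) / 2.0
    if theta >= 90.0:
        theta -= 180.0
    if theta < -90.0:
        theta += 180.0
    return float(theta)


def _ellipse_pixels(
    cy: float, cx: float, a_px: float, b_px: float, theta_deg: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray] | None:
    """Row/col indices of a filled rotated ellipse; None if clipped."""
    th = math.radians(theta_deg)
    r = math.ceil(max(a_px, b_px)) + 1
    r0, r1 = int(math.floor(cy)) - r, int(math.ceil(cy)) + r
    c0, c1 = int(math.floor(cx)) - r, int(math.ceil(cx)) + r
    if r0 < 0 or c0 < 0 or r1 >= shape[0] or c1 >= shape[1]:
        return None
    rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    dx = cols - cx
    dy = -(rows - cy)  # y up
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    if not inside.any():
        return None
    return rows[inside], cols[inside]


def _boundary_um(rows: np.ndarray, cols: np.ndarray, pixel_size: float) -> np.ndarray:
    """8-connectivity boundary pixel centres (μm) of a pixel set."""
    from scipy import ndimage

    r0, c0 = rows.min() - 1, cols.min() - 1
    patch = np.zeros((rows.max() - r0 + 2, cols.max() - c0 + 2), bool)
    patch[rows - r0, cols - c0] = True
    interior = ndimage.binary_erosion(patch, structure=np.ones((3, 3), bool))
    br, bc = np.nonzero(patch & ~interior)
    return np.column_stack((br + r0, bc + c0)).astype(float) * pixel_size


def generate_nuclei_field(
    params: NucleiFieldParams,
) -> tuple[LabeledMask, pd.DataFrame]:
    """Rasterized, non-overlapping elliptical nuclei in spatial clusters.

    Returns the label mask (labels 1..n) and a ground-truth table with
    one row per nucleus: label, cluster id, centre (μm), rasterized
    area (μm²), drawn eccentricity and orientation, and axis lengths.
    Identical parameters (including seed) give identical output.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_size
    labels = np.zeros((h, w), dtype=np.int64)
    cols_truth: list[dict] = []

    # cluster sizes summing exactly to n_nuclei
    sizes_avail = np.array(sorted(params.cluster_size_distribution), int)
    probs = np.array(
        [params.cluster_size_distribution[s] for s in sizes_avail], float
    )
    probs = probs / probs.sum()
    cluster_sizes: list[int] = []
    remaining = params.n_nuclei
    while remaining > 0:
        s = int(rng.choice(sizes_avail, p=probs))
        s = min(s, remaining)
        cluster_sizes.append(s)
        remaining -= s

    placed_boundaries: list[np.ndarray] = []  # μm coords per nucleus
    placed_cluster: list[int] = []
    next_label = 1

    cluster_attempts = 30
    for cid, size in enumerate(cluster_sizes):
        for attempt in range(cluster_attempts):
            trial = _try_place_cluster(
                rng, params, labels, placed_boundaries, cid, size
            )
            if trial is not None:
                break
        else:
            raise PlacementError(
                f"could not place cluster {cid} (size {size}) after "
                f"{cluster_attempts} attempts of {params.max_retries} "
                "placements per nucleus"
            )
        for nuc in trial:
            rows, cols, bnd, meta = nuc
            labels[rows, cols] = next_label
            placed_boundaries.append(bnd)
            placed_cluster.append(cid)
            cols_truth.append(
                {
                    "label": next_label,
                    "cluster_id": cid,
                    "center_x_um": meta["cx"] * params.pixel_size,
                    "center_y_um": meta["cy"] * params.pixel_size,
                    "area_um2": len(rows) * params.pixel_size**2,
                    "eccentricity": meta["ecc"],
                    "orientation_deg": meta["theta"],
                    "major_um": meta["a_px"] * params.pixel_size,
                    "minor_um": meta["b_px"] * params.pixel_size,
                }
            )
            next_label += 1

    truth = pd.DataFrame(
        cols_truth,
        columns=[
            "label", "cluster_id", "center_x_um", "center_y_um", "area_um2",
            "eccentricity", "orientation_deg", "major_um", "minor_um",
        ],
    )
    return LabeledMask(labels=labels, pixel_size=params.pixel_size), truth


def _try_place_cluster(rng, params, labels, placed_boundaries, cid, size):
    """One attempt to place a whole cluster; None on failure."""
    px = params.pixel_size
    shape = labels.shape
    h, w = shape
    other_pts = (
        np.concatenate(placed_boundaries) if placed_boundaries else np.empty((0, 2))
    )
    other_tree = cKDTree(other_pts) if len(other_pts) else None

    members = []  # (rows, cols, boundary_um, meta)
    cluster_canvas = np.zeros(shape, dtype=bool)

    def draw_shape():
        area = rng.uniform(*params.area_range)
        ecc = float(np.clip(rng.normal(params.mean_eccentricity, params.eccentricity_sd), 0.0, 0.95))
        theta = _draw_orientation(rng, params.orientation_concentration)
        axis_ratio = math.sqrt(1.0 - ecc**2)  # b/a
        a_um = math.sqrt(area / (math.pi * axis_ratio))
        return a_um / px, (a_um * axis_ratio) / px, ecc, theta

    for j in range(size):
        ok = False
        for _ in range(params.max_retries):
            a_px, b_px, ecc, theta = draw_shape()
            if j == 0:
                m = a_px + 2
                if h - 1 - m <= m or w - 1 - m <= m:
                    continue
                cy = rng.uniform(m, h - 1 - m)
                cx = rng.uniform(m, w - 1 - m)
            else:
                # aim next to a random existing member
                anchor = members[rng.integers(len(members))][3]
                gap_um = params.intra_cluster_gap * rng.uniform(0.5, 1.0)
                ang = rng.uniform(0, 2 * math.pi)
                dist_px = anchor["a_px"] + a_px + gap_um / px
                cy = anchor["cy"] - dist_px * math.sin(ang)
                cx = anchor["cx"] + dist_px * math.cos(ang)
            pixset = _ellipse_pixels(cy, cx, a_px, b_px, theta, shape)
            if pixset is None:
                continue
            rows, cols = pixset
            if np.any(labels[rows, cols] != 0) or np.any(cluster_canvas[rows, cols]):
                continue
            bnd = _boundary_um(rows, cols, px)
            # distance to other clusters must stay comfortably above 3 μm
            if other_tree is not None:
                d_other, _ = other_tree.query(bnd, k=1)
                if d_other.min() < params.min_intercluster_gap:
                    continue
            if j > 0:
                d_same = min(
                    cKDTree(m[2]).query(bnd, k=1)[0].min() for m in members
                )
                # strictly inside the clustering threshold, never touching
                if not (0 < d_same < min(2.0 * params.intra_cluster_gap, 2.8)):
                    continue
            meta = {"cy": cy, "cx": cx, "a_px": a_px, "b_px": b_px, "ecc": ecc, "theta": theta}
            members.append((rows, cols, bnd, meta))
            cluster_canvas[rows, cols] = True
            ok = True
            break
        if not ok:
            return None
    return members


# ======================================================================
# fluorescence traces
# ======================================================================

@dataclass(frozen=True)
class TraceParams:
    """Parameters of one synthetic burst-stimulation recording.

    The trace starts ~``pre_baseline`` s before the first burst onset
    (t = 0); each burst adds an instantaneous-rise, monoexponential-
    decay transient; amplitudes run down log-linearly so the last burst
    is ``rundown_fraction`` × the first.  ``responder=False`` requires
    a sub-threshold first amplitude (< 0.5 ΔF/F0).
    """

    protocol: StimulationProtocol = field(default_factory=StimulationProtocol)
    sampling_rate: float = 3.3  # Hz
    baseline_F: float = 800.0  # a.u.
    responder: bool = True
    first_amplitude: float = 1.2  # ΔF/F0
    decay_tau: float = 2.0  # s
    rundown_fraction: float = 0.8
    noise_sd: float = 0.0  # a.u. (raw F scale)
    pre_baseline: float = 6.0  # s before first onset
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")
        if not (self.decay_tau > 0):
            raise ValueError("decay_tau must be > 0")
        if not (0 <= self.rundown_fraction <= 1):
            raise ValueError("rundown_fraction must be in [0, 1]")
        if self.baseline_F <= 0:
            raise ValueError("baseline_F must be > 0")
        if self.responder and self.first_amplitude <= RESPONDER_THRESHOLD:
            raise ValueError(
                "responder=True requires first_amplitude > 0.5 ΔF/F0"
            )
        if not self.responder and self.first_amplitude >= RESPONDER_THRESHOLD:
            raise ValueError(
                "responder=False requires first_amplitude < 0.5 ΔF/F0"
            )


@dataclass
class SyntheticTrace:
    """A raw synthetic recording plus its ground truth."""

    time: np.ndarray  # s, t = 0 at first burst onset
    F: np.ndarray  # raw intensity, a.u.
    params: TraceParams
    burst_amplitudes: np.ndarray  # true ΔF/F0 per burst


def burst_amplitudes(params: TraceParams) -> np.ndarray:
    """True per-burst ΔF/F0 amplitudes with log-linear run-down."""
    k = params.protocol.n_bursts
    if k == 1 or params.rundown_fraction == 1.0:
        return np.full(k, params.first_amplitude)
    expo = np.arange(k) / (k - 1)
    return params.first_amplitude * params.rundown_fraction**expo


def generate_trace(params: TraceParams) -> SyntheticTrace:
    """Synthesize one recording; pure function of ``params``.

    The sampling grid is aligned so that the first burst onset falls
    exactly on a sample, and transients superpose across bursts (with
    the default 2 s decay constant the inter-burst carry-over is < 1%).
    """
    dt = 1.0 / params.sampling_rate
    n_pre = int(round(params.pre_baseline * params.sampling_rate))
    n_total = n_pre + int(math.ceil(params.protocol.total_duration * params.sampling_rate)) + 1
    time = (np.arange(n_total) - n_pre) * dt
    amps = burst_amplitudes(params)
    rel = np.ones(n_total)
    for t_k, a_k in zip(params.protocol.burst_onsets, amps):
        after = time >= t_k - 1e-9
        rel[after] += a_k * np.exp(-(time[after] - t_k) / params.decay_tau)
    F = params.baseline_F * rel
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        F = F + rng.normal(0.0, params.noise_sd, n_total)
    return SyntheticTrace(time=time, F=F, params=params, burst_amplitudes=amps)


def generate_trace_cohort(
    n_cells: int,
    p_responder: float,
    seed: int = 0,
    responder_amplitude: tuple[float, float] = (0.6, 2.5),
    nonresponder_amplitude: tuple[float, float] = (0.02, 0.3),
    noise_sd: float = 8.0,
    **kwargs,
) -> list[SyntheticTrace]:
    """A cohort of cells with Bernoulli(p) responder status.

    Responder first amplitudes are drawn uniformly from
    ``responder_amplitude`` and non-responders from
    ``nonresponder_amplitude`` (both well clear of the 0.5 threshold).
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_cells):
        is_resp = bool(rng.random() < p_responder)
        lo, hi = responder_amplitude if is_resp else nonresponder_amplitude
        amp = float(rng.uniform(lo, hi))
        p = TraceParams(
            responder=is_resp,
            first_amplitude=amp,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31 - 1)),
            **kwargs,
        )
        out.append(generate_trace(p))
    return out


# ======================================================================
# AChR blob fields
# ======================================================================

def generate_achr_field(
    n_clusters: int,
    area_distribution,
    field_size: tuple[int, int] = (512, 512),
    pixel_size: float = 0.32,
    seed: int = 0,
    min_gap_um: float = 2.0,
    max_retries: int = 1000,
) -> tuple[LabeledMask, pd.DataFrame]:
    """Non-overlapping disk blobs with prescribed areas.

    ``area_distribution`` is either a sequence of explicit target areas
    (μm², length ``n_clusters``) or a ``(low, high)`` tuple for uniform
    sampling.  The truth table records the exact rasterized area of
    each blob, which is what the area filter measures.
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be ≥ 0")
    rng = np.random.default_rng(seed)
    if isinstance(area_distribution, tuple) and len(area_distribution) == 2:
        areas = rng.uniform(*area_distribution, size=n_clusters)
    else:
        areas = np.asarray(list(area_distribution), float)
        if len(areas) != n_clusters:
            raise ValueError("need one target area per blob")
    h, w = field_size
    labels = np.zeros((h, w), dtype=np.int64)
    centers: list[tuple[float, float, float]] = []  # (cy, cx, r) px
    rows_out = []
    for i, area in enumerate(areas):
        r_px = math.sqrt(area / math.pi) / pixel_size
        m = math.ceil(r_px) + 3
        if h - 1 - m <= m or w - 1 - m <= m:
            raise PlacementError(f"field too small for blob {i} (area {area} μm²)")
        pix = None
        for _ in range(max_retries):
            cy = rng.uniform(m, h - 1 - m)
            cx = rng.uniform(m, w - 1 - m)
            if not all(
                math.hypot(cy - oy, cx - ox) > r_px + orr + min_gap_um / pixel_size
                for oy, ox, orr in centers
            ):
                continue
            pix = _ellipse_pixels(cy, cx, r_px, r_px, 0.0, (h, w))
            if pix is not None:
                break
        if pix is None:
            raise PlacementError(f"could not place blob {i} after {max_retries} tries")
        rr, cc = pix
        labels[rr, cc] = i + 1
        centers.append((cy, cx, r_px))
        rows_out.append(
            {
                "label": i + 1,
                "target_area_um2": float(area),
                "raster_area_um2": len(rr) * pixel_size**2,
                "center_x_um": cx * pixel_size,
                "center_y_um": cy * pixel_size,
            }
        )
    truth = pd.DataFrame(
        rows_out,
        columns=["label", "target_area_um2", "raster_area_um2", "center_x_um", "center_y_um"],
    )
    return LabeledMask(labels=labels, pixel_size=pixel_size), truth


# ======================================================================
# striation profiles
# ======================================================================

def generate_striation_profile(
    period: float,
    n_periods: int = 10,
    peak_width: float = 0.8,
    noise_sd: float = 0.0,
    sampling: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Periodic Gaussian peak train emulating an α-actinin line profile.

    ``period`` is the exact peak-to-peak distance (μm), ``peak_width``
    the FWHM of each Gaussian peak, ``sampling`` the position step
    (μm/sample; must not be coarser than the peak width).  Returns
    (positions_um, intensity).
    """
    if n_periods < 3:
        raise ValueError("n_periods must be ≥ 3")
    if not (period > peak_width):
        raise ValueError("period must exceed peak_width")
    if sampling > peak_width:
        raise ValueError("sampling coarser than peak_width cannot resolve peaks")
    sigma = peak_width / _GAUSS_FWHM
    length = (n_periods + 1) * period
    positions = np.arange(0.0, length + sampling / 2, sampling)
    peaks = period * (np.arange(n_periods) + 1.0)
    intensity = np.zeros_like(positions)
    for p in peaks:
        intensity += np.exp(-((positions - p) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, len(positions))
    return positions, intensity


# ======================================================================
# Ct tables
# ======================================================================

def generate_ct_table(
    genes: list[str],
    conditions: list[str],
    replicates: int,
    true_fold_changes: pd.DataFrame | dict,
    hk_genes: list[str],
    reference_condition: str,
    noise_sd: float = 0.0,
    sample_offset_sd: float = 0.0,
    base_ct: dict[str, float] | None = None,
    efficiency: float = 2.0,
    seed: int = 0,
):
    """Synthetic Ct table inverting exactly under geNorm at zero noise.

    ``true_fold_changes`` maps gene → {condition → fold vs reference};
    housekeeping genes must have fold 1 everywhere (and at least two of
    them are required).  Each sample may carry a global Ct offset
    (``sample_offset_sd``) emulating pipetting/loading differences,
    which the normalization factor absorbs.

    Returns ``(CtTable, truth)`` where truth is the fold-change matrix
    (genes × conditions) the pipeline should recover.
    """
    from .qpcr import CtTable  # local import to avoid cycle

    if len(hk_genes) < 2:
        raise ValueError("at least 2 housekeeping genes required")
    if reference_condition not in conditions:
        raise ValueError("reference_condition must be one of conditions")
    fc = pd.DataFrame(true_fold_changes).T if isinstance(true_fold_changes, dict) else true_fold_changes.copy()
    fc = fc.reindex(index=genes, columns=conditions)
    if fc.isna().any().any():
        raise ValueError("true_fold_changes must cover every gene × condition")
    for g in hk_genes:
        if g not in genes:
            raise ValueError(f"housekeeping gene {g} not in genes")
        if not np.allclose(fc.loc[g], 1.0):
            raise ValueError(f"housekeeping gene {g} must have unit fold change")
    if not np.allclose(fc[reference_condition], 1.0):
        raise ValueError("fold changes must be 1 in the reference condition")

    rng = np.random.default_rng(seed)
    if base_ct is None:
        base_ct = {g: (18.0 if g in hk_genes else 24.0) for g in genes}
    log_e = np.log(efficiency)
    samples, cond_map = [], {}
    data = {}
    for cond in conditions:
        for r in range(replicates):
            s = f"{cond}_{r + 1}"
            samples.append(s)
            cond_map[s] = cond
            offset = rng.normal(0.0, sample_offset_sd) if sample_offset_sd > 0 else 0.0
            col = []
            for g in genes:
                ct = base_ct[g] - math.log(fc.loc[g, cond]) / log_e + offset
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                col.append(ct)
            data[s] = col
    ct = pd.DataFrame(data, index=genes)
    table = CtTable(
        ct=ct,
        conditions=cond_map,
        hk_genes=hk_genes,
        reference_condition=reference_condition,
        efficiency=efficiency,
    )
    return table, fc
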