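"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths:
boundary distances are computed with explicit neighbour loops and
``cdist``, connected components with a hand-rolled BFS, and exact
rank-sum p values by exhaustive enumeration of group assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from myotubekit.masks import LabeledMask


# ----------------------------------------------------------------------
# brute-force oracles
# ----------------------------------------------------------------------

def brute_boundary_pixels(labels: np.ndarray, lab: int) -> np.ndarray:
    """Boundary pixels by explicit 8-neighbour inspection."""
    coords = np.argwhere(labels == lab)
    pix = {tuple(c) for c in coords}
    out = []
    for r, c in pix:
        is_boundary = False
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and (r + dr, c + dc) not in pix:
                    is_boundary = True
        if is_boundary:
            out.append((r, c))
    return np.asarray(out, dtype=float)


def brute_cluster_components(
    mask: LabeledMask, labs: list[int], max_gap: float
) -> list[frozenset[int]]:
    """Single-linkage components from all-pairs boundary distances."""
    bounds = {
        lab: brute_boundary_pixels(mask.labels, lab) * mask.pixel_size
        for lab in labs
    }
    adj: dict[int, set[int]] = {lab: set() for lab in labs}
    for a, b in itertools.combinations(labs, 2):
        if cdist(bounds[a], bounds[b]).min() < max_gap:
            adj[a].add(b)
            adj[b].add(a)
    seen: set[int] = set()
    comps = []
    for lab in labs:
        if lab in seen:
            continue
        comp, queue = {lab}, [lab]
        while queue:
            cur = queue.pop()
            for nxt in adj[cur]:
                if nxt not in comp:
                    comp.add(nxt)
                    queue.append(nxt)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def brute_area_filter(
    labels: np.ndarray, pixel_size: float, min_area: float, max_area: float
) -> set[int]:
    """Labels retained by per-pixel counting (closed interval)."""
    keep = set()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        area = int((labels == lab).sum()) * pixel_size**2
        if min_area <= area <= max_area:
            keep.add(int(lab))
    return keep


def exact_ranksum_p(group_a, group_b) -> float:
    """Exhaustive-permutation two-sided rank-sum p value.

    Counts assignments whose rank sum deviates from the null mean by at
    least the observed deviation (ties at the observed deviation counted
    fully), over all C(N, n_a) group assignments.
    """
    from scipy.stats import rankdata

    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    n1, N = len(a), len(a) + len(b)
    ranks = rankdata(np.concatenate([a, b]))
    mu = n1 * (N + 1) / 2.0
    w_obs = ranks[:n1].sum()
    dev = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(N), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
            count += 1
    return count / total


# ----------------------------------------------------------------------
# mask construction helpers
# ----------------------------------------------------------------------

def mask_from_blocks(blocks, shape, pixel_size=1.0) -> LabeledMask:
    """Build a mask from (label, row-slice, col-slice) rectangles."""
    labels = np.zeros(shape, dtype=np.int64)
    for lab, rs, cs in blocks:
        labels[rs, cs] = lab
    return LabeledMask(labels=labels, pixel_size=pixel_size)


def disk_mask(radius_px: int, pad: int = 3, pixel_size: float = 1.0) -> LabeledMask:
    n = 2 * (radius_px + pad) + 1
    c = radius_px + pad
    rr, cc = np.mgrid[0:n, 0:n]
    labels = (((rr - c) ** 2 + (cc - c) ** 2) <= radius_px**2).astype(np.int64)
    return LabeledMask(labels=labels, pixel_size=pixel_size)


def ellipse_mask(
    a_px: float, b_px: float, theta_deg: float = 0.0, pixel_size: float = 1.0
) -> LabeledMask:
    """Filled rotated ellipse (same angle convention as the package:
    +x axis, CCW positive, y up)."""
    n = 2 * (int(math.ceil(max(a_px, b_px))) + 3) + 1
    c = n // 2
    rr, cc = np.mgrid[0:n, 0:n]
    th = math.radians(theta_deg)
    dx = cc - c
    dy = -(rr - c)
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    labels = (((u / a_px) ** 2 + (v / b_px) ** 2) <= 1.0).astype(np.int64)
    return LabeledMask(labels=labels, pixel_size=pixel_size)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
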