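"""Spatial geometry of modules on the electrode lattice.

Two summary statistics characterise a module's footprint: its diameter,
estimated as twice the radius of gyration of its member electrodes
(2 R_g, the RMS distance to the module centroid for equal masses), and
its compactness, the fraction of all electrodes inside the module's
convex hull that actually belong to the module (1 for a spatially
contiguous, convex module).  Boundary analysis builds distance-matched
pairs: electrodes on a module's hull that have both a lattice nearest
neighbour inside the module and one outside, so within- and
across-boundary comparisons are made at exactly one pitch separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .layout import ArrayLayout

__all__ = [
    "ModuleGeometry",
    "BoundaryPairSet",
    "module_diameter",
    "module_compactness",
    "module_geometry",
    "boundary_pairs",
    "boundary_gc_contrast",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class ModuleGeometry:
    """Per-module spatial summaries for one partition (one layer)."""

    centroid: dict
    diameter: dict
    compactness: dict
    hull_vertices: dict


@dataclass
class BoundaryPairSet:
    """Distance-matched electrode pairs at module boundaries.

    For each module, ``inside[m]`` holds (boundary electrode, neighbour
    inside the module) pairs and ``outside[m]`` (boundary electrode,
    neighbour outside) pairs; every pair is separated by exactly one
    lattice pitch.
    """

    inside: dict = field(default_factory=dict)
    outside: dict = field(default_factory=dict)
    pitch: float = np.nan


def _module_ids(labels: np.ndarray) -> np.ndarray:
    return np.unique(np.asarray(labels))


def module_diameter(labels: np.ndarray, layout: ArrayLayout) -> dict:
    """Module diameter 2 R_g (mm) for every module in ``labels``."""
    labels = np.asarray(labels)
    out = {}
    for m in _module_ids(labels):
        pts = layout.coords[labels == m]
        centroid = pts.mean(axis=0)
        rg = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
        out[int(m)] = 2.0 * rg
    return out


def _hull_contains(pts: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Boolean mask of query points inside or on the convex hull of pts.

    Degenerate hulls (single point, collinear sets) are treated as the
    point/segment itself; lattice points exactly on a hull edge count as
    inside, so rectangular modules reach compactness 1.
    """
    pts = np.asarray(pts, dtype=float)
    if len(pts) == 1:
        return np.linalg.norm(query - pts[0], axis=1) < _EPS
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # collinear: project on the principal axis of the segment
        centroid = pts.mean(axis=0)
        d = pts - centroid
        axis = d[np.argmax(np.linalg.norm(d, axis=1))]
        norm = np.linalg.norm(axis)
        if norm < _EPS:
            return np.linalg.norm(query - centroid, axis=1) < _EPS
        axis = axis / norm
        proj = (query - centroid) @ axis
        perp = (query - centroid) - proj[:, None] * axis
        lims = (pts - centroid) @ axis
        on_line = np.linalg.norm(perp, axis=1) < _EPS
        return on_line & (proj >= lims.min() - _EPS) & (proj <= lims.max() + _EPS)
    a, b = hull.equations[:, :-1], hull.equations[:, -1]
    return np.all(query @ a.T + b <= _EPS, axis=1)


def module_compactness(labels: np.ndarray, layout: ArrayLayout) -> dict:
    """Members / all electrodes within each module's convex hull."""
    labels = np.asarray(labels)
    out = {}
    for m in _module_ids(labels):
        members = labels == m
        inside = _hull_contains(layout.coords[members], layout.coords)
        out[int(m)] = float(members.sum() / inside.sum())
    return out


def module_geometry(labels: np.ndarray, layout: ArrayLayout) -> ModuleGeometry:
    """Centroid, diameter, compactness and hull vertices per module."""
    labels = np.asarray(labels)
    centroid, hull_v = {}, {}
    for m in _module_ids(labels):
        pts = layout.coords[labels == m]
        centroid[int(m)] = tuple(pts.mean(axis=0))
        idx = np.nonzero(labels == m)[0]
        if len(pts) >= 3:
            try:
                hull_v[int(m)] = [int(idx[v]) for v in ConvexHull(pts).vertices]
            except QhullError:
                hull_v[int(m)] = [int(i) for i in idx]
        else:
            hull_v[int(m)] = [int(i) for i in idx]
    return ModuleGeometry(
        centroid=centroid,
        diameter=module_diameter(labels, layout),
        compactness=module_compactness(labels, layout),
        hull_vertices=hull_v,
    )


def boundary_pairs(labels: np.ndarray, layout: ArrayLayout) -> BoundaryPairSet:
    """Distance-matched boundary pairs for every module.

    Boundary electrodes are module members lying on the module's convex
    hull.  An electrode qualifies if it has at least one lattice
    4-neighbour inside its module and at least one outside; both pair
    lists then sit at identical (one pitch) distance.
    """
    labels = np.asarray(labels)
    mods = _module_ids(labels)
    if len(mods) < 2:
        result = BoundaryPairSet(pitch=layout.pitch)
        for m in mods:
            result.inside[int(m)] = []
            result.outside[int(m)] = []
        return result
    result = BoundaryPairSet(pitch=layout.pitch)
    for m in mods:
        member_idx = np.nonzero(labels == m)[0]
        pts = layout.coords[member_idx]
        if len(pts) >= 3:
            try:
                hull = ConvexHull(pts)
                a, b = hull.equations[:, :-1], hull.equations[:, -1]
                on_hull = np.any(np.abs(pts @ a.T + b) < _EPS, axis=1)
                boundary = member_idx[on_hull]
            except QhullError:
                boundary = member_idx
        else:
            boundary = member_idx
        ins, outs = [], []
        for e in boundary:
            nb = layout.lattice_neighbors(int(e))
            nb_in = [u for u in nb if labels[u] == m]
            nb_out = [u for u in nb if labels[u] != m]
            if nb_in and nb_out:
                ins.extend((int(e), u) for u in nb_in)
                outs.extend((int(e), u) for u in nb_out)
        if not ins:
            logger.info("module %s has no qualifying boundary electrodes", m)
        result.inside[int(m)] = ins
        result.outside[int(m)] = outs
    return result


def boundary_gc_contrast(adjacency: np.ndarray, pairs: BoundaryPairSet) -> dict:
    """Mean GC for boundary-inside vs boundary-outside pairs, per module.

    Each unordered pair contributes the average of its two directed
    weights.  Modules with an empty pair list are excluded from the
    pooled means.  Returns per-module means (paired-test inputs) and
    pooled means.
    """
    adjacency = np.asarray(adjacency)
    per_module = {}
    for m in pairs.inside:
        ins, outs = pairs.inside[m], pairs.outside[m]
        if not ins or not outs:
            continue
        w_in = np.mean([(adjacency[a, b] + adjacency[b, a]) / 2 for a, b in ins])
        w_out = np.mean([(adjacency[a, b] + adjacency[b, a]) / 2 for a, b in outs])
        per_module[m] = (float(w_in), float(w_out))
    inside_means = [v[0] for v in per_module.values()]
    outside_means = [v[1] for v in per_module.values()]
    return {
        "per_module": per_module,
        "inside_mean": float(np.mean(inside_means)) if inside_means else np.nan,
        "outside_mean": float(np.mean(outside_means)) if outside_means else np.nan,
    }
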