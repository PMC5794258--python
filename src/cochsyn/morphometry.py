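"""Geometric classification of synaptic vesicles in electron micrographs.

Vesicles are assigned to pools by distance criteria measured from the
vesicle membrane (center distance minus radius) to the nearest point of
the target structure:

* membrane-proximal (MP): within 25 nm of the active-zone membrane and
  within 80 nm of the presynaptic density (PD),
* ribbon-associated (RA): within 80 nm of the ribbon outline (first layer)
  and not MP — ribbon-occupied synapses,
* PD-associated (PDA): within 80 nm of the PD and not MP — ribbonless
  synapses,
* other: everything else.

An extended criterion (50 nm membrane / 100 nm PD) used for tomogram
analysis is available via ``mode="extended"``.  Thresholds are inclusive.
Coordinates are 2D (nm); the same rules apply verbatim to 3D point sets
when 3-component coordinates are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import LineString, Point, Polygon

MP_MEMBRANE_NM = 25.0
MP_PD_NM = 80.0
POOL_NM = 80.0
MP_MEMBRANE_EXT_NM = 50.0
MP_PD_EXT_NM = 100.0


@dataclass
class VesicleRecord:
    """A synaptic vesicle: center plus horizontal/vertical outer diameters."""

    center: Tuple[float, ...]
    diameter_h: float
    diameter_v: float
    tethers: Optional[int] = None

    def __post_init__(self) -> None:
        if self.diameter_h <= 0 or self.diameter_v <= 0:
            raise ValueError("diameters must be positive")
        if self.tethers is not None and self.tethers < 0:
            raise ValueError("tether count must be >= 0")

    @property
    def diameter(self) -> float:
        """Mean of the horizontal and vertical outer diameters."""
        return 0.5 * (self.diameter_h + self.diameter_v)

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass
class AZGeometry:
    """Active-zone geometry: membrane polyline, PD segment(s), ribbon."""

    membrane: np.ndarray                       # (n, 2) polyline, nm
    pd_segments: List[np.ndarray]              # each (m, 2) polyline on the membrane
    ribbon: Optional[np.ndarray] = None        # (k, 2) polygon outline
    psd: Optional[np.ndarray] = None           # (j, 2) polyline

    def __post_init__(self) -> None:
        self.membrane = np.asarray(self.membrane, dtype=float)
        self.pd_segments = [np.asarray(p, dtype=float)
                            for p in self.pd_segments]
        if self.ribbon is not None:
            self.ribbon = np.asarray(self.ribbon, dtype=float)
        if self.psd is not None:
            self.psd = np.asarray(self.psd, dtype=float)


def _dist_to_polyline(point: np.ndarray, line: np.ndarray) -> float:
    if len(line) == 1:
        return float(np.linalg.norm(point - line[0]))
    return float(Point(point).distance(LineString(line)))


def _dist_to_polygon_outline(point: np.ndarray, poly: np.ndarray) -> float:
    """Distance to the polygon boundary; 0 inside."""
    pg = Polygon(poly)
    p = Point(point)
    if pg.contains(p):
        return 0.0
    return float(p.distance(pg.exterior))


def membrane_distance(vesicle: VesicleRecord, structure: np.ndarray,
                      polygon: bool = False) -> float:
    """Distance from the vesicle membrane to a structure (may be negative
    when the vesicle overlaps it)."""
    c = np.asarray(vesicle.center, dtype=float)
    if polygon:
        d = _dist_to_polygon_outline(c, structure)
    else:
        d = _dist_to_polyline(c, structure)
    return d - vesicle.radius


def classify_pools(vesicles: Sequence[VesicleRecord], geometry: AZGeometry,
                   mode: str = "standard") -> List[str]:
    """Label each vesicle as ``MP``, ``RA``, ``PDA`` or ``other``.

    Ribbon-occupied active zones (geometry carries a ribbon outline) use the
    MP/RA pools; ribbonless ones use MP/PDA.  ``mode="extended"`` applies
    the 50/100 nm membrane-proximal criterion and no RA pool (as used for
    electron tomograms without explicit first-layer tracing).
    """
    if mode == "standard":
        mp_mem, mp_pd = MP_MEMBRANE_NM, MP_PD_NM
        use_ra = geometry.ribbon is not None
    elif mode == "extended":
        mp_mem, mp_pd = MP_MEMBRANE_EXT_NM, MP_PD_EXT_NM
        use_ra = False
    else:
        raise ValueError("mode must be 'standard' or 'extended'")

    labels = []
    for ves in vesicles:
        d_mem = membrane_distance(ves, geometry.membrane)
        d_pd = min(membrane_distance(ves, seg)
                   for seg in geometry.pd_segments)
        if d_mem <= mp_mem and d_pd <= mp_pd:
            labels.append("MP")
            continue
        if use_ra:
            d_rib = membrane_distance(ves, geometry.ribbon, polygon=True)
            labels.append("RA" if d_rib <= POOL_NM else "other")
        else:
            labels.append("PDA" if d_pd <= POOL_NM else "other")
    return labels


def pool_counts_and_fractions(labels: Sequence[str]) -> Dict[str, Dict[str, float]]:
    """Counts and fractions per pool (fractions over all counted vesicles)."""
    if not labels:
        raise ValueError("empty label set")
    counts: Dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    total = len(labels)
    return {"counts": {k: float(v) for k, v in counts.items()},
            "fractions": {k: v / total for k, v in counts.items()},
            "total": {"n": float(total)}}


def polyline_length(line: np.ndarray) -> float:
    line = np.asarray(line, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(line, axis=0), axis=1)))


def structure_metrics(geometry: AZGeometry) -> Dict[str, float]:
    """PD length, PSD length and ribbon height/width/area.

    The PD (and PSD) length is the arc length along the membrane; ribbon
    height and width are the extents along the principal axes of its
    outline (height = long axis) and the area is the shoelace polygon
    area.  Raises on self-intersecting ribbon outlines.
    """
    out: Dict[str, float] = {
        "pd_length": sum(polyline_length(seg) for seg in geometry.pd_segments)
    }
    if geometry.psd is not None:
        out["psd_length"] = polyline_length(geometry.psd)
    if geometry.ribbon is not None:
        poly = Polygon(geometry.ribbon)
        if not poly.is_valid:
            raise ValueError("self-intersecting ribbon outline")
        # densely sample the boundary so principal axes reflect the shape
        boundary = poly.exterior
        n = max(int(boundary.length / max(boundary.length / 200.0, 1e-9)), 4)
        pts = np.array([boundary.interpolate(i / n, normalized=True).coords[0]
                        for i in range(n)])
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt.T
        ext = np.ptp(proj, axis=0)
        out["ribbon_height"] = float(np.max(ext))
        out["ribbon_width"] = float(np.min(ext))
        out["ribbon_area"] = float(poly.area)
    return out
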