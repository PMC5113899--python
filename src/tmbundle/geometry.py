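"""Helix-bundle axis, axial radius of gyration, compactness and handedness.

Because rough transmembrane models carry no explicit membrane, bundle
compactness is measured about an average axis inferred from the helices
themselves: each TM segment gets two 4-residue capping zones, cap-midpoint
pairs define candidate axis segments, and these are averaged (longest
first, orientation-aligned so antiparallel helices do not cancel).  The
axial radius of gyration (RoG) about this axis is computed under three
weighting schemes; models with RoG over 15 Å very likely contain one or
more "stray" helices, and anything over 12 Å deserves a check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .evaluate import CaTrace
from .topology import TMSegment

RogScheme = Literal["tm_only", "tm_caps", "whole"]

#: axial-RoG guidance thresholds, Å: above CHECK deserves inspection,
#: above STRAY almost certainly contains a detached helix
ROG_CHECK = 12.0
ROG_STRAY = 15.0


@dataclass(frozen=True)
class CapZone:
    """The two 4-residue capping zones of one TM segment."""

    segment_index: int
    n_cap: tuple[int, ...]
    c_cap: tuple[int, ...]


@dataclass
class BundleAxis:
    axis_points: np.ndarray      # (k, 3) running-mean points
    direction: np.ndarray        # unit vector
    point: np.ndarray            # final mean point on the axis

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, float)
        nrm = np.linalg.norm(self.direction)
        if nrm < 1e-12:
            raise ValueError("degenerate axis direction")
        self.direction = self.direction / nrm


def assign_caps(segments: list[TMSegment], chain_length: int,
                extend: int = 0) -> list[CapZone]:
    """Assign two 4-residue capping zones per segment.

    The default cap holds the segment's two terminal residues plus the two
    immediately beyond.  With ``extend`` > 0 the two outward residues slide
    outward; the extension saturates so no cap residue lies more than 10
    positions outside the segment.  Caps are clipped at the chain ends
    (keeping at least the two terminal residues).
    """
    if not 0 <= extend <= 10:
        raise ValueError("extend must be in 0..10")
    k = min(extend, 8)
    caps = []
    for si, seg in enumerate(segments):
        if len(seg) < 2:
            raise ValueError(f"segment {seg} too short for capping (needs >= 2 residues)")
        n_inner = (seg.start, seg.start + 1)
        c_inner = (seg.end - 1, seg.end)
        n_outer = tuple(r for r in (seg.start - 2 - k, seg.start - 1 - k) if r >= 1)
        c_outer = tuple(r for r in (seg.end + 1 + k, seg.end + 2 + k) if r <= chain_length)
        n_cap = tuple(sorted(set(n_outer + n_inner)))
        c_cap = tuple(sorted(set(c_inner + c_outer) - set(n_cap)))
        caps.append(CapZone(si, n_cap, c_cap))
    return caps


def bundle_axis(trace: CaTrace, caps: list[CapZone]) -> BundleAxis:
    """Average bundle axis accumulated from cap-midpoint pairs.

    Each segment's cap midpoints define an axis candidate from its N-cap to
    its C-cap.  Starting from the most widely separated pair, the remaining
    pairs are folded in by decreasing separation; a pair whose direction
    opposes the running mean is flipped first, so antiparallel helices
    reinforce rather than cancel the axis.
    """
    if len(caps) < 1:
        raise ValueError("need at least one cap zone")
    idx = trace.index_of()

    def midpoint(resids: tuple[int, ...]) -> np.ndarray | None:
        pts = [trace.coords[idx[r]] for r in resids if r in idx]
        return np.mean(pts, axis=0) if pts else None

    pairs = []
    for cap in caps:
        m_n, m_c = midpoint(cap.n_cap), midpoint(cap.c_cap)
        if m_n is None or m_c is None:
            continue
        length = float(np.linalg.norm(m_c - m_n))
        if length > 1e-9:
            pairs.append((length, (m_n + m_c) / 2.0, (m_c - m_n) / length))
    if not pairs:
        raise ValueError("all cap pairs are degenerate; cannot define an axis")
    pairs.sort(key=lambda t: -t[0])

    mean_pt = pairs[0][1].copy()
    mean_dir = pairs[0][2].copy()
    points = [mean_pt.copy()]
    for count, (_, pt, direction) in enumerate(pairs[1:], start=2):
        if np.dot(direction, mean_dir) < 0:
            direction = -direction
        mean_pt = mean_pt + (pt - mean_pt) / count
        mean_dir = mean_dir + (direction - mean_dir) / count
        points.append(mean_pt.copy())
    return BundleAxis(np.array(points), mean_dir, mean_pt)


def _residue_weights(trace: CaTrace, segments: list[TMSegment],
                     caps: list[CapZone], scheme: RogScheme) -> np.ndarray:
    in_tm = np.zeros(len(trace), bool)
    in_cap = np.zeros(len(trace), bool)
    idx = trace.index_of()
    for seg in segments:
        for r in seg.residues():
            if r in idx:
                in_tm[idx[r]] = True
    for cap in caps:
        for r in cap.n_cap + cap.c_cap:
            if r in idx:
                in_cap[idx[r]] = True
    in_cap &= ~in_tm  # TM membership takes precedence where zones overlap
    if scheme == "tm_only":
        w = np.where(in_tm, 1.0, 0.0)
    elif scheme == "tm_caps":
        w = np.where(in_tm, 1.0, np.where(in_cap, 0.5, 0.0))
    elif scheme == "whole":
        w = np.where(in_tm, 2.0, np.where(in_cap, 1.0, 0.5))
    else:
        raise ValueError(f"unknown RoG scheme {scheme!r}")
    return w


def axial_rog(trace: CaTrace, axis: BundleAxis, segments: list[TMSegment],
              caps: list[CapZone], scheme: RogScheme = "whole") -> float:
    """Weighted radius of gyration about the bundle axis, in Å.

    r_i is the perpendicular distance of residue i's Cα from the infinite
    line through the axis mean point along the mean direction.  Weights per
    scheme: ``tm_only`` (TM 1, rest 0), ``tm_caps`` (TM 1, caps 0.5, rest 0),
    ``whole`` (TM 2, caps 1, rest 0.5).
    """
    w = _residue_weights(trace, segments, caps, scheme)
    if w.sum() <= 0:
        raise ValueError("no residue carries positive weight under this scheme")
    rel = trace.coords - axis.point
    along = rel @ axis.direction
    perp = rel - np.outer(along, axis.direction)
    r2 = np.einsum("ij,ij->i", perp, perp)
    return float(np.sqrt(np.sum(w * r2) / np.sum(w)))


def flag_compactness(rog: float) -> str:
    """Map an axial RoG to {"ok", "check", "stray"} (12/15 Å guidance)."""
    if rog < 0:
        raise ValueError("RoG cannot be negative")
    if rog > ROG_STRAY:
        return "stray"
    if rog > ROG_CHECK:
        return "check"
    return "ok"


def bundle_handedness(trace: CaTrace, segments: list[TMSegment],
                      axis: BundleAxis) -> int:
    """Sign of the helix arrangement's rotational sense about the axis.

    Helix midpoints are projected onto the plane normal to the axis and the
    signed area of the cyclic polygon they trace in sequence order gives the
    sense: +1 when the traversal runs clockwise viewed from the tip of the
    canonical axis, −1 anticlockwise, 0 when degenerate (collinear
    midpoints).  The axis sign is canonicalized to the first helix's N→C
    direction so the result does not depend on cap accumulation order.  A
    mirror image always flips the sign — the geometric check for the
    enantiomer ambiguity that distance constraints cannot resolve.
    """
    if len(segments) < 3:
        raise ValueError("handedness needs at least 3 helices")
    idx = trace.index_of()
    mids = []
    for seg in segments:
        pts = [trace.coords[idx[r]] for r in seg.residues() if r in idx]
        if not pts:
            raise ValueError(f"segment {seg} has no residues in the trace")
        mids.append(np.mean(pts, axis=0))
    d = axis.direction
    first = segments[0]
    if first.start in idx and first.end in idx:
        nc = trace.coords[idx[first.end]] - trace.coords[idx[first.start]]
        if np.dot(nc, d) < 0:
            d = -d
    proj = [m - np.dot(m - axis.point, d) * d - axis.point for m in mids]
    area2 = 0.0
    n = len(proj)
    for k in range(n):
        area2 += float(np.dot(np.cross(proj[k], proj[(k + 1) % n]), d))
    if abs(area2) < 1e-9:
        return 0
    # negative signed area about +d means the sequence advances clockwise
    # when viewed from the tip of the canonical axis
    return -1 if area2 > 0 else 1
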