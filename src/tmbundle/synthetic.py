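"""Ground-truth helix bundles, oracle contacts, topology tracks, and decoys.

Everything the rest of the package needs for testing is generated here from
first principles: idealized α-helix bundles with known segment definitions
and handedness, contact lists derived from the true structure (with
controllable rank noise), per-method topology tracks with boundary jitter,
and the classic decoy families — mirror images (the enantiomer ambiguity),
stray helices (non-compact fragment-assembly failures), swapped-helix
folds, and coordinate noise.  All generators are pure functions of their
spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .contacts import ContactPair, ContactSet, assign_ranks, rank_transform
from .evaluate import CaTrace, pseudo_centroids
from .topology import TMSegment

#: textbook ideal α-helix geometry
RISE_PER_RESIDUE = 1.5      # Å
TWIST_PER_RESIDUE = 100.0   # degrees
CA_RADIUS = 2.3             # Å


@dataclass
class BundleSpec:
    """Geometry of an idealized up/down transmembrane helix bundle."""

    n_helices: int = 4
    helix_length: int = 20
    loop_length: int = 6
    bundle_radius: float = 8.0
    rise_per_residue: float = RISE_PER_RESIDUE
    twist_per_residue: float = TWIST_PER_RESIDUE
    ca_radius: float = CA_RADIUS
    handedness: str = "clockwise"            # sense of helix order about +z
    topology: list[int] = field(default_factory=list)  # +1 up / -1 down per helix
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise ValueError("need at least one helix")
        if self.helix_length < 4 or self.loop_length < 1:
            raise ValueError("helix and loop lengths must be positive (helix >= 4)")
        if self.handedness not in ("clockwise", "anticlockwise"):
            raise ValueError("handedness must be clockwise or anticlockwise")
        if not self.topology:
            self.topology = [1 if k % 2 == 0 else -1 for k in range(self.n_helices)]
        if len(self.topology) != self.n_helices:
            raise ValueError("topology must list one up/down flag per helix")


def _ideal_helix(n: int, rise: float, twist_deg: float, radius: float,
                 up: bool) -> np.ndarray:
    """Ideal α-helix along ±z, centred on the z axis, phase 0 at residue 0."""
    k = np.arange(n)
    ang = np.deg2rad(twist_deg) * k
    z = rise * k
    pts = np.stack([radius * np.cos(ang), radius * np.sin(ang), z], axis=1)
    if not up:
        # run downward, mirrored through the xz plane so the helix itself
        # keeps its right-handed twist
        pts = pts[:, [0, 1, 2]] * np.array([1.0, -1.0, -1.0])
    pts[:, 2] -= pts[:, 2].mean()
    return pts


def _loop_path(p0: np.ndarray, p1: np.ndarray, n_loop: int, up_side: bool) -> np.ndarray:
    """Loop of n_loop residues joining p0 to p1 with ~3.8 Å spacing.

    Points follow a straight base path with a sinusoidal bump away from the
    membrane; the bump height is solved so the polyline length matches the
    required (n_loop + 1) * 3.8 Å span.
    """
    n_seg = n_loop + 1
    target = n_seg * 3.8
    chord = float(np.linalg.norm(p1 - p0))
    if chord > target:
        raise ValueError(
            f"loop of {n_loop} residues cannot span {chord:.1f} Å "
            f"(max {target:.1f} Å)")
    fine = np.linspace(0.0, 1.0, 512)
    base = p0[None, :] + fine[:, None] * (p1 - p0)[None, :]
    direction = np.array([0.0, 0.0, 1.0 if up_side else -1.0])

    def curve(h: float) -> np.ndarray:
        return base + (h * np.sin(np.pi * fine))[:, None] * direction

    def length_for(h: float) -> float:
        return float(np.sum(np.linalg.norm(np.diff(curve(h), axis=0), axis=1)))

    if length_for(0.0) >= target - 1e-9:
        h = 0.0
    else:
        h = brentq(lambda x: length_for(x) - target, 0.0, target)
    pts = curve(h)
    # resample interior residues at equal arc length for ~3.8 Å spacing
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    want = np.arange(1, n_loop + 1) * arc[-1] / n_seg
    out = np.empty((n_loop, 3))
    for k, s in enumerate(want):
        j = int(np.searchsorted(arc, s))
        j = min(max(j, 1), len(arc) - 1)
        frac = (s - arc[j - 1]) / max(arc[j] - arc[j - 1], 1e-12)
        out[k] = pts[j - 1] + frac * (pts[j] - pts[j - 1])
    return out


def make_bundle(spec: BundleSpec) -> tuple[CaTrace, list[TMSegment], dict]:
    """Build an idealized helix bundle with known truth.

    Helices sit at equal angles on a circle of ``bundle_radius``; successive
    helices advance clockwise or anticlockwise about +z (viewed from the
    tip of the first helix's N→C direction) per ``handedness``; the up/down
    pattern follows ``spec.topology``.  Returns
    the Cα trace, the true TM segment list, and truth metadata
    (handedness label, bundle axis, per-helix residue ranges).
    """
    sense = -1.0 if spec.handedness == "clockwise" else 1.0
    coords: list[np.ndarray] = []
    segments: list[TMSegment] = []
    resid = 1
    prev_end_pt: np.ndarray | None = None
    helix_ranges: list[tuple[int, int]] = []
    for k in range(spec.n_helices):
        ang = sense * 2.0 * math.pi * k / max(spec.n_helices, 1)
        centre = spec.bundle_radius * np.array([math.cos(ang), math.sin(ang), 0.0])
        up = spec.topology[k] > 0
        pts = _ideal_helix(spec.helix_length, spec.rise_per_residue,
                           spec.twist_per_residue, spec.ca_radius, up) + centre
        if prev_end_pt is not None:
            loop = _loop_path(prev_end_pt, pts[0], spec.loop_length,
                              up_side=not up)
            coords.extend(loop)
            resid += len(loop)
        start = resid
        coords.extend(pts)
        resid += spec.helix_length
        side = "inside" if up else "outside"
        segments.append(TMSegment(start, resid - 1, n_term_side=side))
        helix_ranges.append((start, resid - 1))
        prev_end_pt = pts[-1]
    trace = CaTrace(f"bundle_seed{spec.seed}", list(range(1, resid)),
                    np.array(coords))
    truth = {
        "handedness": spec.handedness,
        "axis": np.array([0.0, 0.0, 1.0]),
        "helix_ranges": helix_ranges,
        "spec": spec,
    }
    return trace, segments, truth


def oracle_contacts(trace: CaTrace, cutoff: float = 8.0, rank_noise: float = 0.0,
                    seed: int = 0, min_sep: int = 5) -> ContactSet:
    """Contact list derived from the true structure.

    Pairs whose pseudo-centroid separation is within ``cutoff`` (and whose
    sequence separation is at least ``min_sep``) are listed with raw score
    1/(1 + (d/cutoff)²), ranked by descending score.  ``rank_noise`` swaps
    that fraction of adjacent rank pairs (seeded) to emulate imperfect
    coevolution rankings, then the set is rank-transformed.
    """
    if not 0.0 <= rank_noise <= 1.0:
        raise ValueError("rank_noise must be in [0, 1]")
    if trace.centroids is None:
        trace = pseudo_centroids(trace)
    n = len(trace)
    pairs: list[ContactPair] = []
    cen = trace.centroids
    for a in range(n):
        for b in range(a + 1, n):
            ri, rj = trace.residue_ids[a], trace.residue_ids[b]
            if rj - ri < min_sep:
                continue
            d = float(np.linalg.norm(cen[a] - cen[b]))
            if d <= cutoff:
                pairs.append(ContactPair(i=ri, j=rj, p_raw=1.0 / (1.0 + (d / cutoff) ** 2)))
    ranked = assign_ranks(pairs)
    if rank_noise > 0 and len(ranked) > 1:
        rng = np.random.default_rng(seed)
        order = list(range(len(ranked)))
        n_swaps = int(rank_noise * (len(ranked) - 1))
        sites = rng.choice(len(ranked) - 1, size=min(n_swaps, len(ranked) - 1),
                           replace=False)
        for s in sorted(sites):
            order[s], order[s + 1] = order[s + 1], order[s]
        from dataclasses import replace as _replace
        ranked = [_replace(ranked[o], rank=r)
                  for r, o in enumerate(order, start=1)]
        ranked.sort(key=lambda p: p.rank)
    cset = ContactSet(L=max(trace.residue_ids), method="oracle", pairs=ranked)
    return rank_transform(cset)


def make_decoys(trace: CaTrace, kind: str, magnitude: float = 10.0,
                helix: int = 0, helix_b: int = 1,
                segments: list[TMSegment] | None = None,
                seed: int = 0) -> CaTrace:
    """Derive a decoy from a true trace.

    kinds: ``mirror`` (negate x — the enantiomer), ``stray_helix`` (translate
    one helix radially outward by ``magnitude`` Å), ``swap_helices``
    (re-thread the chain through two helices' exchanged positions), ``noise``
    (per-atom Gaussian jitter of σ = ``magnitude``).
    """
    xyz = trace.coords.copy()
    mid = f"{trace.model_id}_{kind}"
    if kind == "mirror":
        xyz[:, 0] *= -1.0
    elif kind == "noise":
        rng = np.random.default_rng(seed)
        xyz = xyz + rng.normal(scale=magnitude, size=xyz.shape)
    elif kind in ("stray_helix", "swap_helices"):
        if segments is None:
            raise ValueError(f"{kind} requires the segment list")
        if not 0 <= helix < len(segments):
            raise ValueError(f"invalid helix index {helix}")
        idx = trace.index_of()
        rows_a = [idx[r] for r in segments[helix].residues() if r in idx]
        if kind == "stray_helix":
            centre = xyz[rows_a].mean(axis=0)
            radial = centre - np.array([0.0, 0.0, centre[2]])
            nrm = np.linalg.norm(radial)
            direction = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
            xyz[rows_a] += magnitude * direction
        else:
            if not 0 <= helix_b < len(segments) or helix_b == helix:
                raise ValueError(f"invalid helix pair ({helix}, {helix_b})")
            rows_b = [idx[r] for r in segments[helix_b].residues() if r in idx]
            if len(rows_a) != len(rows_b):
                raise ValueError("swap requires equal-length helices")
            a_pts, b_pts = xyz[rows_a].copy(), xyz[rows_b].copy()
            # keep each slot's chain direction: reverse the incoming helix
            # if the two run in opposite directions
            da = a_pts[-1] - a_pts[0]
            db = b_pts[-1] - b_pts[0]
            flip = float(np.dot(da, db)) < 0
            xyz[rows_a] = b_pts[::-1] if flip else b_pts
            xyz[rows_b] = a_pts[::-1] if flip else a_pts
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    return CaTrace(mid, list(trace.residue_ids), xyz)


def make_topology_tracks(segments: list[TMSegment], chain_length: int,
                         n_methods: int = 3, jitter: int = 0,
                         seed: int = 0) -> dict[str, list[TMSegment]]:
    """Per-method copies of the true segments with jittered boundaries."""
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, list[TMSegment]] = {}
    for m in range(n_methods):
        segs: list[TMSegment] = []
        prev_end = 0
        for seg in segments:
            ds = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            de = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            start = max(prev_end + 1, seg.start + ds)
            end = min(chain_length, max(start, seg.end + de))
            segs.append(TMSegment(start, end, n_term_side=seg.n_term_side))
            prev_end = end
        out[f"method{m + 1}"] = segs
    return out
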