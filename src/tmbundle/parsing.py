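"""Contact-map stripe parsing: helix-pair packing orientation and boundary DP.

Contacts between a pair of packed α-helices form stripes in the contact map:
parallel to the main diagonal for parallel packing (j - i ≈ const) and
orthogonal to it for antiparallel packing (i + j ≈ const).  Each candidate
helix pair is fitted with both stripe models (fixed slopes ±1) and labelled
by the stronger fit; segment boundaries are then adjusted to maximise the
total fit over all helix pairs, solved exactly by dynamic programming over
the segment-interaction graph (max-sum variable elimination).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import networkx as nx

from .contacts import ContactSet
from .topology import TMSegment

Orientation = Literal["parallel", "antiparallel", "none"]

#: residual half-width of the stripe model, in residues
DEFAULT_HALF_WIDTH = 4.0
#: minimum contacts in a block for a non-"none" orientation (two points fit any line)
DEFAULT_MIN_SUPPORT = 3
#: strengths are quantized to this resolution inside the optimizer so the
#: dynamic program is exact integer arithmetic (deterministic tie-breaks)
_QUANTUM = 1e-9


@dataclass(frozen=True)
class SegmentBlock:
    """The contact block between one helix pair and its stripe fits."""

    seg_a: TMSegment
    seg_b: TMSegment
    orientation: Orientation
    strength_par: float
    strength_anti: float
    n_support: int

    @property
    def strength(self) -> float:
        """Strength of the winning orientation (0 for 'none')."""
        if self.orientation == "parallel":
            return self.strength_par
        if self.orientation == "antiparallel":
            return self.strength_anti
        return 0.0


@dataclass
class ParseResult:
    blocks: list[SegmentBlock]
    adjusted_segments: list[TMSegment]
    total_fit: float


def _stripe_strength(offsets: Sequence[float], weights: Sequence[float],
                     half_width: float) -> float:
    """Best Σ e·max(0, 1 - |offset - c|/w) over the intercept c.

    The objective is piecewise linear in c with breakpoints at the data
    offsets, so the optimum is attained at one of them; ties take the
    smallest intercept.
    """
    best = 0.0
    for c in sorted(set(offsets)):
        s = sum(w * max(0.0, 1.0 - abs(o - c) / half_width)
                for o, w in zip(offsets, weights))
        if s > best + 1e-15:
            best = s
    return best


def orientation_fit(contacts: ContactSet, seg_a: TMSegment, seg_b: TMSegment,
                    half_width: float = DEFAULT_HALF_WIDTH,
                    min_support: int = DEFAULT_MIN_SUPPORT) -> SegmentBlock:
    """Fit parallel and antiparallel stripe models to one helix-pair block.

    Collects contacts (i, j) with i in ``seg_a`` and j in ``seg_b`` (the
    segments are ordered internally, so the fit is symmetric under swapping
    them).  The parallel model is j = i + c, the antiparallel model
    j = -i + c, both with the intercept fitted to maximise the e-weighted
    triangular-kernel support.
    """
    if seg_a.start > seg_b.start:
        seg_a, seg_b = seg_b, seg_a
    ii: list[int] = []
    jj: list[int] = []
    ww: list[float] = []
    for p in contacts.pairs:
        if p.i in seg_a and p.j in seg_b:
            ii.append(p.i)
            jj.append(p.j)
            ww.append(p.e)
    n = len(ii)
    if n == 0:
        return SegmentBlock(seg_a, seg_b, "none", 0.0, 0.0, 0)
    s_par = _stripe_strength([j - i for i, j in zip(ii, jj)], ww, half_width)
    s_anti = _stripe_strength([j + i for i, j in zip(ii, jj)], ww, half_width)
    if n < min_support:
        orient: Orientation = "none"
    elif s_par > s_anti:
        orient = "parallel"
    else:
        orient = "antiparallel"  # ties default to the common TM-bundle case
    return SegmentBlock(seg_a, seg_b, orient, s_par, s_anti, n)


def _block_strength_q(contacts: ContactSet, a: TMSegment, b: TMSegment,
                      half_width: float, min_support: int) -> int:
    """Quantized winning-orientation strength of a block (0 if unsupported)."""
    blk = orientation_fit(contacts, a, b, half_width, min_support)
    return round(blk.strength / _QUANTUM)


def optimize_boundaries(contacts: ContactSet, segments: list[TMSegment],
                        max_shift: int = 5,
                        half_width: float = DEFAULT_HALF_WIDTH,
                        min_support: int = DEFAULT_MIN_SUPPORT) -> ParseResult:
    """Shift segment boundaries to maximise the total stripe fit.

    Each segment's start and end may move independently by up to
    ``max_shift`` residues, subject to segments staying within the chain,
    non-empty and non-overlapping.  The objective is the sum of winning
    stripe strengths over all segment pairs evaluated at the shifted
    boundaries.  Because non-adjacent helix pairs couple distant segments'
    shifts, the exact optimum is found by max-sum variable elimination over
    the segment-interaction graph rather than a simple chain recursion;
    strengths are quantized to integers so the optimum and its tie-breaks
    (smallest total absolute shift, then lexicographically smallest shift
    vector) are reproducible exactly.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    for a, b in zip(segments, segments[1:]):
        if b.start <= a.end:
            raise ValueError("input segments must be sorted and non-overlapping")
    n = len(segments)
    if n == 0:
        return ParseResult([], [], 0.0)
    L = contacts.L

    # per-segment shift domains, ordered so that index order is (ds, de)
    # lexicographic — the positional tie-break code below then selects the
    # lexicographically smallest shift vector among score ties
    domains: list[list[tuple[int, int]]] = []
    for seg in segments:
        dom = []
        for ds in range(-max_shift, max_shift + 1):
            for de in range(-max_shift, max_shift + 1):
                s, e = seg.start + ds, seg.end + de
                if 1 <= s <= e <= L:
                    dom.append((ds, de))
        if not dom:
            raise ValueError(f"segment {seg} admits no legal boundary shift")
        domains.append(dom)
    dmax = max(len(d) for d in domains)

    def shifted(k: int, choice: tuple[int, int]) -> TMSegment:
        ds, de = choice
        return replace(segments[k], start=segments[k].start + ds,
                       end=segments[k].end + de)

    # pair factors: quantized block strength per (choice_k, choice_l);
    # pairs with no contacts in the widest window are constant 0 and skipped
    def window_has_contacts(a: TMSegment, b: TMSegment) -> bool:
        lo_a, hi_a = a.start - max_shift, a.end + max_shift
        lo_b, hi_b = b.start - max_shift, b.end + max_shift
        return any(lo_a <= p.i <= hi_a and lo_b <= p.j <= hi_b
                   for p in contacts.pairs)

    pair_tables: dict[tuple[int, int], list[list[int]]] = {}
    for k, l in itertools.combinations(range(n), 2):
        if not window_has_contacts(segments[k], segments[l]):
            continue
        tab = [[_block_strength_q(contacts, shifted(k, ck), shifted(l, cl),
                                  half_width, min_support)
                for cl in domains[l]] for ck in domains[k]]
        pair_tables[(k, l)] = tab

    # objective per full assignment, as an exact integer triple:
    #   (total strength, -total |shift|, -positional code)
    def unary(k: int, idx: int) -> tuple[int, int, int]:
        ds, de = domains[k][idx]
        return (0, -(abs(ds) + abs(de)), -idx * dmax ** (n - 1 - k))

    NEG = (-(10 ** 18), 0, 0)

    def add(a: tuple[int, int, int], b: tuple[int, int, int]) -> tuple[int, int, int]:
        return (a[0] + b[0], a[1] + b[1], a[2] + b[2])

    # factor graph: scopes and table lookups
    factors: list[tuple[tuple[int, ...], dict]] = []
    for k in range(n):
        factors.append(((k,), {"kind": "unary", "k": k}))
    for (k, l), tab in pair_tables.items():
        factors.append(((k, l), {"kind": "pair", "tab": tab}))
    for k in range(n - 1):  # non-overlap between consecutive segments
        factors.append(((k, k + 1), {"kind": "overlap", "k": k}))

    def factor_value(scope: tuple[int, ...], info: dict,
                     assign: dict[int, int]) -> tuple[int, int, int]:
        if info["kind"] == "unary":
            return unary(info["k"], assign[info["k"]])
        if info["kind"] == "pair":
            k, l = scope
            return (info["tab"][assign[k]][assign[l]], 0, 0)
        k = info["k"]
        end_k = segments[k].end + domains[k][assign[k]][1]
        start_n = segments[k + 1].start + domains[k + 1][assign[k + 1]][0]
        return (0, 0, 0) if end_k < start_n else NEG

    # max-sum variable elimination in sequence order, with recorded argmaxes
    live: list[tuple[tuple[int, ...], object]] = [
        (scope, ("base", info)) for scope, info in factors]
    recovery: list[tuple[int, tuple[int, ...], dict]] = []

    def eval_factor(entry, assign: dict[int, int]) -> tuple[int, int, int]:
        scope, payload = entry
        tag = payload[0]
        if tag == "base":
            return factor_value(scope, payload[1], assign)
        table = payload[1]
        key = tuple(assign[v] for v in scope)
        return table[key]

    for v in range(n):
        touching = [f for f in live if v in f[0]]
        rest = [f for f in live if v not in f[0]]
        out_scope = tuple(sorted({u for f in touching for u in f[0]} - {v}))
        table: dict[tuple[int, ...], tuple[int, int, int]] = {}
        argmax: dict[tuple[int, ...], int] = {}
        for combo in itertools.product(*(range(len(domains[u])) for u in out_scope)):
            assign = dict(zip(out_scope, combo))
            best, best_idx = None, -1
            for idx in range(len(domains[v])):
                assign[v] = idx
                total = (0, 0, 0)
                for f in touching:
                    total = add(total, eval_factor(f, assign))
                if best is None or total > best:
                    best, best_idx = total, idx
            del assign[v]
            table[combo] = best  # type: ignore[assignment]
            argmax[combo] = best_idx
        recovery.append((v, out_scope, argmax))
        live = rest + [(out_scope, ("msg", table))]

    final = (0, 0, 0)
    for f in live:
        final = add(final, eval_factor(f, {}))
    if final[0] <= NEG[0] // 2:
        raise ValueError("no non-overlapping boundary assignment exists")

    # back-substitute in reverse elimination order
    choice: dict[int, int] = {}
    for v, out_scope, argmax in reversed(recovery):
        key = tuple(choice[u] for u in out_scope)
        choice[v] = argmax[key]

    adjusted = [shifted(k, domains[k][choice[k]]) for k in range(n)]
    blocks = [orientation_fit(contacts, a, b, half_width, min_support)
              for a, b in itertools.combinations(adjusted, 2)]
    total = sum(b.strength for b in blocks)
    return ParseResult(blocks=blocks, adjusted_segments=adjusted, total_fit=total)


def parse_segments(contacts: ContactSet, segments: list[TMSegment],
                   max_shift: int = 0, **kw) -> ParseResult:
    """Convenience wrapper: fit all blocks, optionally optimizing boundaries."""
    return optimize_boundaries(contacts, segments, max_shift=max_shift, **kw)


def packing_graph(parse: ParseResult, min_strength: float = 0.0) -> nx.Graph:
    """Helix-packing graph: nodes are 1-based segment indices, edges carry
    the winning orientation and its strength.

    Blocks with orientation "none" (or strength at or below ``min_strength``)
    contribute no edge.
    """
    g = nx.Graph()
    index_of = {(s.start, s.end): k + 1 for k, s in enumerate(parse.adjusted_segments)}
    for k, s in enumerate(parse.adjusted_segments, start=1):
        g.add_node(k, start=s.start, end=s.end)
    for blk in parse.blocks:
        if blk.orientation == "none" or blk.strength <= min_strength:
            continue
        a = index_of[(blk.seg_a.start, blk.seg_a.end)]
        b = index_of[(blk.seg_b.start, blk.seg_b.end)]
        g.add_edge(a, b, orientation=blk.orientation, weight=blk.strength,
                   n_support=blk.n_support)
    return g


def packing_summary(graph: nx.Graph) -> str:
    """Text cartoon of the packing graph, e.g. ``"1-2 anti; 3-4 anti; 1-4 anti"``."""
    parts = []
    for a, b in sorted(graph.edges()):
        tag = "anti" if graph.edges[a, b]["orientation"] == "antiparallel" else "par"
        parts.append(f"{a}-{b} {tag}")
    return "; ".join(parts)
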