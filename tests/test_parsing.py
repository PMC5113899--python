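"""Stripe-orientation fitting and exact boundary optimization."""

import itertools

import networkx as nx
import numpy as np
import pytest

from tmbundle import (BundleSpec, ContactPair, ContactSet, TMSegment,
                      make_bundle, optimize_boundaries, oracle_contacts,
                      orientation_fit, packing_graph, packing_summary)
from tmbundle.contacts import assign_ranks, rank_transform
from tmbundle.parsing import ParseResult, _QUANTUM


def _cset(entries, L=60):
    pairs = assign_ranks([ContactPair(i, j, s) for i, j, s in entries])
    return rank_transform(ContactSet(L=L, pairs=pairs))


def brute_stripe_strength(offsets, weights, w=4.0):
    """Independent evaluation: scan every candidate intercept."""
    best = 0.0
    for c in offsets:
        s = sum(wt * max(0.0, 1.0 - abs(o - c) / w) for o, wt in zip(offsets, weights))
        best = max(best, s)
    return best


class TestOrientationFit:
    def test_perfect_antiparallel_stripe(self):
        # contacts exactly on i + j = 40
        entries = [(i, 40 - i, 0.9) for i in range(10, 18)]
        cs = _cset(entries)
        blk = orientation_fit(cs, TMSegment(8, 18), TMSegment(22, 32))
        assert blk.orientation == "antiparallel"
        total_e = sum(p.e for p in cs.pairs)
        assert blk.strength_anti == pytest.approx(total_e)
        assert blk.strength_par < blk.strength_anti

    def test_perfect_parallel_stripe(self):
        entries = [(i, i + 25, 0.9) for i in range(10, 18)]
        cs = _cset(entries)
        blk = orientation_fit(cs, TMSegment(8, 18), TMSegment(33, 45))
        assert blk.orientation == "parallel"

    def test_segment_swap_invariant(self):
        entries = [(i, 40 - i, 0.9) for i in range(10, 16)]
        cs = _cset(entries)
        a, b = TMSegment(8, 18), TMSegment(22, 32)
        blk1 = orientation_fit(cs, a, b)
        blk2 = orientation_fit(cs, b, a)
        assert blk1 == blk2

    def test_below_support_is_none(self):
        cs = _cset([(10, 30, 0.9), (11, 29, 0.8)])
        blk = orientation_fit(cs, TMSegment(8, 18), TMSegment(25, 35))
        assert blk.orientation == "none"
        assert blk.n_support == 2

    def test_noisy_hairpin_matches_brute_force(self):
        trace, segments, _ = make_bundle(
            BundleSpec(n_helices=2, bundle_radius=5.0, seed=3))
        cs = oracle_contacts(trace, rank_noise=0.2, seed=3)
        a, b = segments
        blk = orientation_fit(cs, a, b)
        assert blk.orientation == "antiparallel"
        inblock = [(p.i, p.j, p.e) for p in cs.pairs if p.i in a and p.j in b]
        ww = [e for _, _, e in inblock]
        assert blk.strength_par == pytest.approx(
            brute_stripe_strength([j - i for i, j, _ in inblock], ww))
        assert blk.strength_anti == pytest.approx(
            brute_stripe_strength([j + i for i, j, _ in inblock], ww))


def brute_force_boundaries(contacts, segments, max_shift):
    """Exhaustive enumeration over every legal boundary placement, scoring
    with the same quantized tuple objective the optimizer declares."""
    L = contacts.L
    n = len(segments)
    domains = []
    for seg in segments:
        dom = [(ds, de)
               for ds in range(-max_shift, max_shift + 1)
               for de in range(-max_shift, max_shift + 1)
               if 1 <= seg.start + ds <= seg.end + de <= L]
        domains.append(dom)
    dmax = max(len(d) for d in domains)
    best_key, best_assign = None, None
    for combo in itertools.product(*(range(len(d)) for d in domains)):
        shifted = []
        ok = True
        prev_end = 0
        for k, idx in enumerate(combo):
            ds, de = domains[k][idx]
            s, e = segments[k].start + ds, segments[k].end + de
            if s <= prev_end:
                ok = False
                break
            shifted.append(TMSegment(s, e))
            prev_end = e
        if not ok:
            continue
        strength = 0
        for a, b in itertools.combinations(shifted, 2):
            strength += round(orientation_fit(contacts, a, b).strength / _QUANTUM)
        abs_shift = sum(abs(domains[k][idx][0]) + abs(domains[k][idx][1])
                        for k, idx in enumerate(combo))
        code = sum(idx * dmax ** (n - 1 - k) for k, idx in enumerate(combo))
        key = (strength, -abs_shift, -code)
        if best_key is None or key > best_key:
            best_key, best_assign = key, shifted
    return best_assign, best_key


def random_instance(rng, L=60):
    starts = sorted(rng.choice(np.arange(5, L - 15), size=3, replace=False))
    segments = []
    prev_end = 0
    for s in starts:
        s = max(int(s), prev_end + 2)
        e = min(s + int(rng.integers(6, 11)), L - 1)
        if e <= s:
            return None
        segments.append(TMSegment(s, e))
        prev_end = e
    if any(b.start <= a.end for a, b in zip(segments, segments[1:])):
        return None
    entries = {}
    for a, b in itertools.combinations(segments, 2):
        for _ in range(int(rng.integers(3, 8))):
            i = int(rng.integers(a.start - 2, a.end + 3))
            j = int(rng.integers(b.start - 2, b.end + 3))
            if 1 <= i < j <= L:
                entries[(i, j)] = float(rng.random())
    if len(entries) < 3:
        return None
    cs = rank_transform(ContactSet(L=L, pairs=assign_ranks(
        [ContactPair(i, j, s) for (i, j), s in entries.items()])))
    return cs, segments


class TestOptimizeBoundaries:
    def test_zero_shift_is_identity(self, oracle4, bundle4):
        _, segments, _ = bundle4
        res = optimize_boundaries(oracle4, segments, max_shift=0)
        assert [(s.start, s.end) for s in res.adjusted_segments] == \
               [(s.start, s.end) for s in segments]
        expect = sum(orientation_fit(oracle4, a, b).strength
                     for a, b in itertools.combinations(segments, 2))
        assert res.total_fit == pytest.approx(expect)

    def test_shift_recovers_truncated_truth(self, oracle4, bundle4):
        # helices declared 3 residues short of the truth: the optimizer
        # must extend the boundaries and strictly increase the fit
        _, segments, _ = bundle4
        trimmed = [TMSegment(s.start + 3, s.end - 3) for s in segments]
        base = optimize_boundaries(oracle4, trimmed, max_shift=0)
        res = optimize_boundaries(oracle4, trimmed, max_shift=3)
        assert res.total_fit > base.total_fit
        for adj, true_seg in zip(res.adjusted_segments, segments):
            assert abs(adj.start - true_seg.start) <= 3
            assert abs(adj.end - true_seg.end) <= 3

    def test_monotone_in_max_shift(self, oracle4, bundle4):
        _, segments, _ = bundle4
        fits = [optimize_boundaries(oracle4, segments, max_shift=k).total_fit
                for k in (0, 1, 2)]
        assert fits == sorted(fits)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        inst = None
        while inst is None:
            inst = random_instance(rng)
        cs, segments = inst
        max_shift = int(rng.integers(1, 3))
        res = optimize_boundaries(cs, segments, max_shift=max_shift)
        brute_segs, brute_key = brute_force_boundaries(cs, segments, max_shift)
        assert [(s.start, s.end) for s in res.adjusted_segments] == \
               [(s.start, s.end) for s in brute_segs]
        assert res.total_fit == pytest.approx(brute_key[0] * _QUANTUM, abs=1e-7)


class TestPackingGraph:
    def test_flhb_like_pattern(self):
        # two strong hairpins (1+2, 3+4) plus a single 1-4 packing
        trace, segments, _ = make_bundle(BundleSpec(seed=1))
        s1, s2, s3, s4 = segments
        entries = []
        for a, b in [(s1, s2), (s3, s4), (s1, s4)]:
            c = a.end + b.start
            for i in range(a.start + 2, a.end - 1):
                j = c - i
                if b.start <= j <= b.end:
                    entries.append((i, j, 0.9))
        dedup = {(i, j): s for i, j, s in entries}
        cs = _cset([(i, j, s) for (i, j), s in dedup.items()], L=segments[-1].end)
        res = optimize_boundaries(cs, segments, max_shift=0)
        g = packing_graph(res)
        assert set(map(frozenset, g.edges())) == \
               {frozenset({1, 2}), frozenset({3, 4}), frozenset({1, 4})}
        assert all(d["orientation"] == "antiparallel" for _, _, d in g.edges(data=True))

    def test_empty_parse_gives_empty_graph(self):
        g = packing_graph(ParseResult(blocks=[], adjusted_segments=[], total_fit=0.0))
        assert g.number_of_edges() == 0

    def test_graph_is_undirected_with_shared_labels(self, oracle4, bundle4):
        _, segments, _ = bundle4
        res = optimize_boundaries(oracle4, segments, max_shift=0)
        g = packing_graph(res)
        assert isinstance(g, nx.Graph)
        for a, b in g.edges():
            assert g.edges[a, b] == g.edges[b, a]

    def test_summary_format(self, oracle4, bundle4):
        _, segments, _ = bundle4
        res = optimize_boundaries(oracle4, segments, max_shift=0)
        text = packing_summary(packing_graph(res))
        assert "1-2 anti" in text

    def test_adjacent_pairs_antiparallel_no_spurious_edges(self, bundle4):
        # noisy oracle of an up-down bundle: every adjacent pair is
        # antiparallel and no diagonal (non-packed) edge appears
        trace, segments, _ = bundle4
        cs = oracle_contacts(trace, rank_noise=0.2, seed=11)
        res = optimize_boundaries(cs, segments, max_shift=0)
        g = packing_graph(res)
        expected = {frozenset({1, 2}), frozenset({2, 3}), frozenset({3, 4}),
                    frozenset({1, 4})}
        assert set(map(frozenset, g.edges())) == expected
        assert all(d["orientation"] == "antiparallel"
                   for _, _, d in g.edges(data=True))
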