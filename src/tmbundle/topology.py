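"""Transmembrane topology tracks and their thick/thin consensus.

Per-method topology predictions arrive as per-residue letter tracks
(``i`` = inside, ``M`` = membrane, ``o`` = outside, TOPCONS style) or as
segment tables.  The consensus is computed per residue by vote: residues
where every method predicts membrane are "all" (drawn as a thick bar),
residues where at least two agree are "majority" (thin bar).  Maximal runs
of agreeing residues become consensus segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

Side = Literal["inside", "outside", "unknown"]


@dataclass(frozen=True)
class TMSegment:
    """One predicted membrane-spanning helix (1-based inclusive bounds)."""

    start: int
    end: int
    n_term_side: Side = "unknown"
    agreement: str | None = None  # "all" | "majority" on consensus segments

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("segments are 1-based")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def __contains__(self, resid: int) -> bool:
        return self.start <= resid <= self.end


@dataclass
class TopologyConsensus:
    per_method: dict[str, list[TMSegment]]
    consensus: list[TMSegment]


def _check_sorted(segments: list[TMSegment], origin: str) -> None:
    for a, b in zip(segments, segments[1:]):
        if b.start <= a.end:
            raise ValueError(f"{origin}: segments overlap or are unsorted: {a} vs {b}")


def segments_from_track(track: str) -> list[TMSegment]:
    """Convert an i/M/o per-residue track to a sorted segment list."""
    allowed = set("iMo")
    bad = set(track) - allowed
    if bad:
        raise ValueError(f"unknown topology letters {sorted(bad)}; alphabet is i/M/o")
    segs: list[TMSegment] = []
    start = None
    prev_side: Side = "unknown"
    side_of = {"i": "inside", "o": "outside"}
    for pos, ch in enumerate(track, start=1):
        if ch == "M":
            if start is None:
                start = pos
        else:
            if start is not None:
                segs.append(TMSegment(start, pos - 1, n_term_side=prev_side))
                start = None
            prev_side = side_of[ch]
    if start is not None:
        segs.append(TMSegment(start, len(track), n_term_side=prev_side))
    return segs


def track_from_segments(segments: list[TMSegment], length: int) -> str:
    """Inverse of :func:`segments_from_track` (flanks alternate from n_term_side)."""
    _check_sorted(segments, "track_from_segments")
    letters = ["?"] * length
    for s in segments:
        if s.end > length:
            raise ValueError(f"segment {s} exceeds chain length {length}")
        for r in s.residues():
            letters[r - 1] = "M"
    # fill flanking regions, alternating sides across each helix
    side = segments[0].n_term_side if segments else "unknown"
    cur = {"inside": "i", "outside": "o", "unknown": "i"}[side]
    for k in range(length):
        if letters[k] == "M":
            continue
        if k > 0 and letters[k - 1] == "M":
            cur = "o" if cur == "i" else "i"
        letters[k] = cur
    return "".join(letters)


def read_topology_table(path: str | Path) -> dict[str, list[TMSegment]]:
    """Read per-method topology predictions.

    Two layouts are accepted and auto-detected per line:

    * letter tracks: ``method<whitespace>iiiMMMMooo`` (one row per method);
    * segment tables: ``method<TAB>start<TAB>end[<TAB>side]`` rows.

    All letter tracks must share one length.
    """
    path = Path(path)
    per_method: dict[str, list[TMSegment]] = {}
    table_rows: dict[str, list[tuple[int, int, Side]]] = {}
    track_len: int | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) == 2 and set(toks[1]) <= set("iMo"):
            method, track = toks
            if track_len is None:
                track_len = len(track)
            elif len(track) != track_len:
                raise ValueError(
                    f"{path}:{lineno}: track length {len(track)} != {track_len}")
            per_method[method] = segments_from_track(track)
        elif len(toks) in (3, 4):
            method = toks[0]
            try:
                start, end = int(toks[1]), int(toks[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad segment row") from exc
            side: Side = toks[3] if len(toks) == 4 else "unknown"  # type: ignore[assignment]
            if side not in ("inside", "outside", "unknown"):
                raise ValueError(f"{path}:{lineno}: unknown side {side!r}")
            table_rows.setdefault(method, []).append((start, end, side))
        else:
            raise ValueError(f"{path}:{lineno}: unrecognised topology line")
    for method, rows in table_rows.items():
        segs = [TMSegment(s, e, n_term_side=sd) for s, e, sd in sorted(rows)]
        _check_sorted(segs, f"{path} method {method}")
        per_method[method] = segs
    if not per_method:
        raise ValueError(f"{path}: no topology rows found")
    return per_method


def write_segments(segments: list[TMSegment], path: str | Path,
                   method: str = "consensus") -> None:
    """Write segments as a 1-based TSV: method, start, end, n_term_side."""
    lines = ["# method\tstart\tend\tn_term_side"]
    for s in segments:
        lines.append(f"{method}\t{s.start}\t{s.end}\t{s.n_term_side}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_segments(path: str | Path) -> list[TMSegment]:
    """Read a single-method segment TSV written by :func:`write_segments`."""
    per_method = read_topology_table(path)
    if len(per_method) != 1:
        raise ValueError(f"{path}: expected one method, found {sorted(per_method)}")
    return next(iter(per_method.values()))


def consensus_segments(per_method: Mapping[str, list[TMSegment]]) -> TopologyConsensus:
    """Per-residue vote consensus over >=2 methods.

    A residue is membrane-"all" when every method places it in a TM segment
    and membrane-"majority" when at least two do.  Maximal runs of (all or
    majority) residues become consensus segments; a run is tagged "all" only
    if every residue in it is unanimous.  The n-terminal side of each
    consensus segment is the majority vote of the methods' flanking-side
    calls (ties give "unknown").
    """
    methods = sorted(per_method)
    if len(methods) < 2:
        raise ValueError("consensus requires at least two methods")
    n_methods = len(methods)
    length = max((s.end for m in methods for s in per_method[m]), default=0)
    votes = [0] * (length + 1)  # 1-based
    for m in methods:
        _check_sorted(per_method[m], f"method {m}")
        for seg in per_method[m]:
            for r in seg.residues():
                votes[r] += 1

    consensus: list[TMSegment] = []
    run_start = None
    run_all = True
    for r in range(1, length + 2):
        in_run = r <= length and votes[r] >= 2
        if in_run:
            if run_start is None:
                run_start, run_all = r, True
            if votes[r] < n_methods:
                run_all = False
        elif run_start is not None:
            side = _vote_side(per_method, run_start, r - 1)
            consensus.append(TMSegment(run_start, r - 1, n_term_side=side,
                                       agreement="all" if run_all else "majority"))
            run_start = None
    return TopologyConsensus(per_method=dict(per_method), consensus=consensus)


def _vote_side(per_method: Mapping[str, list[TMSegment]], start: int, end: int) -> Side:
    tally = {"inside": 0, "outside": 0}
    for segs in per_method.values():
        best = None  # method's segment overlapping the consensus run
        for s in segs:
            if s.start <= end and s.end >= start:
                best = s
                break
        if best is not None and best.n_term_side in tally:
            tally[best.n_term_side] += 1
    if tally["inside"] > tally["outside"]:
        return "inside"
    if tally["outside"] > tally["inside"]:
        return "outside"
    return "unknown"
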