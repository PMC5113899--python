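"""Ranked residue–residue contact predictions: I/O, normalization, combination.

Coevolution methods (PSICOV, GREMLIN, EVfold, ...) emit ranked lists of
predicted residue pairs whose "reliability" scores live on method-specific
scales with very different distributions.  To make scores comparable across
methods, the raw ranking is converted to a normalized reliability

    e = exp(-r^2 * 0.01 / L)

where ``r`` is the 1-based rank of the pair and ``L`` the protein length.
Under this transform the number of pairs above any fixed value of ``e`` grows
in proportion to the square root of the protein length, so longer proteins
retain proportionally more usable contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence


class ContactFileError(ValueError):
    """Raised for malformed or inconsistent contact files."""


@dataclass(frozen=True)
class ContactPair:
    """A predicted residue pair (1-based indices, ``i < j``)."""

    i: int
    j: int
    p_raw: float
    rank: int = 0
    e: float = 0.0

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError(f"require i < j, got ({self.i}, {self.j})")
        if self.i < 1:
            raise ValueError(f"residue indices are 1-based, got i={self.i}")

    @property
    def separation(self) -> int:
        return self.j - self.i


@dataclass
class ContactSet:
    """A ranked list of contact predictions for one protein.

    Parameters
    ----------
    L : int
        Protein length (residue count); all pair indices must be <= L.
    method : str
        Source tag, e.g. ``"psicov"``, ``"gremlin"``, ``"evfold"`` or
        ``"consensus"``.
    pairs : list of ContactPair
        Stored in rank order (rank 1 first) once ranks are assigned.
    """

    L: int
    method: str = "unknown"
    pairs: list[ContactPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"protein length must be positive, got {self.L}")
        seen: set[tuple[int, int]] = set()
        for p in self.pairs:
            if p.j > self.L:
                raise ContactFileError(
                    f"pair ({p.i}, {p.j}) exceeds protein length {self.L}"
                )
            key = (p.i, p.j)
            if key in seen:
                raise ContactFileError(f"duplicate pair ({p.i}, {p.j})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def pair_dict(self) -> dict[tuple[int, int], ContactPair]:
        return {(p.i, p.j): p for p in self.pairs}


def assign_ranks(pairs: Iterable[ContactPair]) -> list[ContactPair]:
    """Rank pairs by descending raw score; ties broken by (i, j) order."""
    ordered = sorted(pairs, key=lambda p: (-p.p_raw, p.i, p.j))
    return [replace(p, rank=r) for r, p in enumerate(ordered, start=1)]


def rank_transform(cset: ContactSet) -> ContactSet:
    """Convert ranks to the normalized reliability e = exp(-r^2 * 0.01 / L).

    The top-ranked pair scores just under 1 (rank is 1-based) and ``e`` decays
    with the square of the rank, scaled by protein length so that the count of
    pairs with e > exp(-1) is 10*sqrt(L).
    """
    if cset.L <= 0:
        raise ValueError("protein length must be positive")
    if any(p.rank < 1 for p in cset.pairs):
        raise ValueError("ranks must be assigned before rank_transform")
    pairs = [
        replace(p, e=math.exp(-(p.rank ** 2) * 0.01 / cset.L))
        for p in sorted(cset.pairs, key=lambda p: p.rank)
    ]
    return ContactSet(L=cset.L, method=cset.method, pairs=pairs)


def combine_contact_sets(sets: Sequence[ContactSet], method: str = "consensus") -> ContactSet:
    """Combine rank-transformed sets by summing normalized reliabilities.

    A pair missing from a method contributes 0 for that method.  The summed
    values are re-ranked and rank-transformed again so the consensus lives on
    the same (0, 1] scale as its inputs.
    """
    if not sets:
        raise ValueError("need at least one contact set to combine")
    L = sets[0].L
    for s in sets[1:]:
        if s.L != L:
            raise ValueError(f"protein length mismatch: {s.L} != {L}")
    summed: dict[tuple[int, int], float] = {}
    for s in sets:
        for p in s.pairs:
            if p.e <= 0.0:
                raise ValueError(
                    f"set '{s.method}' is not rank-transformed (pair ({p.i},{p.j}) has e=0)"
                )
            summed[(p.i, p.j)] = summed.get((p.i, p.j), 0.0) + p.e
    pairs = [ContactPair(i=i, j=j, p_raw=v) for (i, j), v in summed.items()]
    out = ContactSet(L=L, method=method, pairs=assign_ranks(pairs))
    return rank_transform(out)


def filter_pairs(cset: ContactSet, min_sep: int = 0, top_k: int | None = None) -> ContactSet:
    """Drop short-range pairs (j - i < min_sep), keep the top_k by rank.

    Ranks are re-assigned 1..k on the survivors; ``e`` values are recomputed
    from the new ranks.  An empty result is legal.
    """
    if min_sep < 0:
        raise ValueError("min_sep must be >= 0")
    surv = [p for p in cset.pairs if p.separation >= min_sep]
    surv.sort(key=lambda p: p.rank)
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        surv = surv[:top_k]
    pairs = [replace(p, rank=r) for r, p in enumerate(surv, start=1)]
    out = ContactSet(L=cset.L, method=cset.method, pairs=pairs)
    return rank_transform(out) if pairs else out


# ---------------------------------------------------------------------------
# File I/O
#
# CASP-RR is the canonical interchange format:
#   optional "PFRMAT RR" / "TARGET ..." / "MODEL ..." headers,
#   optional sequence lines, then "i j d1 d2 score" records, "END" footer.
# PSICOV emits whitespace-separated "i j 0 8 score".
# GREMLIN and EVfold emit delimited tables with a header row; the reader
# detects the header and maps columns (i, j, score) by name.
# ---------------------------------------------------------------------------

DIALECTS = ("casp_rr", "psicov", "gremlin", "evfold")

_GREMLIN_COLS = {"i": ("i", "res_i", "pos_i"), "j": ("j", "res_j", "pos_j"),
                 "score": ("score", "scaled_score", "raw_score", "prob")}
_EVFOLD_COLS = {"i": ("i", "res_i"), "j": ("j", "res_j"),
                "score": ("score", "ec_score", "cn", "prob")}


def _parse_record(i_s: str, j_s: str, score_s: str, lineno: int, path: str) -> ContactPair:
    try:
        i, j, score = int(i_s), int(j_s), float(score_s)
    except ValueError as exc:
        raise ContactFileError(f"{path}:{lineno}: malformed record: {exc}") from exc
    if i == j:
        raise ContactFileError(f"{path}:{lineno}: self-contact ({i}, {j})")
    if i > j:
        i, j = j, i
    if i < 1:
        raise ContactFileError(f"{path}:{lineno}: residue index < 1")
    return ContactPair(i=i, j=j, p_raw=score)


def read_contact_list(path: str | Path, dialect: str = "casp_rr",
                      length: int | None = None, method: str | None = None) -> ContactSet:
    """Read a ranked contact list in one of the supported dialects.

    Pairs are stored with ``i < j`` (swapped if needed) and ranked by
    descending raw score with deterministic (i, j) tie-breaks.  ``length``
    must be supplied unless the file header declares it (CASP-RR ``TARGET``
    lines do not; the writer below emits a ``REMARK LENGTH`` header that the
    reader honours).
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    lines = path.read_text().splitlines()
    pairs: list[ContactPair] = []
    header_len: int | None = None
    tag = method or dialect

    if dialect in ("casp_rr", "psicov"):
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line:
                continue
            up = line.upper()
            if up.startswith("METHOD"):
                toks = line.split(maxsplit=1)
                if method is None and len(toks) == 2:
                    tag = toks[1].strip()
                continue
            if up.startswith(("PFRMAT", "TARGET", "AUTHOR", "MODEL", "END")):
                continue
            if up.startswith("REMARK"):
                toks = line.split()
                if len(toks) >= 3 and toks[1].upper() == "LENGTH":
                    header_len = int(toks[2])
                continue
            toks = line.split()
            if len(toks) == 1 and toks[0].isalpha():
                continue  # sequence line
            if len(toks) < 3:
                raise ContactFileError(f"{path}:{lineno}: expected >=3 fields, got {len(toks)}")
            if len(toks) >= 5:
                pairs.append(_parse_record(toks[0], toks[1], toks[4], lineno, str(path)))
            else:
                pairs.append(_parse_record(toks[0], toks[1], toks[2], lineno, str(path)))
    else:
        colmap = _GREMLIN_COLS if dialect == "gremlin" else _EVFOLD_COLS
        body = [(n, l) for n, l in enumerate(lines, start=1) if l.strip()]
        if not body:
            raise ContactFileError(f"{path}: empty file")
        first = body[0][1]
        delim = "," if ("," in first and "\t" not in first) else None
        header_toks = [t.strip().lower() for t in (first.split(delim))]
        idx: dict[str, int] = {}
        has_header = any(t in colmap["score"] for t in header_toks)
        if has_header:
            for role, names in colmap.items():
                for name in names:
                    if name in header_toks:
                        idx[role] = header_toks.index(name)
                        break
                else:
                    raise ContactFileError(
                        f"{path}: header lacks a recognised '{role}' column")
            body = body[1:]
        else:
            idx = {"i": 0, "j": 1, "score": len(first.split(delim)) - 1}
        for lineno, raw in body:
            toks = [t.strip() for t in raw.split(delim)]
            try:
                i_s, j_s, s_s = toks[idx["i"]], toks[idx["j"]], toks[idx["score"]]
            except IndexError as exc:
                raise ContactFileError(f"{path}:{lineno}: too few columns") from exc
            pairs.append(_parse_record(i_s, j_s, s_s, lineno, str(path)))

    L = length if length is not None else header_len
    if L is None:
        if not pairs:
            raise ContactFileError(f"{path}: no pairs and no declared length")
        L = max(p.j for p in pairs)
    return ContactSet(L=L, method=tag, pairs=assign_ranks(pairs))


def write_contact_list(cset: ContactSet, path: str | Path, dialect: str = "casp_rr") -> None:
    """Write a contact set; CASP-RR is the canonical round-trip format."""
    path = Path(path)
    out: list[str] = []
    ordered = sorted(cset.pairs, key=lambda p: p.rank if p.rank else 0)
    if dialect == "casp_rr":
        out.append("PFRMAT RR")
        out.append(f"REMARK LENGTH {cset.L}")
        out.append(f"METHOD {cset.method}")
        out.append("MODEL 1")
        for p in ordered:
            out.append(f"{p.i} {p.j} 0 8 {p.p_raw:.17g}")
        out.append("END")
    elif dialect == "psicov":
        for p in ordered:
            out.append(f"{p.i} {p.j} 0 8 {p.p_raw:.17g}")
    elif dialect == "gremlin":
        out.append("i\tj\tscore")
        for p in ordered:
            out.append(f"{p.i}\t{p.j}\t{p.p_raw:.17g}")
    elif dialect == "evfold":
        out.append("i,j,ec_score")
        for p in ordered:
            out.append(f"{p.i},{p.j},{p.p_raw:.17g}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(out) + "\n")
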