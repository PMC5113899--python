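"""Top-slice consensus selection from score-vs-compactness plots.

Plotting model score (y) against axial RoG (x) puts the best models —
highest score and/or most compact — in the upper left.  A diagonal slice
y = gradient·x + c with gradient 10 is lowered (c chosen) until it selects
up to ``max_n`` models above the line; this is equivalent to ranking models
by the margin y − gradient·x.  Slices taken under different contact sets
are then combined by keeping only models that appear in at least
``min_count`` slices.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence


@dataclass
class SliceSelection:
    contact_set_tag: str
    intercept: float
    selected: list[str]              # model ids, best margin first
    margins: dict[str, float]        # id -> score - gradient*rog


def top_slice(scores: Mapping[str, float], rogs: Mapping[str, float],
              gradient: float = 10.0, max_n: int = 20,
              tag: str = "slice") -> SliceSelection:
    """Select up to ``max_n`` models above the line y = gradient·x + c.

    The largest intercept c admitting at most ``max_n`` models is used, so
    the selection is exactly the top ``max_n`` models by margin
    score − gradient·RoG; boundary ties break by higher score, then lower
    RoG, then model id.
    """
    if not scores:
        raise ValueError("no models to select from")
    if set(scores) != set(rogs):
        raise ValueError("scores and RoGs must cover the same models")
    if gradient <= 0:
        raise ValueError("gradient must be positive")
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    margins = {m: scores[m] - gradient * rogs[m] for m in scores}
    order = sorted(margins, key=lambda m: (-margins[m], -scores[m], rogs[m], m))
    chosen = order[:max_n]
    c = margins[chosen[-1]]
    return SliceSelection(contact_set_tag=tag, intercept=c, selected=chosen,
                          margins={m: margins[m] for m in chosen})


def cross_slice_cull(selections: Sequence[SliceSelection],
                     min_count: int = 3) -> list[str]:
    """Keep models occurring in at least ``min_count`` slices.

    Ordered by occurrence count (descending), then mean margin across the
    slices containing the model, then model id.
    """
    if not selections:
        raise ValueError("need at least one slice selection")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = defaultdict(int)
    margin_sum: dict[str, float] = defaultdict(float)
    for sel in selections:
        for m in sel.selected:
            counts[m] += 1
            margin_sum[m] += sel.margins[m]
    keep = [m for m, c in counts.items() if c >= min_count]
    keep.sort(key=lambda m: (-counts[m], -margin_sum[m] / counts[m], m))
    return keep


def balance_pool(tagged_ids: Mapping[str, str], occurrence: Mapping[str, int],
                 per_method_target: int) -> list[str]:
    """Per construction method, keep the ``per_method_target`` most-recurrent
    models (all of them if a method has fewer); ties break by model id."""
    if per_method_target < 0:
        raise ValueError("per_method_target must be >= 0")
    by_method: dict[str, list[str]] = defaultdict(list)
    for mid, method in tagged_ids.items():
        by_method[method].append(mid)
    kept: list[str] = []
    for method in sorted(by_method):
        ids = sorted(by_method[method], key=lambda m: (-occurrence.get(m, 0), m))
        kept.extend(ids[:per_method_target])
    return kept
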