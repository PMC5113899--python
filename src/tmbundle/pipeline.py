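"""End-to-end workflow: contacts → parse → score → RoG → compare → select.

The pipeline reproduces the consensus model-evaluation workflow: normalize
and combine the contact predictions, parse the contact map against the
segment track, score every model against every contact set, measure axial
compactness, build the pairwise wRMSD matrix and fold-space embedding, and
emit the top-slice consensus pool plus a machine-readable manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import distance_matrix, project_foldspace
from .contacts import (combine_contact_sets, filter_pairs, rank_transform,
                       read_contact_list)
from .evaluate import ScoreParams, pseudo_centroids, score_model
from .geometry import assign_caps, axial_rog, bundle_axis, bundle_handedness, flag_compactness
from .parsing import optimize_boundaries, packing_graph, packing_summary
from .pdbio import read_ca_trace
from .selection import SliceSelection, cross_slice_cull, top_slice
from .topology import TMSegment, read_segments


class StageError(RuntimeError):
    """Raised with the failing stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    contact_files: list[str]
    model_files: list[str]
    segment_file: str
    out_dir: str
    dialect: str = "casp_rr"
    length: int | None = None
    s: float = 5.0
    n_top: int = 100
    min_sep: int = 8
    gradient: float = 10.0
    max_n: int = 20
    min_count: int = 3
    extend: int = 0
    max_shift: int = 5
    weight_scale: float = 10.0
    dim: int = 3
    seed: int = 1
    rog_scheme: str = "whole"
    extra: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns a manifest of produced artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- contacts ---------------------------------------------------------
    try:
        csets = []
        for f in config.contact_files:
            cs = read_contact_list(f, dialect=config.dialect, length=config.length)
            if cs.method == config.dialect:  # no tag in the file: use its name
                cs.method = Path(f).stem
            csets.append(rank_transform(cs))
        if not csets:
            raise ValueError("no contact files given")
    except Exception as exc:
        raise StageError("contacts", str(exc)) from exc
    combined = csets[0] if len(csets) == 1 else combine_contact_sets(csets)
    all_sets = csets + ([combined] if len(csets) > 1 else [])

    # --- models -----------------------------------------------------------
    try:
        if not config.model_files:
            raise ValueError("no model files given")
        traces = [pseudo_centroids(read_ca_trace(f)) for f in config.model_files]
    except Exception as exc:
        raise StageError("models", str(exc)) from exc

    # --- segments + parsing ----------------------------------------------
    try:
        segments = read_segments(config.segment_file)
        parse = optimize_boundaries(filter_pairs(combined, min_sep=5),
                                    segments, max_shift=config.max_shift)
        graph = packing_graph(parse)
        (out / "packing.txt").write_text(packing_summary(graph) + "\n")
    except Exception as exc:
        raise StageError("parse", str(exc)) from exc
    segments = parse.adjusted_segments

    # --- scoring + geometry ----------------------------------------------
    params = ScoreParams(s=config.s, n_top=config.n_top, min_sep=config.min_sep)
    rows = []
    try:
        caps = assign_caps(segments, max(len(t) for t in traces), extend=config.extend)
        for t in traces:
            axis = bundle_axis(t, caps)
            rog = axial_rog(t, axis, segments, caps, scheme=config.rog_scheme)  # type: ignore[arg-type]
            hand = bundle_handedness(t, segments, axis) if len(segments) >= 3 else 0
            row = {"model_id": t.model_id, "rog": rog,
                   "compactness": flag_compactness(rog), "handedness": hand}
            for cs in all_sets:
                row[f"score_{cs.method}"] = score_model(t, cs, params).score
            rows.append(row)
        scores = pd.DataFrame(rows).set_index("model_id")
        scores.to_csv(out / "scores.tsv", sep="\t", float_format="%.6f")
    except Exception as exc:
        raise StageError("score", str(exc)) from exc

    # --- compare + embed --------------------------------------------------
    embedding_file = None
    if len(traces) >= config.dim + 2:
        try:
            dmat = distance_matrix(traces)
            np.savetxt(out / "distance_matrix.tsv", dmat, delimiter="\t", fmt="%.6f")
            emb = project_foldspace(dmat, dim=config.dim,
                                    weight_scale=config.weight_scale, seed=config.seed)
            coords = pd.DataFrame(emb.coords, index=scores.index,
                                  columns=[f"dim{k + 1}" for k in range(config.dim)])
            coords.to_csv(out / "embedding.tsv", sep="\t", float_format="%.6f")
            embedding_file = "embedding.tsv"
        except Exception as exc:
            raise StageError("embed", str(exc)) from exc

    # --- selection --------------------------------------------------------
    try:
        selections: list[SliceSelection] = []
        for cs in all_sets:
            col = f"score_{cs.method}"
            sel = top_slice(scores[col].to_dict(), scores["rog"].to_dict(),
                            gradient=config.gradient, max_n=config.max_n,
                            tag=cs.method)
            selections.append(sel)
        pool = cross_slice_cull(selections, min_count=min(config.min_count,
                                                          len(selections)))
        (out / "pool.txt").write_text("\n".join(pool) + "\n")
    except Exception as exc:
        raise StageError("select", str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "s": config.s, "n_top": config.n_top, "min_sep": config.min_sep,
            "gradient": config.gradient, "max_n": config.max_n,
            "min_count": config.min_count, "extend": config.extend,
            "max_shift": config.max_shift, "weight_scale": config.weight_scale,
            "dim": config.dim, "rog_scheme": config.rog_scheme,
        },
        "inputs": {
            "contacts": list(config.contact_files),
            "models": list(config.model_files),
            "segments": config.segment_file,
        },
        "outputs": {
            "scores": "scores.tsv", "packing": "packing.txt", "pool": "pool.txt",
            "embedding": embedding_file,
        },
        "pool": pool,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
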