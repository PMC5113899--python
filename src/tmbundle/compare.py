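"""Weighted superposition, RMSD suite, and fold-space projection.

Rough models often contain a few wildly deviant positions (typically long
loops), so plain RMSD over a whole-structure superposition is misleading.
Residues are therefore weighted by the similarity of their structural
environments: here the environment of residue i is its internal distance
profile, and the weight is exp(−Δ_i/σ) where Δ_i is the mean absolute
discrepancy between the two models' distance profiles at i.  Three further
weighting schemes (TM-only, TM+caps, whole-chain) mirror the axial-RoG
weights.

Ensembles of models are embedded into a low-dimensional fold-space by
gradual multi-dimensional projection: pairwise wRMSD values are first
repaired to satisfy the triangle inequality, embedded exactly in N−1
dimensions (classical scaling), then the dimensionality is halved stage by
stage with weighted stress majorization (weights min(1, scale/d), so close
pairs dominate) until the target 2 or 3 dimensions is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from .evaluate import CaTrace
from .geometry import CapZone, _residue_weights
from .topology import TMSegment

RMSD_SCHEMES = ("env_weighted", "tm_only", "tm_caps", "whole")


# ---------------------------------------------------------------------------
# weights and superposition
# ---------------------------------------------------------------------------

def environment_weights(a: CaTrace, b: CaTrace, sigma: float = 4.0) -> np.ndarray:
    """Per-residue weights from internal-distance-profile agreement.

    Δ_i = mean_j | d_a(i,j) − d_b(i,j) | over all other residues j; the
    weight is exp(−Δ_i/σ) ∈ (0, 1], so residues whose context is preserved
    between the two models dominate the superposition.  The models must
    share one residue numbering (no alignment problem).
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    da = np.linalg.norm(a.coords[:, None, :] - a.coords[None, :, :], axis=-1)
    db = np.linalg.norm(b.coords[:, None, :] - b.coords[None, :, :], axis=-1)
    n = len(a)
    delta = np.abs(da - db).sum(axis=1) / max(n - 1, 1)
    return np.exp(-delta / sigma)


def weighted_superpose(a: CaTrace, b: CaTrace,
                       w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares rigid superposition of b onto a (Kabsch).

    Returns ``(R, t, wrmsd)`` with b mapped by ``x -> R @ x + t``;
    reflections are excluded (proper rotations only), so a mirror image
    retains a positive residual.  wRMSD = sqrt(Σ w_i‖a_i − (R b_i + t)‖² / Σ w_i).
    """
    if len(a) != len(b):
        raise ValueError("length mismatch")
    w = np.asarray(w, float)
    if w.shape != (len(a),):
        raise ValueError("one weight per residue required")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    wa = w / w.sum()
    ca = wa @ a.coords
    cb = wa @ b.coords
    A = a.coords - ca
    B = b.coords - cb
    H = (B * wa[:, None]).T @ A
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = a.coords - (b.coords @ R.T + t)
    wrmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff)) / w.sum()))
    return R, t, wrmsd


def rmsd_suite(a: CaTrace, b: CaTrace, segments: list[TMSegment],
               caps: list[CapZone], sigma: float = 4.0) -> dict[str, float]:
    """The four weighted RMSDs, each from its own weighted superposition:
    environment-weighted, TM-only, TM+caps (caps half weight), and whole
    chain (TM double, caps unit, rest half)."""
    out = {}
    for scheme in RMSD_SCHEMES:
        if scheme == "env_weighted":
            w = environment_weights(a, b, sigma=sigma)
        else:
            w = _residue_weights(a, segments, caps, scheme)  # type: ignore[arg-type]
        out[scheme] = weighted_superpose(a, b, w)[2]
    return out


def distance_matrix(traces: list[CaTrace], segments: list[TMSegment] | None = None,
                    caps: list[CapZone] | None = None,
                    scheme: str = "env_weighted") -> np.ndarray:
    """Symmetric pairwise wRMSD matrix over a model ensemble."""
    if len(traces) < 2:
        raise ValueError("need at least two models")
    n0 = len(traces[0])
    for t in traces:
        if len(t) != n0:
            raise ValueError(f"model {t.model_id} has {len(t)} residues, expected {n0}")
    if scheme != "env_weighted" and (segments is None or caps is None):
        raise ValueError(f"scheme {scheme!r} requires segments and caps")
    n = len(traces)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if scheme == "env_weighted":
                w = environment_weights(traces[i], traces[j])
            else:
                w = _residue_weights(traces[i], segments, caps, scheme)  # type: ignore[arg-type]
            d[i, j] = d[j, i] = weighted_superpose(traces[i], traces[j], w)[2]
    return d


def cumulative_rmsd(reference: CaTrace, others: list[CaTrace],
                    segments: list[TMSegment] | None = None,
                    caps: list[CapZone] | None = None,
                    scheme: str = "env_weighted") -> list[float]:
    """Sorted ascending wRMSDs of the reference against each other model."""
    if not others:
        raise ValueError("need at least one other model")
    vals = []
    for o in others:
        if scheme == "env_weighted":
            w = environment_weights(reference, o)
        else:
            w = _residue_weights(reference, segments, caps, scheme)  # type: ignore[arg-type]
        vals.append(weighted_superpose(reference, o, w)[2])
    return sorted(vals)


# ---------------------------------------------------------------------------
# fold-space projection
# ---------------------------------------------------------------------------

@dataclass
class Embedding:
    coords: np.ndarray          # (n, dim)
    stress: float               # weighted residual, see stress()
    dim_schedule: list[int]


def repair_triangle_inequality(d: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Replace every d_ab violating d_ab <= d_ac + d_cb by the tightest
    path bound (all-pairs shortest paths)."""
    d = np.asarray(d, float)
    fixed = floyd_warshall(d, directed=False)
    # only tighten genuine violations; never let the path bound inflate an
    # entry (dense csgraph treats exact zeros as missing edges)
    return np.where(fixed < d - tol, fixed, d)


def _stress(coords: np.ndarray, delta: np.ndarray, w: np.ndarray) -> float:
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    iu = np.triu_indices_from(delta, k=1)
    num = np.sum(w[iu] * (delta[iu] - d[iu]) ** 2)
    den = np.sum(w[iu])
    return float(num / den) if den > 0 else 0.0


def _smacof(coords: np.ndarray, delta: np.ndarray, w: np.ndarray,
            tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Weighted stress majorization (Guttman transform) at fixed dimension."""
    n = coords.shape[0]
    V = -w.copy()
    np.fill_diagonal(V, 0.0)
    np.fill_diagonal(V, -V.sum(axis=1))
    Vp = np.linalg.pinv(V)
    prev = _stress(coords, delta, w)
    for _ in range(max_iter):
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 1e-12, delta / d, 0.0)
        B = -w * ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        coords = Vp @ (B @ coords)
        cur = _stress(coords, delta, w)
        if prev > 0 and (prev - cur) / prev < tol:
            prev = cur
            break
        prev = cur
    return coords


def _classical_init(delta: np.ndarray) -> np.ndarray:
    """Classical scaling: exact embedding in <= n-1 dims for Euclidean input."""
    n = delta.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (delta ** 2) @ J
    evals, evecs = np.linalg.eigh(Bmat)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals[: n - 1], 0.0, None)
    return evecs[:, : n - 1] * np.sqrt(pos)


def project_foldspace(d: np.ndarray, dim: int = 3, weight_scale: float = 10.0,
                      seed: int = 0, tol: float = 1e-6,
                      max_iter: int = 500) -> Embedding:
    """Gradual multi-dimensional projection of a wRMSD matrix.

    Stages: (1) triangle-inequality repair; (2) exact classical-scaling
    start in n−1 dimensions; (3) dimension halving down to ``dim``, each
    stage refined by weighted stress majorization with pair weights
    min(1, weight_scale/δ) — distances under ``weight_scale`` Å count in
    full, weaker similarities are down-weighted by their inverse RMSD.
    ``seed`` controls only the infinitesimal symmetry-breaking jitter.
    """
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-8) or np.any(d < 0):
        raise ValueError("distance matrix needs zero diagonal and non-negative entries")
    n = d.shape[0]
    if n < dim + 1:
        raise ValueError(f"need at least dim+1 = {dim + 1} models, got {n}")

    delta = repair_triangle_inequality(d)
    with np.errstate(divide="ignore"):
        w = np.where(delta > 1e-12, np.minimum(1.0, weight_scale / delta), 1.0)
    np.fill_diagonal(w, 0.0)

    coords = _classical_init(delta)
    rng = np.random.default_rng(seed)
    coords = coords + rng.normal(scale=1e-9, size=coords.shape)

    schedule = [n - 1]
    cur = n - 1
    while cur > dim:
        cur = max(dim, cur // 2)
        schedule.append(cur)
    coords = _smacof(coords, delta, w, tol, max_iter)
    for target in schedule[1:]:
        # reduce along principal axes of the current configuration
        centred = coords - coords.mean(axis=0)
        _, _, Vt = np.linalg.svd(centred, full_matrices=False)
        coords = centred @ Vt[:target].T
        coords = _smacof(coords, delta, w, tol, max_iter)
    return Embedding(coords=coords, stress=_stress(coords, delta, w),
                     dim_schedule=schedule)


class FoldSpaceProjection:
    """Estimator-style wrapper around :func:`project_foldspace`.

    Mirrors the ``sklearn.manifold.MDS(dissimilarity="precomputed")`` API:
    ``fit``/``fit_transform`` take a precomputed wRMSD matrix and expose
    ``embedding_`` and ``stress_`` attributes.
    """

    def __init__(self, n_components: int = 3, weight_scale: float = 10.0,
                 seed: int = 0, tol: float = 1e-6, max_iter: int = 500):
        self.n_components = n_components
        self.weight_scale = weight_scale
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "weight_scale": self.weight_scale,
                "seed": self.seed, "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "FoldSpaceProjection":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "FoldSpaceProjection":
        emb = project_foldspace(X, dim=self.n_components,
                                weight_scale=self.weight_scale, seed=self.seed,
                                tol=self.tol, max_iter=self.max_iter)
        self.embedding_ = emb.coords
        self.stress_ = emb.stress
        self.dim_schedule_ = emb.dim_schedule
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).embedding_
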