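"""Discriminative scale learning: sparse nonnegative weights over scales.

Given per-scale distance vectors ``h`` for within-positive pairs (columns of
``H_p``, S x N_p) and positive-vs-negative pairs (columns of ``H_b``,
S x N_b), the intra- and inter-class distance kernels are the Gram matrices

    S_p = H_p H_p^T,      S_b = H_b H_b^T.

The scale weight vector ``w`` maximizes the discriminant ratio
``w^T S_b w / w^T S_p w`` over the simplex-like box constraints; after a
least-squares reformulation (with ``R_p^T R_p`` the Cholesky factorization
of ``S_p``) and an l1 relaxation of the sum constraint, the problem becomes

    min_{a, w >= 0}  || H_b^T R_p^{-1} - H_b^T w a^T ||_F^2 + eta ||w||_1,
    subject to ||w||_2^2 = 1,

solved by alternating optimization:

* w-step: a LASSO/ridge problem, transformed to sparse nonnegative least
  squares and solved by block principal pivoting;
* a-step: the closed form ``a = R_p^{-T} S_b w / sqrt(w^T S_b S_b w)``.

Scales whose converged weight reaches ``sigma * max(w)`` are selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .features.distances import pairwise_scale_distances
from .types import DistanceMetricSpec, MultiScaleFeatureSet

__all__ = [
    "DistanceKernels",
    "ScaleWeights",
    "NonDiscriminativeError",
    "build_distance_kernels",
    "assemble_kernels",
    "update_a",
    "solve_w",
    "snnls_bpp",
    "learn_scale_weights",
    "select_scales",
    "reformulation_objective",
]

#: relative ridge added to S_p before Cholesky so R_p always exists
RIDGE_SCALE = 1e-8


class NonDiscriminativeError(RuntimeError):
    """Raised when ``S_b w = 0``: no scale separates the classes."""


@dataclass
class DistanceKernels:
    """Per-scale pairwise-distance matrices and their Gram kernels."""

    H_p: np.ndarray  # (S, N_p) within-positive distance columns
    H_b: np.ndarray  # (S, N_b) positive-vs-negative distance columns
    S_p: np.ndarray  # (S, S) intra-class kernel H_p H_p^T
    S_b: np.ndarray  # (S, S) inter-class kernel H_b H_b^T
    R_p: np.ndarray  # (S, S) upper-triangular, R_p^T R_p = S_p + ridge I
    ridge: float
    slice_ids_p: np.ndarray = field(default=None)  # type: ignore[assignment]
    slice_ids_b: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_scales(self) -> int:
        return self.H_p.shape[0]


def assemble_kernels(
    H_p: np.ndarray,
    H_b: np.ndarray,
    slice_ids_p: np.ndarray | None = None,
    slice_ids_b: np.ndarray | None = None,
) -> DistanceKernels:
    """Build Gram kernels and the ridged Cholesky factor from distance columns."""
    H_p = np.asarray(H_p, dtype=np.float64)
    H_b = np.asarray(H_b, dtype=np.float64)
    if H_p.ndim != 2 or H_b.ndim != 2 or H_p.shape[0] != H_b.shape[0]:
        raise ValueError("H_p and H_b must be 2-D with a shared scale axis")
    if np.any(H_p < 0) or np.any(H_b < 0):
        raise ValueError("distance entries must be nonnegative")
    S = H_p.shape[0]
    S_p = H_p @ H_p.T
    S_b = H_b @ H_b.T
    ridge = RIDGE_SCALE * max(np.trace(S_p) / S, 1.0)
    R_p = cholesky(S_p + ridge * np.eye(S), lower=False)
    return DistanceKernels(
        H_p=H_p, H_b=H_b, S_p=S_p, S_b=S_b, R_p=R_p, ridge=ridge,
        slice_ids_p=slice_ids_p, slice_ids_b=slice_ids_b,
    )


def _sample_pairs(rng: np.random.Generator, n_a: int, n_b: int, cap: int,
                  same_set: bool) -> np.ndarray:
    """Uniform seeded sample (without replacement) of index pairs.

    ``same_set=True`` enumerates unordered pairs i < j within one set.
    """
    total = n_a * (n_a - 1) // 2 if same_set else n_a * n_b
    if total <= cap:
        flat = np.arange(total)
    else:
        flat = rng.choice(total, size=cap, replace=False)
    if same_set:
        # unrank unordered pairs (i < j) from the lexicographic enumeration
        i = np.empty(len(flat), dtype=np.intp)
        j = np.empty(len(flat), dtype=np.intp)
        # row starts: pairs with first index i occupy a block of (n_a-1-i)
        starts = np.concatenate([[0], np.cumsum(n_a - 1 - np.arange(n_a - 1))])
        i = np.searchsorted(starts, flat, side="right") - 1
        j = flat - starts[i] + i + 1
        return np.column_stack([i, j])
    return np.column_stack([flat // n_b, flat % n_b])


def build_distance_kernels(
    pos: MultiScaleFeatureSet,
    neg: MultiScaleFeatureSet,
    metric: DistanceMetricSpec | None = None,
    pairs_per_slice: int = 2000,
    seed: int = 0,
) -> DistanceKernels:
    """Sample per-slice pairs and assemble the distance kernels.

    Columns of ``H_p`` come from within-positive pairs of the same slice and
    columns of ``H_b`` from positive x negative pairs of the same slice; at
    most ``pairs_per_slice`` of each kind per slice, sampled reproducibly.
    """
    if pos.n_pixels == 0 or neg.n_pixels == 0:
        raise ValueError("both positive and negative feature sets must be non-empty")
    if pairs_per_slice < 1:
        raise ValueError("pairs_per_slice must be >= 1")
    rng = np.random.default_rng(seed)
    slices = np.unique(np.concatenate([pos.slice_ids, neg.slice_ids]))
    cols_p, cols_b, sid_p, sid_b = [], [], [], []
    for t in slices:
        ip = np.flatnonzero(pos.slice_ids == t)
        ineg = np.flatnonzero(neg.slice_ids == t)
        if len(ip) >= 2:
            pp = _sample_pairs(rng, len(ip), len(ip), pairs_per_slice, same_set=True)
            idx = np.column_stack([ip[pp[:, 0]], ip[pp[:, 1]]])
            cols_p.append(pairwise_scale_distances(pos, pos, metric, pairs=idx))
            sid_p.append(np.full(len(idx), t, dtype=np.intp))
        if len(ip) >= 1 and len(ineg) >= 1:
            pb = _sample_pairs(rng, len(ip), len(ineg), pairs_per_slice, same_set=False)
            idx = np.column_stack([ip[pb[:, 0]], ineg[pb[:, 1]]])
            cols_b.append(pairwise_scale_distances(pos, neg, metric, pairs=idx))
            sid_b.append(np.full(len(idx), t, dtype=np.intp))
    if not cols_p:
        raise ValueError("no slice contains two positive samples; cannot form "
                         "within-positive pairs")
    if not cols_b:
        raise ValueError("no slice contains both a positive and a negative sample")
    return assemble_kernels(
        np.hstack(cols_p), np.hstack(cols_b),
        slice_ids_p=np.concatenate(sid_p), slice_ids_b=np.concatenate(sid_b),
    )


def update_a(kernels: DistanceKernels, w: np.ndarray,
             normalize: bool = False) -> np.ndarray:
    """Closed-form a-step: ``a = R_p^{-T} S_b w / sqrt(w^T S_b S_b w)``.

    ``normalize=True`` rescales the result to unit L2 norm (the exact
    constrained minimizer direction); the default keeps the printed form,
    whose denominator is ``||S_b w||_2`` and does not normalize ``a``.
    """
    w = np.asarray(w, dtype=np.float64)
    sbw = kernels.S_b @ w
    denom = float(np.sqrt(sbw @ sbw))
    if denom <= 1e-30:
        raise NonDiscriminativeError(
            "S_b w = 0: the current weights carry no between-class signal"
        )
    a = solve_triangular(kernels.R_p, sbw, trans="T", lower=False) / denom
    if normalize:
        a = a / np.linalg.norm(a)
    return a


def snnls_bpp(Q: np.ndarray, c: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Minimize ``0.5 w^T Q w + c^T w`` s.t. ``w >= 0`` (Q SPD).

    Block principal pivoting on the complementarity system
    ``g = Q w + c, w >= 0, g >= 0, w * g = 0``: variables in the passive set
    F are solved exactly, infeasible variables are exchanged in blocks, with
    the standard backup rule (shrinking exchange, then single pivot with the
    largest index) to guarantee termination.
    """
    S = len(c)
    F = np.zeros(S, dtype=bool)  # passive set (w free), complement active at 0
    w = np.zeros(S)
    g = c.copy()
    n_backup = 3
    lowest = S + 1
    for _ in range(max_iter):
        infeas_w = F & (w < -1e-12)
        infeas_g = (~F) & (g < -1e-12)
        n_infeas = int(infeas_w.sum() + infeas_g.sum())
        if n_infeas == 0:
            break
        if n_infeas < lowest:
            lowest = n_infeas
            n_backup = 3
        elif n_backup > 0:
            n_backup -= 1
        else:
            # anti-cycling: flip only the infeasible variable of largest index
            idx = np.flatnonzero(infeas_w | infeas_g).max()
            infeas_w = np.zeros(S, dtype=bool)
            infeas_g = np.zeros(S, dtype=bool)
            if F[idx]:
                infeas_w[idx] = True
            else:
                infeas_g[idx] = True
        F = F & ~infeas_w | infeas_g
        w = np.zeros(S)
        if F.any():
            w[F] = np.linalg.solve(Q[np.ix_(F, F)], -c[F])
        g = Q @ w + c
    return np.maximum(w, 0.0)


def solve_w(kernels: DistanceKernels, a: np.ndarray, alpha: float = 0.1,
            eta: float = 0.001) -> np.ndarray:
    """w-step: min_{w>=0} ||H_b^T R_p^{-1} a - H_b^T w||^2 + alpha ||w||^2 + eta ||w||_1.

    With ``w >= 0`` the l1 term is linear, so the problem is the nonnegative
    quadratic program ``0.5 w^T Q w + c^T w`` with ``Q = 2 (S_b + alpha I)``
    and ``c = eta 1 - 2 S_b R_p^{-1} a``, solved by block principal pivoting.
    """
    if alpha < 0 or eta < 0:
        raise ValueError("alpha and eta must be nonnegative")
    a = np.asarray(a, dtype=np.float64)
    S = kernels.n_scales
    z = solve_triangular(kernels.R_p, a, lower=False)  # R_p^{-1} a
    Q = 2.0 * (kernels.S_b + alpha * np.eye(S))
    # guard: S_b can be PSD-singular and alpha may be 0
    Q = Q + 1e-12 * max(np.trace(Q) / S, 1.0) * np.eye(S)
    c = eta * np.ones(S) - 2.0 * (kernels.S_b @ z)
    return snnls_bpp(Q, c)


def reformulation_objective(kernels: DistanceKernels, a: np.ndarray,
                            w: np.ndarray, alpha: float, eta: float) -> float:
    """Monitored objective ``||H_b^T R_p^{-1} - H_b^T w a^T||_F^2 +
    alpha ||w||_2^2 + eta ||w||_1``."""
    w = np.asarray(w, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    # H_b^T R_p^{-1} = (R_p^{-T} H_b)^T, via a triangular solve
    M = solve_triangular(kernels.R_p, kernels.H_b, trans="T", lower=False).T
    resid = M - np.outer(kernels.H_b.T @ w, a)
    return float(
        np.sum(resid * resid)
        + alpha * float(w @ w)
        + eta * float(np.sum(np.abs(w)))
    )


@dataclass
class ScaleWeights:
    """Learned nonnegative per-scale weights and the selected-scale set."""

    w: np.ndarray
    selected: tuple[int, ...]  # 0-based scale indices
    sigma: float
    alpha: float
    eta: float
    a: np.ndarray | None = None
    iterations: int = 0
    converged: bool = False
    fallback_uniform: bool = False
    objective_history: tuple[float, ...] = ()
    scale_sizes: tuple[int, ...] | None = None

    @property
    def w_max(self) -> float:
        return float(np.max(self.w))

    @property
    def selected_sizes(self) -> tuple[int, ...]:
        if self.scale_sizes is None:
            raise ValueError("scale_sizes not recorded on this weight vector")
        return tuple(self.scale_sizes[i] for i in self.selected)

    def to_json(self, family: str | None = None) -> str:
        return json.dumps({
            "family": family,
            "scales": list(self.scale_sizes) if self.scale_sizes else None,
            "w": [float(v) for v in self.w],
            "selected": list(self.selected),
            "sigma": self.sigma,
            "alpha": self.alpha,
            "eta": self.eta,
            "iterations": self.iterations,
            "converged": self.converged,
            "fallback_uniform": self.fallback_uniform,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScaleWeights":
        d = json.loads(text)
        return cls(
            w=np.asarray(d["w"], dtype=np.float64),
            selected=tuple(d["selected"]),
            sigma=float(d["sigma"]), alpha=float(d["alpha"]), eta=float(d["eta"]),
            iterations=int(d["iterations"]), converged=bool(d["converged"]),
            fallback_uniform=bool(d.get("fallback_uniform", False)),
            scale_sizes=tuple(d["scales"]) if d.get("scales") else None,
        )


def select_scales(w: np.ndarray, sigma: float = 0.3) -> tuple[int, ...]:
    """Indices of scales with ``w_s >= sigma * max(w)`` (argmax always in)."""
    if not 0.0 < sigma < 1.0:
        raise ValueError("sigma must lie strictly between 0 and 1")
    w = np.asarray(w, dtype=np.float64)
    w_max = float(np.max(w))
    if w_max <= 0.0:
        raise ValueError("all scale weights are zero; nothing to select")
    return tuple(int(i) for i in np.flatnonzero(w >= sigma * w_max - 1e-15))


def learn_scale_weights(
    kernels: DistanceKernels,
    alpha: float = 0.1,
    eta: float = 0.001,
    sigma: float = 0.3,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    normalize_a: bool = False,
    scale_sizes: tuple[int, ...] | None = None,
) -> ScaleWeights:
    """Alternating optimization over (a, w) from uniform initialization.

    Stops when the relative w-change drops below ``tol`` or after
    ``max_iter`` sweeps; the final w is rescaled to unit L2 norm.  If the
    iteration collapses to w = 0 (or no scale carries between-class signal)
    the uniform weight vector is returned with ``fallback_uniform=True``.
    ``seed`` is part of the interface for reproducibility bookkeeping; the
    procedure itself is deterministic.
    """
    del seed  # deterministic given the kernels
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    S = kernels.n_scales
    w = np.full(S, 1.0 / S)
    a = None
    history: list[float] = []
    converged = False
    fallback = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            a = update_a(kernels, w, normalize=normalize_a)
        except NonDiscriminativeError:
            fallback = np.allclose(w, 0.0) or it == 1
            break
        w_new = solve_w(kernels, a, alpha=alpha, eta=eta)
        history.append(reformulation_objective(kernels, a, w_new, alpha, eta))
        rel = np.linalg.norm(w_new - w) / max(np.linalg.norm(w), 1e-12)
        w = w_new
        if rel < tol:
            converged = True
            break
    norm = np.linalg.norm(w)
    if norm <= 1e-12 or fallback:
        w = np.full(S, 1.0 / np.sqrt(S))
        fallback = True
    else:
        w = w / norm
    return ScaleWeights(
        w=w,
        selected=select_scales(w, sigma),
        sigma=sigma, alpha=alpha, eta=eta,
        a=a, iterations=it, converged=converged,
        fallback_uniform=fallback,
        objective_history=tuple(history),
        scale_sizes=scale_sizes,
    )


def save_weights(path: str | Path, weights: ScaleWeights, family: str | None = None) -> None:
    Path(path).write_text(weights.to_json(family=family))


def load_weights(path: str | Path) -> ScaleWeights:
    return ScaleWeights.from_json(Path(path).read_text())
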