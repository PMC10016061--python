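"""Fusion of the nine metric layers into one integrated network.

Each subject has nine OMST-filtered single-metric networks.  They are fused
into a single *integrated weighted SBN* by a linear combination whose
coefficients reflect each layer's informativeness: layers that sit far from
the others in graph diffusion distance (GDD) carry complementary information
and receive a higher weight, while layers redundant with the rest receive a
lower one.  The weights are normalised to sum to 1 and the combined matrix is
re-normalised to maximum weight 1.

The GDD between two graphs is the maximal Frobenius-norm difference between
their heat kernels ``exp(-t L)`` over diffusion time ``t`` (``L`` the
weighted graph Laplacian, degree matrix minus weights).  At 90 nodes the
kernels are evaluated exactly through the Laplacian eigendecomposition; the
time search scans a fixed logarithmic grid and refines the interior maximum
by golden-section search.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .core import (
    INTEGRATED,
    ConnectomeError,
    MultiLayerConnectome,
    WeightedConnectome,
    normalize_connectome,
)

#: Diffusion-time grid: 100 log-spaced points spanning five decades.
DEFAULT_T_GRID = np.logspace(-2.5, 2.5, 100)

WEIGHT_STRATEGIES = ("mean", "min", "softmax")


def _laplacian_eig(c: WeightedConnectome) -> tuple[np.ndarray, np.ndarray]:
    w = c.weights
    lap = np.diag(w.sum(axis=1)) - w
    vals, vecs = np.linalg.eigh(lap)
    return vals, vecs


def _kernel_distance_sq(
    la: np.ndarray, lb: np.ndarray, m2: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """``||exp(-t L_a) - exp(-t L_b)||_F^2`` for each t, via eigenvalues.

    ``m2`` is the elementwise square of ``V_a^T V_b``.  Uses
    ``||A - B||^2 = tr(A^2) + tr(B^2) - 2 tr(AB)`` for symmetric kernels.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ea = np.exp(-np.outer(t, la))  # (T, N)
    eb = np.exp(-np.outer(t, lb))
    tr_a2 = np.exp(-2.0 * np.outer(t, la)).sum(axis=1)
    tr_b2 = np.exp(-2.0 * np.outer(t, lb)).sum(axis=1)
    cross = np.einsum("ti,ij,tj->t", ea, m2, eb)
    return np.maximum(tr_a2 + tr_b2 - 2.0 * cross, 0.0)


def _gdd_from_eigs(
    eig_a: tuple[np.ndarray, np.ndarray],
    eig_b: tuple[np.ndarray, np.ndarray],
    t_grid: np.ndarray,
) -> float:
    la, va = eig_a
    lb, vb = eig_b
    m2 = (va.T @ vb) ** 2
    d2 = _kernel_distance_sq(la, lb, m2, t_grid)
    k = int(np.argmax(d2))
    best = float(d2[k])
    # one golden-section refinement around an interior grid maximum
    if 0 < k < len(t_grid) - 1 and best > 0:
        neg = lambda t: -float(_kernel_distance_sq(la, lb, m2, t)[0])
        try:
            res = minimize_scalar(
                neg,
                bracket=(t_grid[k - 1], t_grid[k], t_grid[k + 1]),
                method="golden",
                options={"xtol": 1e-4, "maxiter": 40},
            )
            best = max(best, -float(res.fun))
        except ValueError:
            pass  # flat bracket; grid value stands
    return float(np.sqrt(best))


def graph_diffusion_distance(
    a: WeightedConnectome,
    b: WeightedConnectome,
    t_grid: Sequence[float] | np.ndarray | None = None,
) -> float:
    """GDD between two networks on the same region table.

    Nonnegative, symmetric, and zero for identical inputs (a pseudo-metric:
    co-spectral pairs can coincide).  Invariant to relabelling both graphs by
    the same node permutation.
    """
    if a.n != b.n:
        raise ConnectomeError("graphs differ in size")
    if a.regions != b.regions:
        raise ConnectomeError("graphs use different region tables")
    grid = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    if np.array_equal(a.weights, b.weights):
        return 0.0
    return _gdd_from_eigs(_laplacian_eig(a), _laplacian_eig(b), grid)


def gdd_matrix(
    ml: MultiLayerConnectome,
    t_grid: Sequence[float] | np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise GDD between all layers, in the multilayer's key order."""
    grid = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    names = list(ml.layers)
    eigs = {m: _laplacian_eig(ml.layers[m]) for m in names}
    k = len(names)
    g = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.array_equal(ml.layers[names[i]].weights, ml.layers[names[j]].weights):
                continue
            g[i, j] = g[j, i] = _gdd_from_eigs(eigs[names[i]], eigs[names[j]], grid)
    return g


def informativeness_weights(
    gdd: np.ndarray,
    layer_names: Sequence[str],
    strategy: str = "mean",
) -> dict[str, float]:
    """Layer weights from a pairwise GDD matrix, normalised to sum 1.

    ``"mean"`` (default): weight proportional to the mean GDD from a layer to
    the others — distant (complementary) layers score high, redundant layers
    low.  ``"min"`` uses the minimal off-diagonal GDD instead; ``"softmax"``
    exponentiates standardised mean GDDs.  If all distances vanish the rule
    degenerates and uniform weights are returned with a warning.
    """
    g = np.asarray(gdd, dtype=float)
    k = len(layer_names)
    if g.shape != (k, k):
        raise ConnectomeError("GDD matrix does not match the layer list")
    if np.any(g < 0) or not np.allclose(g, g.T):
        raise ConnectomeError("GDD matrix must be symmetric nonnegative")
    if strategy not in WEIGHT_STRATEGIES:
        raise ValueError(f"unknown weight strategy {strategy!r}")
    off = g[~np.eye(k, dtype=bool)].reshape(k, k - 1)
    if not np.any(off > 0):
        warnings.warn(
            "all pairwise layer distances are zero; falling back to uniform weights",
            RuntimeWarning,
            stacklevel=2,
        )
        raw = np.ones(k)
    elif strategy == "mean":
        raw = off.mean(axis=1)
    elif strategy == "min":
        raw = off.min(axis=1)
    else:  # softmax of standardised mean GDD
        mean = off.mean(axis=1)
        scale = mean.std()
        raw = np.exp((mean - mean.mean()) / scale) if scale > 0 else np.ones(k)
    w = raw / raw.sum()
    return dict(zip(layer_names, w.tolist()))


def integrate_layers(
    ml: MultiLayerConnectome, weights: Mapping[str, float]
) -> WeightedConnectome:
    """Linear combination of (filtered, normalised) layers, max renormalised.

    The integrated matrix is symmetric with zero diagonal and maximum weight
    1; its edge set is the union of the layers' edge sets.  Metric name is
    ``"integrated"``.
    """
    if set(weights) != set(ml.layers):
        raise ConnectomeError("weights do not match the layer names")
    total = float(sum(weights.values()))
    if not np.isclose(total, 1.0):
        raise ConnectomeError(f"layer weights must sum to 1, got {total:g}")
    combined = np.zeros((ml.regions.n, ml.regions.n))
    for name, layer in ml.layers.items():
        combined += weights[name] * layer.weights
    fused = WeightedConnectome(combined, ml.regions, INTEGRATED)
    return normalize_connectome(fused)
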