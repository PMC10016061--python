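"""Semi-metric analysis of a weighted brain network.

The integrated network is mapped to a distance graph, ``d_ij = 1/w_ij - 1``
for existing edges (strong connections are short), and all-pairs shortest
paths ``dt`` are computed on it.  The *semi-metric ratio* of an existing edge,

    SMR_ij = d_ij / dt_ij  >= 1,

is 1 when the direct edge is itself a shortest path (a *metric* edge) and
greater than 1 when some multi-hop detour is shorter — a triangle-inequality
violation (a *semi-metric* edge), read as redundant, dispersed routing.

Aggregation scales:

* SMR fraction of semi-metric edges — globally, within the left hemisphere,
  within the right hemisphere, and over interhemispheric edges;
* BAI = left SMR / right SMR, a hemispheric asymmetry index (> 1 leftward);
* SMP per node — fraction of a node's incident edges that are semi-metric —
  averaged globally and per hemisphere.

Shortest paths are computed once on the full graph; hemispheric values
classify the full-graph SMR matrix by endpoint location (subgraphs are a
reordering, not a recomputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import johnson

from .core import ConnectomeError, RegionTable, WeightedConnectome

#: Relative slack above 1 before an edge counts as semi-metric; float
#: shortest paths can differ from the direct distance at machine precision
#: on metric edges.
SEMI_METRIC_TOL = 1e-9

# edge classification codes
ABSENT = 0
METRIC = 1
SEMI_METRIC = 2
CLASS_NAMES = {ABSENT: "absent", METRIC: "metric", SEMI_METRIC: "semi_metric"}


def distance_transform(c: WeightedConnectome) -> np.ndarray:
    """Map a normalised connectome to its distance graph.

    ``d_ij = 1/w_ij - 1`` on existing edges, ``+inf`` for absent pairs, zero
    diagonal.  Requires weights in ``(0, 1]`` on edges (max-normalised
    input); a weight above 1 violates normalisation and is rejected.
    """
    w = c.weights
    if np.any(w > 1):
        raise ConnectomeError("weights above 1: connectome is not normalized")
    d = np.full_like(w, np.inf)
    mask = w > 0
    d[mask] = 1.0 / w[mask] - 1.0
    np.fill_diagonal(d, 0.0)
    return d


def all_pairs_shortest_paths(d: np.ndarray) -> np.ndarray:
    """Exact all-pairs shortest paths over a distance graph.

    Uses Johnson's algorithm; ``+inf`` appears only between different
    connected components.  Zero-distance edges (weight exactly 1) are real
    edges and are preserved.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    finite = np.isfinite(d[iu, ju])
    rows, cols = iu[finite], ju[finite]
    vals = d[rows, cols]
    graph = sparse.csr_matrix(
        (
            np.concatenate([vals, vals]),
            (np.concatenate([rows, cols]), np.concatenate([cols, rows])),
        ),
        shape=(n, n),
    )
    dt = johnson(graph, directed=False)
    return dt


@dataclass
class SMRMatrix:
    """Per-edge semi-metric ratios plus the edge classification.

    ``smr`` is ``NaN`` on absent pairs and the diagonal; on existing edges it
    is ``d_ij / dt_ij >= 1``.  ``edge_class`` holds the integer codes
    ``ABSENT`` / ``METRIC`` / ``SEMI_METRIC``.
    """

    smr: np.ndarray
    edge_class: np.ndarray

    @property
    def n(self) -> int:
        return self.smr.shape[0]

    def existing(self) -> np.ndarray:
        """Upper-triangle boolean mask of existing edges."""
        return np.triu(self.edge_class != ABSENT, k=1)

    def semi_metric(self) -> np.ndarray:
        """Upper-triangle boolean mask of semi-metric edges."""
        return np.triu(self.edge_class == SEMI_METRIC, k=1)

    def to_frame(self, regions: RegionTable) -> pd.DataFrame:
        """SMR values as a labelled matrix with absent pairs left empty."""
        return pd.DataFrame(self.smr, index=regions.names, columns=regions.names)


def smr_matrix(
    d: np.ndarray, dt: np.ndarray, tol: float = SEMI_METRIC_TOL
) -> SMRMatrix:
    """Form the SMR matrix and classify edges.

    An existing edge is semi-metric iff ``smr > 1 + tol``, metric otherwise;
    pairs without a direct edge are absent.  ``dt == 0`` with ``d > 0``
    cannot happen for valid inputs (it would need two exactly
    maximum-weight edges chaining a zero-length detour) and signals a
    corrupted state.
    """
    d = np.asarray(d, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if d.shape != dt.shape:
        raise ConnectomeError("distance and shortest-path matrices differ in shape")
    n = d.shape[0]
    offdiag = ~np.eye(n, dtype=bool)
    exists = np.isfinite(d) & offdiag
    if np.any(exists & (dt == 0) & (d > 0)):
        raise ConnectomeError("zero shortest path on a positive-distance edge")
    smr = np.full_like(d, np.nan)
    zero_direct = exists & (d == 0)
    smr[zero_direct] = 1.0  # maximum-weight edge: direct distance 0 is minimal
    pos = exists & (d > 0)
    smr[pos] = d[pos] / dt[pos]
    edge_class = np.full(d.shape, ABSENT, dtype=np.int8)
    edge_class[exists] = METRIC
    edge_class[exists & (smr > 1.0 + tol)] = SEMI_METRIC
    return SMRMatrix(smr=smr, edge_class=edge_class)


@dataclass
class SemiMetricSummary:
    """SMR and SMP aggregates of one subject at every spatial scale.

    Fractions are expressed in ``[0, 1]``; ``bai = smr_left / smr_right``
    (> 1 leftward asymmetry).  ``smp_node`` has one entry per node.
    """

    smr_global: float
    smr_left: float
    smr_right: float
    smr_inter: float
    bai: float
    smp_node: np.ndarray
    smp_global: float
    smp_left: float
    smp_right: float

    def as_row(self) -> dict[str, float]:
        return {
            "smr_global": self.smr_global,
            "smr_left": self.smr_left,
            "smr_right": self.smr_right,
            "smr_inter": self.smr_inter,
            "bai": self.bai,
            "smp_global": self.smp_global,
            "smp_left": self.smp_left,
            "smp_right": self.smp_right,
        }


def _edge_hemisphere_masks(regions: RegionTable) -> tuple[np.ndarray, ...]:
    hemi = np.asarray(regions.hemispheres)
    left = (hemi[:, None] == "L") & (hemi[None, :] == "L")
    right = (hemi[:, None] == "R") & (hemi[None, :] == "R")
    inter = hemi[:, None] != hemi[None, :]
    return left, right, inter


def _fraction(semi: np.ndarray, existing: np.ndarray, scope: np.ndarray, label: str) -> float:
    n_exist = int((existing & scope).sum())
    if n_exist == 0:
        raise ConnectomeError(f"no existing edges in the {label} scope")
    return float((semi & scope).sum() / n_exist)


def smr_scales(
    s: SMRMatrix, regions: RegionTable, zero_right: str = "raise"
) -> dict[str, float]:
    """Fraction of semi-metric edges at the global/left/right/inter scales
    plus the BAI.

    Denominators count *existing* edges of each scope.  Raises when a
    hemisphere contributes no intra-hemispheric edges.  A zero right
    fraction leaves the BAI undefined: the default contract raises;
    ``zero_right="nan"`` records the BAI as missing instead (cohort runs
    treat it as a missing value rather than aborting on one degenerate
    subject).
    """
    if zero_right not in ("raise", "nan"):
        raise ValueError("zero_right must be 'raise' or 'nan'")
    left, right, inter = _edge_hemisphere_masks(regions)
    existing, semi = s.existing(), s.semi_metric()
    out = {
        "smr_global": _fraction(semi, existing, np.ones_like(left), "global"),
        "smr_left": _fraction(semi, existing, left, "intra-left"),
        "smr_right": _fraction(semi, existing, right, "intra-right"),
        "smr_inter": _fraction(semi, existing, inter, "interhemispheric"),
    }
    if out["smr_right"] == 0:
        if zero_right == "raise":
            raise ConnectomeError("right-hemisphere SMR is zero; BAI undefined")
        logging.getLogger(__name__).warning(
            "right-hemisphere SMR is zero; recording BAI as missing"
        )
        out["bai"] = float("nan")
    else:
        out["bai"] = out["smr_left"] / out["smr_right"]
    return out


def smp_scales(
    s: SMRMatrix, regions: RegionTable
) -> tuple[np.ndarray, float, float, float]:
    """Per-node semi-metric percentage and its global/hemispheric means.

    ``smp_node[i]`` is the fraction of node ``i``'s incident edges that are
    semi-metric; the global value is the mean over all nodes, hemispheric
    values the means over each hemisphere's nodes.  Requires every node to
    have degree >= 1 (guaranteed on connected networks).
    """
    exists_full = s.edge_class != ABSENT
    semi_full = s.edge_class == SEMI_METRIC
    degree = exists_full.sum(axis=1)
    if np.any(degree == 0):
        isolated = np.flatnonzero(degree == 0) + 1
        raise ConnectomeError(f"isolated nodes (1-based): {isolated.tolist()}")
    smp_node = semi_full.sum(axis=1) / degree
    left, right = regions.left_indices, regions.right_indices
    smp_left = float(smp_node[left].mean()) if left.size else float("nan")
    smp_right = float(smp_node[right].mean()) if right.size else float("nan")
    return smp_node, float(smp_node.mean()), smp_left, smp_right


def semimetric_profile(
    c: WeightedConnectome, tol: float = SEMI_METRIC_TOL
) -> tuple[SMRMatrix, SemiMetricSummary]:
    """Full semi-metric analysis of one normalised, connected network.

    Composes the distance transform, all-pairs shortest paths, SMR matrix and
    the scale aggregations; returns both the per-edge matrix and the summary.
    """
    if not c.is_connected():
        raise ConnectomeError("network is disconnected; shortest paths undefined")
    d = distance_transform(c)
    dt = all_pairs_shortest_paths(d)
    s = smr_matrix(d, dt, tol=tol)
    smr = smr_scales(s, c.regions, zero_right="nan")
    smp_node, smp_global, smp_left, smp_right = smp_scales(s, c.regions)
    summary = SemiMetricSummary(
        smr_global=smr["smr_global"],
        smr_left=smr["smr_left"],
        smr_right=smr["smr_right"],
        smr_inter=smr["smr_inter"],
        bai=smr["bai"],
        smp_node=smp_node,
        smp_global=smp_global,
        smp_left=smp_left,
        smp_right=smp_right,
    )
    return s, summary


def analyze_subject(c: WeightedConnectome) -> SemiMetricSummary:
    """Semi-metric summary of one subject's integrated network."""
    return semimetric_profile(c)[1]
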