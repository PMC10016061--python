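"""Data model, I/O and basic descriptors for weighted structural brain networks.

A structural brain network (SBN) is an undirected weighted graph whose nodes
are brain parcels (here the 90-region AAL parcellation, 45 per hemisphere)
and whose edge weights summarise white-matter connectivity between parcels.
Every downstream stage of the pipeline — topological filtering, multi-layer
fusion, semi-metric analysis — consumes and produces the
:class:`WeightedConnectome` defined here.

Connectivity matrices are plain delimited text: one square ``N x N`` matrix
per (subject, metric) pair, whitespace- or comma-separated.  Node indices are
1-based in files and reports, matching the AAL convention; hemisphere
membership always comes from the :class:`RegionTable`, never from index
parity.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

HEMISPHERES = ("L", "R")

#: The nine connectivity metrics, in canonical layer order: fractional
#: anisotropy, mean diffusivity, radial diffusivity, number of streamlines,
#: percentage of streamlines, streamline density, tract volume, tract length,
#: Euclidean distance between node centroids.
METRIC_LAYERS = ("FA", "MD", "RD", "NS", "PS", "SLD", "TV", "TL", "ED")

#: Metric name of the fused network produced by layer integration.
INTEGRATED = "integrated"

#: Default tolerance for repairing numerically asymmetric input matrices.
#: Tractography outputs are symmetric by construction; larger asymmetry
#: signals corrupted input.
ASYMMETRY_TOL = 1e-8


class ConnectomeError(ValueError):
    """A connectivity matrix or region table violates the data model."""


# ---------------------------------------------------------------------------
# Region table


@dataclass(frozen=True)
class RegionTable:
    """Ordered node lookup: region name and hemisphere label per node.

    Node ``i`` (1-based in every external interface) has name ``names[i-1]``
    and hemisphere ``hemispheres[i-1]`` (``"L"`` or ``"R"``).  Homologous
    regions are matched by base name: ``Hippocampus_L`` and ``Hippocampus_R``
    share the base ``Hippocampus``.
    """

    names: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.hemispheres):
            raise ConnectomeError("names and hemispheres differ in length")
        if len(self.names) == 0:
            raise ConnectomeError("empty region table")
        if len(set(self.names)) != len(self.names):
            raise ConnectomeError("duplicate region names")
        bad = sorted(set(self.hemispheres) - set(HEMISPHERES))
        if bad:
            raise ConnectomeError(f"invalid hemisphere labels: {bad}")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def left_indices(self) -> np.ndarray:
        """0-based indices of left-hemisphere nodes."""
        return np.flatnonzero(np.asarray(self.hemispheres) == "L")

    @property
    def right_indices(self) -> np.ndarray:
        """0-based indices of right-hemisphere nodes."""
        return np.flatnonzero(np.asarray(self.hemispheres) == "R")

    def base_name(self, i: int) -> str:
        """Base (hemisphere-free) name of 0-based node ``i``."""
        name = self.names[i]
        for suffix in ("_L", "_R"):
            if name.endswith(suffix):
                return name[: -len(suffix)]
        return name

    def homologous_pairs(self) -> list[tuple[str, int, int]]:
        """``(base_name, left_index, right_index)`` for every bilateral pair.

        Raises if any base name does not resolve to exactly one node per
        hemisphere.
        """
        left: dict[str, int] = {}
        right: dict[str, int] = {}
        for i, h in enumerate(self.hemispheres):
            base = self.base_name(i)
            side = left if h == "L" else right
            if base in side:
                raise ConnectomeError(f"base name {base!r} duplicated in {h}")
            side[base] = i
        if set(left) != set(right):
            odd = sorted(set(left) ^ set(right))
            raise ConnectomeError(f"regions without a homologue: {odd}")
        return [(b, left[b], right[b]) for b in sorted(left, key=left.get)]

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionTable":
        """Read a region table CSV with columns ``index,name,hemisphere``.

        Indices must be the consecutive integers ``1..N``.
        """
        df = pd.read_csv(path)
        required = {"index", "name", "hemisphere"}
        if not required.issubset(df.columns):
            raise ConnectomeError(f"region table needs columns {sorted(required)}")
        df = df.sort_values("index")
        expected = np.arange(1, len(df) + 1)
        if not np.array_equal(df["index"].to_numpy(), expected):
            raise ConnectomeError("region indices must be consecutive 1..N")
        return cls(tuple(df["name"].astype(str)), tuple(df["hemisphere"].astype(str)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "index": np.arange(1, self.n + 1),
                "name": self.names,
                "hemisphere": self.hemispheres,
            }
        ).to_csv(path, index=False)

    @classmethod
    def aal90(cls) -> "RegionTable":
        """The 90-region AAL cerebrum lookup (45 regions per hemisphere)."""
        return _load_aal90()

    @classmethod
    def generic(cls, n_nodes: int) -> "RegionTable":
        """A synthetic bilateral table with ``n_nodes/2`` regions per side.

        Regions interleave L/R like the AAL ordering; base names are
        ``region01 .. regionK``.
        """
        if n_nodes < 2 or n_nodes % 2:
            raise ConnectomeError("generic region table needs an even n_nodes >= 2")
        names: list[str] = []
        hemis: list[str] = []
        for k in range(n_nodes // 2):
            names += [f"region{k + 1:02d}_L", f"region{k + 1:02d}_R"]
            hemis += ["L", "R"]
        return cls(tuple(names), tuple(hemis))


@functools.lru_cache(maxsize=1)
def _load_aal90() -> RegionTable:
    with resources.as_file(
        resources.files("semiconn.data").joinpath("aal90.csv")
    ) as p:
        table = RegionTable.from_csv(p)
    if table.n != 90:
        raise ConnectomeError("packaged AAL table is corrupted")
    return table


# ---------------------------------------------------------------------------
# Weighted connectome


@dataclass
class WeightedConnectome:
    """One symmetric nonnegative weighted network with a hemisphere partition.

    Invariants enforced at construction: square matrix matching the region
    table, finite nonnegative entries, exact symmetry, zero diagonal.
    ``max == 1`` is *not* required here — it is established by
    :func:`normalize_connectome`, which is an explicit pipeline stage.
    """

    weights: np.ndarray
    regions: RegionTable
    metric_name: str = "unknown"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] != self.regions.n:
            raise ConnectomeError(
                f"matrix size {w.shape[0]} does not match region table "
                f"({self.regions.n} regions)"
            )
        if not np.all(np.isfinite(w)):
            raise ConnectomeError("non-finite weights")
        if np.any(w < 0):
            raise ConnectomeError("negative weights")
        if not np.array_equal(w, w.T):
            raise ConnectomeError("weights not symmetric")
        if np.any(np.diagonal(w) != 0):
            raise ConnectomeError("nonzero diagonal (self-connections)")
        self.weights = w

    @property
    def n(self) -> int:
        return self.regions.n

    def edge_mask(self) -> np.ndarray:
        """Boolean upper-triangle mask of existing (positive-weight) edges."""
        return np.triu(self.weights > 0, k=1)

    def edge_count(self) -> int:
        return int(self.edge_mask().sum())

    def is_connected(self) -> bool:
        graph = sparse.csr_matrix(self.weights)
        n_comp, _ = connected_components(graph, directed=False)
        return n_comp == 1

    def with_weights(
        self, weights: np.ndarray, metric_name: str | None = None
    ) -> "WeightedConnectome":
        return WeightedConnectome(
            weights, self.regions, metric_name or self.metric_name
        )


@dataclass
class MultiLayerConnectome:
    """The per-metric networks of one subject, keyed by metric name."""

    subject_id: str
    layers: dict[str, WeightedConnectome]

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ConnectomeError("no layers")
        first = next(iter(self.layers.values())).regions
        for name, c in self.layers.items():
            if c.regions is not first and c.regions != first:
                raise ConnectomeError(f"layer {name!r} uses a different region table")
            if c.metric_name != name:
                raise ConnectomeError(
                    f"layer key {name!r} does not match metric_name {c.metric_name!r}"
                )

    @property
    def regions(self) -> RegionTable:
        return next(iter(self.layers.values())).regions

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(self.layers)


# ---------------------------------------------------------------------------
# I/O


def read_connectome(
    path: str | Path,
    regions: RegionTable,
    metric_name: str,
    asymmetry_tol: float = ASYMMETRY_TOL,
) -> WeightedConnectome:
    """Read one delimited square connectivity matrix.

    Accepts comma- or whitespace-delimited numeric text.  The matrix must be
    ``N x N`` with ``N == regions.n`` and nonnegative.  Asymmetry up to
    ``asymmetry_tol`` (absolute) is repaired by averaging ``W`` with its
    transpose; anything larger is an error.  The diagonal is forced to zero
    (self-connections carry no information).
    """
    try:
        df = pd.read_csv(path, header=None, sep=r"[,\s]+", engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ConnectomeError(f"cannot parse matrix file {path}: {exc}") from exc
    try:
        w = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ConnectomeError(f"non-numeric cells in {path}") from exc
    if w.ndim != 2 or w.shape != (regions.n, regions.n):
        raise ConnectomeError(
            f"{path}: expected {regions.n}x{regions.n} matrix, got {w.shape}"
        )
    if not np.all(np.isfinite(w)):
        raise ConnectomeError(f"{path}: non-finite entries")
    if np.any(w < 0):
        raise ConnectomeError(f"{path}: negative entries")
    asym = float(np.max(np.abs(w - w.T)))
    if asym > asymmetry_tol:
        raise ConnectomeError(
            f"{path}: asymmetry {asym:g} exceeds tolerance {asymmetry_tol:g}"
        )
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedConnectome(w, regions, metric_name)


def write_connectome(c: WeightedConnectome, path: str | Path) -> None:
    """Write a connectome as comma-delimited text, round-trip safe."""
    np.savetxt(path, c.weights, delimiter=",", fmt="%.17g")


# ---------------------------------------------------------------------------
# Normalisation and descriptors


def normalize_connectome(c: WeightedConnectome) -> WeightedConnectome:
    """Scale weights so the maximum edge weight equals 1.

    The diagonal is (re-)zeroed before the maximum is taken.  An all-zero
    matrix carries no network and is rejected.  Idempotent.
    """
    w = c.weights.copy()
    np.fill_diagonal(w, 0.0)
    m = float(w.max())
    if m <= 0:
        raise ConnectomeError("all-zero connectome cannot be normalized")
    if m == 1.0:
        return c.with_weights(w)
    return c.with_weights(w / m)


@dataclass(frozen=True)
class NetworkDescriptors:
    """Sparsity and strength decomposition of one network.

    Each undirected edge is counted once: ``global_strength`` is the sum of
    upper-triangle weights, and ``left + right + inter == global`` up to
    float tolerance.
    """

    sparsity: float
    global_strength: float
    left_strength: float
    right_strength: float
    inter_strength: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sparsity": self.sparsity,
            "global_strength": self.global_strength,
            "left_strength": self.left_strength,
            "right_strength": self.right_strength,
            "inter_strength": self.inter_strength,
        }


def descriptors(c: WeightedConnectome) -> NetworkDescriptors:
    """Sparsity plus global / hemispheric / interhemispheric strength.

    Sparsity is the number of existing edges divided by the number of
    possible edges ``N(N-1)/2`` (4005 for the 90-node parcellation).
    """
    n = c.n
    possible = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    w = c.weights[iu]
    hemi = np.asarray(c.regions.hemispheres)
    hi, hj = hemi[iu[0]], hemi[iu[1]]
    left = (hi == "L") & (hj == "L")
    right = (hi == "R") & (hj == "R")
    inter = hi != hj
    return NetworkDescriptors(
        sparsity=float(np.count_nonzero(w) / possible),
        global_strength=float(w.sum()),
        left_strength=float(w[left].sum()),
        right_strength=float(w[right].sum()),
        inter_strength=float(w[inter].sum()),
    )
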