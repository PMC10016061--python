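"""Synthetic multi-metric connectome cohorts.

The cohort data this pipeline was designed around (diffusion-MRI networks of
young adults recruited by polygenic-risk extremes) is access-restricted, so
every downstream stage is exercised on synthetic connectomes that emulate its
structural regime:

* 90 nodes split 45/45 by hemisphere (any even node count is supported);
* a latent *mirror-symmetric* backbone: node positions are drawn for one
  hemisphere and reflected, intra-hemispheric edges follow a
  distance-dependent random geometric rule (weight ``exp(-dist/scale)``),
  the right block mirrors the left exactly, and a thinner interhemispheric
  block always includes the homotopic (mirror-pair) edges;
* nine layers that are rank-preserving noisy monotone transforms of the
  backbone with controllable pairwise correlation — the integration stage
  only consumes their mutual (dis)similarity, not biophysics;
* a configurable group effect: in the "high" group a fraction of intra-left
  edges is attenuated (multiplied by ``effect_attenuation``, each edge in a
  random subset of layers), weakening direct routes so shortest paths
  reroute and left-hemisphere semi-metricity rises.
  ``effect_attenuation = 1`` is the exchangeable null.

Everything is deterministic given the config seed; per-subject seeds derive
from ``(cfg.seed, group, subject index)`` via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst
from scipy.spatial.distance import cdist

from .core import (
    METRIC_LAYERS,
    ConnectomeError,
    MultiLayerConnectome,
    RegionTable,
    WeightedConnectome,
)
from .volumes import VolumeSet

GROUPS = ("low", "high")

# spawn keys separating the independent random streams of one config
_KEY_BACKBONE = 0
_KEY_MANIFEST = 1
_KEY_SUBJECT = 2
_KEY_VOLUMES = 3

#: Spatial decay scale of edge weights, in unit-cube coordinates.  Sets the
#: weight heterogeneity and hence the baseline level of semi-metricity.
LENGTH_SCALE = 1.0

#: Interhemispheric edge density as a fraction of the intra-hemispheric one
#: (callosal connections are sparser than within-hemisphere wiring).
INTER_DENSITY_RATIO = 0.5

#: Probability that an effect-selected edge is attenuated in any given layer.
#: The group effect weakens each selected intra-left edge in a random subset
#: of layers rather than all of them: the direct route then drops out of the
#: topological filter in the attenuated layers (shortest paths reroute) while
#: the remaining layers keep it present, so the fused network carries the
#: edge with reduced weight instead of losing it outright.
EFFECT_LAYER_FRACTION = 0.7


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions emulated.

    ``n_per_group=90`` matches the imaging cohort (two groups of ~90);
    ``effect_attenuation=0.3`` applied to ``effect_edge_fraction=0.25`` of
    intra-left edges is the canonical injected effect, set to 1.0 for null
    cohorts.  ``layer_correlation`` is the shared fraction of log-noise
    between layers; ``noise_sd`` the log-scale noise level.
    """

    n_per_group: int = 90
    n_nodes: int = 90
    baseline_density: float = 0.6
    layer_count: int = 9
    layer_correlation: float = 0.9
    effect_attenuation: float = 0.3
    effect_edge_fraction: float = 0.25
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConnectomeError("n_per_group must be positive")
        if self.n_nodes < 4 or self.n_nodes % 2:
            raise ConnectomeError("n_nodes must be an even integer >= 4")
        if not 0 < self.baseline_density <= 1:
            raise ConnectomeError("baseline_density must be in (0, 1]")
        if self.layer_count < 1:
            raise ConnectomeError("layer_count must be positive")
        if not 0 <= self.layer_correlation <= 1:
            raise ConnectomeError("layer_correlation must be in [0, 1]")
        if not 0 < self.effect_attenuation <= 1:
            raise ConnectomeError("effect_attenuation must be in (0, 1]")
        if not 0 <= self.effect_edge_fraction <= 1:
            raise ConnectomeError("effect_edge_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConnectomeError("noise_sd must be nonnegative")

    def layer_names(self) -> tuple[str, ...]:
        """Layer keys: the nine canonical metric names, or ``layer01..`` when
        a different layer count is requested."""
        if self.layer_count == len(METRIC_LAYERS):
            return METRIC_LAYERS
        return tuple(f"layer{i + 1:02d}" for i in range(self.layer_count))

    def region_table(self) -> RegionTable:
        return RegionTable.aal90() if self.n_nodes == 90 else RegionTable.generic(self.n_nodes)


# ---------------------------------------------------------------------------
# Fig.-style toy fixture

#: 1-based undirected edges of the five-node worked example.
TOY_EDGES: dict[tuple[int, int], float] = {
    (1, 2): 0.4,
    (2, 3): 0.4,
    (1, 5): 0.2,
    (2, 5): 0.1,
    (4, 5): 0.3,
    (3, 4): 0.2,
}


def make_toy_network() -> WeightedConnectome:
    """The five-node proximity toy network used in worked examples.

    All nodes are assigned to the left hemisphere; no normalisation is
    applied (the maximum weight is already below 1).
    """
    w = np.zeros((5, 5))
    for (i, j), v in TOY_EDGES.items():
        w[i - 1, j - 1] = w[j - 1, i - 1] = v
    regions = RegionTable(
        names=tuple(f"node{i}" for i in range(1, 6)), hemispheres=("L",) * 5
    )
    return WeightedConnectome(w, regions, metric_name="toy")


def path_weight_sum(c: WeightedConnectome, path: list[int] | tuple[int, ...]) -> float:
    """Sum of raw edge weights along a 1-based node path; errors on a gap."""
    total = 0.0
    for a, b in zip(path[:-1], path[1:]):
        w = c.weights[a - 1, b - 1]
        if w <= 0:
            raise ConnectomeError(f"no edge between nodes {a} and {b}")
        total += float(w)
    return total


# ---------------------------------------------------------------------------
# Backbone


@functools.lru_cache(maxsize=16)
def _backbone(cfg: SyntheticConfig) -> tuple[RegionTable, np.ndarray]:
    """Mirror-symmetric latent weight matrix shared by a config's cohort."""
    regions = cfg.region_table()
    n = cfg.n_nodes
    pairs = regions.homologous_pairs()
    h = len(pairs)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(_KEY_BACKBONE,))
    )
    base_pos = rng.uniform(size=(h, 3))
    pos = np.zeros((n, 3))
    for k, (_, li, ri) in enumerate(pairs):
        pos[li] = base_pos[k]
        pos[ri] = base_pos[k] * (-1, 1, 1) + (2.0, 0.0, 0.0)  # mirror at x=1
    strength = np.exp(-cdist(pos, pos) / LENGTH_SCALE)
    np.fill_diagonal(strength, 0.0)

    hemi = np.asarray(regions.hemispheres)
    left_block = (hemi[:, None] == "L") & (hemi[None, :] == "L")
    inter_block = hemi[:, None] != hemi[None, :]
    triu = np.triu(np.ones((n, n), dtype=bool), k=1)

    w = np.zeros((n, n))
    # intra-left edges: strongest baseline_density fraction, then mirrored
    left_pairs = np.argwhere(left_block & triu)
    s_left = strength[left_pairs[:, 0], left_pairs[:, 1]]
    k_keep = max(h - 1, int(round(cfg.baseline_density * len(left_pairs))))
    keep = np.argsort(s_left)[::-1][:k_keep]
    li_of = {b: li for b, li, _ in pairs}
    ri_of = {b: ri for b, _, ri in pairs}
    base_of = {li: b for b, li, _ in pairs}
    for idx in keep:
        i, j = left_pairs[idx]
        v = strength[i, j]
        w[i, j] = w[j, i] = v
        mi, mj = ri_of[base_of[i]], ri_of[base_of[j]]
        w[mi, mj] = w[mj, mi] = v  # exact mirror weight
    # interhemispheric: homotopic pairs always present, plus strongest others
    for _, li, ri in pairs:
        w[li, ri] = w[ri, li] = strength[li, ri]
    inter_pairs = np.argwhere(inter_block & triu)
    s_inter = strength[inter_pairs[:, 0], inter_pairs[:, 1]]
    k_inter = int(round(cfg.baseline_density * INTER_DENSITY_RATIO * len(inter_pairs)))
    for idx in np.argsort(s_inter)[::-1][:k_inter]:
        i, j = inter_pairs[idx]
        w[i, j] = w[j, i] = strength[i, j]
    # connectivity guarantee: union with the maximum-weight spanning tree of
    # the full proximity graph, symmetrised across hemispheres
    with np.errstate(divide="ignore"):
        dist = np.where(strength > 0, 1.0 / strength, 0.0)
    mst = _scipy_mst(sparse.csr_matrix(dist)).tocoo()
    for i, j in zip(mst.row, mst.col):
        for a, b in _mirrored_edge(int(i), int(j), hemi, base_of, li_of, ri_of):
            if w[a, b] == 0:
                w[a, b] = w[b, a] = strength[a, b]
    return regions, w


def _mirrored_edge(i, j, hemi, base_of_left, li_of, ri_of):
    """An edge plus its hemisphere-mirrored counterpart (if intra-hemispheric)."""
    yield i, j
    right_base = {v: k for k, v in ri_of.items()}

    def mirror(x):
        if hemi[x] == "L":
            return ri_of[base_of_left[x]]
        return li_of[right_base[x]]

    if hemi[i] == hemi[j]:
        yield mirror(i), mirror(j)


# ---------------------------------------------------------------------------
# Subjects and cohorts


def subject_seed(cfg: SyntheticConfig, group: str, index: int) -> int:
    """Deterministic per-subject seed from ``(cfg.seed, group, index)``."""
    g = GROUPS.index(group)
    ss = np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(_KEY_SUBJECT, g, index)
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def generate_subject(
    cfg: SyntheticConfig, group: str, subject_seed: int, subject_id: str | None = None
) -> MultiLayerConnectome:
    """One subject's multi-layer connectome.

    Layers share the config's mirror-symmetric backbone; each layer applies a
    fixed monotone power transform plus correlated log-normal noise.  For the
    "high" group, ``effect_edge_fraction`` of the intra-left edges (chosen by
    the subject's own generator) are multiplied by ``effect_attenuation``,
    each in a random ``EFFECT_LAYER_FRACTION`` of the layers, so the
    weakened routes reroute in those layers yet stay present in the fused
    network.  Byte-identical output for identical arguments.
    """
    if group not in GROUPS:
        raise ConnectomeError(f"group must be one of {GROUPS}")
    regions, backbone = _backbone(cfg)
    rng = np.random.default_rng(int(subject_seed))
    n = cfg.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    present = backbone[iu, ju] > 0
    ei, ej = iu[present], ju[present]
    base_w = backbone[ei, ej]
    m = len(base_w)

    hemi = np.asarray(regions.hemispheres)
    intra_left = (hemi[ei] == "L") & (hemi[ej] == "L")
    chosen = np.array([], dtype=int)
    if group == "high" and cfg.effect_attenuation < 1:
        left_idx = np.flatnonzero(intra_left)
        k = int(round(cfg.effect_edge_fraction * len(left_idx)))
        # the lesion targets established (above-median-weight) connections:
        # weak edges are rarely retained by the topological filter, so
        # attenuating them would not perturb the filtered network at all
        left_w = base_w[left_idx]
        eligible = left_idx[left_w >= np.median(left_w)]
        chosen = rng.choice(eligible, size=min(k, eligible.size), replace=False)

    rho = cfg.layer_correlation
    shared = rng.standard_normal(m)
    gammas = _layer_gammas(cfg.layer_count)
    layers: dict[str, WeightedConnectome] = {}
    for name, gamma in zip(cfg.layer_names(), gammas):
        mult = np.ones(m)
        if chosen.size:
            hit = chosen[rng.random(chosen.size) < EFFECT_LAYER_FRACTION]
            mult[hit] = cfg.effect_attenuation
        eps = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal(m)
        vals = (base_w**gamma) * np.exp(cfg.noise_sd * eps) * mult
        w = np.zeros((n, n))
        w[ei, ej] = vals
        w[ej, ei] = vals
        layers[name] = WeightedConnectome(w, regions, metric_name=name)
    sid = subject_id or f"sub-{group}-{int(subject_seed):010d}"
    return MultiLayerConnectome(subject_id=sid, layers=layers)


def _layer_gammas(layer_count: int) -> np.ndarray:
    """Monotone power exponents making layers distinct but rank-preserving."""
    if layer_count == 1:
        return np.array([1.0])
    return np.linspace(0.7, 1.4, layer_count)


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[list[MultiLayerConnectome], pd.DataFrame]:
    """A full two-group cohort plus its manifest.

    The manifest carries ``subject_id, group, sex, age, seed`` (sex balanced
    within group, age drawn near 22 years — interface completeness only).
    Two calls with the same config return identical cohorts.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(_KEY_MANIFEST,))
    )
    subjects: list[MultiLayerConnectome] = []
    rows = []
    for group in GROUPS:
        for i in range(cfg.n_per_group):
            sid = f"sub-{group}{i + 1:03d}"
            seed_i = subject_seed(cfg, group, i)
            subjects.append(generate_subject(cfg, group, seed_i, subject_id=sid))
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "sex": "F" if i % 2 == 0 else "M",
                    "age": float(np.round(rng.normal(22.1, 0.8), 2)),
                    "seed": seed_i,
                }
            )
    return subjects, pd.DataFrame(rows)


def generate_volumes(
    cfg: SyntheticConfig, asymmetry_shift: float = 0.0
) -> dict[str, VolumeSet]:
    """Per-subject regional volumes plus hemispheric intracranial volumes.

    Region base volumes are fixed per config; left-hemisphere volumes are
    scaled by ``(1 + asymmetry_shift)``; multiplicative log-normal noise with
    scale ``cfg.noise_sd`` perturbs subject volumes (zero noise makes the
    volumetric asymmetry index exactly ``1 + asymmetry_shift`` under equal
    ICVs).  Keys match :func:`generate_cohort`'s subject ids.
    """
    if asymmetry_shift <= -1:
        raise ConnectomeError("asymmetry_shift must exceed -1 (positive volumes)")
    regions = cfg.region_table()
    pairs = regions.homologous_pairs()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(_KEY_VOLUMES,))
    )
    # fixed per-region base volumes, mirrored across hemispheres (mm^3)
    base = rng.uniform(3000.0, 15000.0, size=len(pairs))
    base_icv = 7.3e5  # half-brain intracranial volume, mm^3
    out: dict[str, VolumeSet] = {}
    for group in GROUPS:
        for i in range(cfg.n_per_group):
            sid = f"sub-{group}{i + 1:03d}"
            vols = np.zeros(regions.n)
            noise = rng.standard_normal(regions.n)
            for k, (_, li, ri) in enumerate(pairs):
                vols[li] = base[k] * (1.0 + asymmetry_shift)
                vols[ri] = base[k]
            vols = vols * np.exp(cfg.noise_sd * 0.2 * noise)
            icv_l = base_icv * float(np.exp(cfg.noise_sd * 0.05 * rng.standard_normal()))
            icv_r = base_icv * float(np.exp(cfg.noise_sd * 0.05 * rng.standard_normal()))
            out[sid] = VolumeSet(volumes=vols, icv_left=icv_l, icv_right=icv_r)
    return out
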