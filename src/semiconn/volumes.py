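"""Volumetric brain-asymmetry index (BAI^Vol).

Regional gray-matter volumes, normalised by hemispheric intracranial volume
(ICV), are summed per hemisphere over a bilateral subnetwork; the index is
the left/right ratio of those sums (> 1 leftward asymmetry).  Shipped
subnetworks: the 13-region language network, the conventional AAL
subcortical set, and the whole cerebrum.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .core import ConnectomeError, RegionTable


@dataclass
class VolumeSet:
    """Per-region volumes (mm^3) plus hemispheric intracranial volumes."""

    volumes: np.ndarray
    icv_left: float
    icv_right: float

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=np.float64)
        if v.ndim != 1:
            raise ConnectomeError("volumes must be a flat vector")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ConnectomeError("volumes must be positive and finite")
        if self.icv_left <= 0 or self.icv_right <= 0:
            raise ConnectomeError("intracranial volumes must be positive")
        self.volumes = v


@dataclass(frozen=True)
class SubnetworkDefinition:
    """A named bilateral subnetwork given by hemisphere-free base names."""

    name: str
    region_names: tuple[str, ...]

    def resolve(self, regions: RegionTable) -> tuple[np.ndarray, np.ndarray]:
        """0-based (left, right) node indices; each base name must match
        exactly one region per hemisphere."""
        pairs = {b: (li, ri) for b, li, ri in regions.homologous_pairs()}
        missing = [r for r in self.region_names if r not in pairs]
        if missing:
            raise ConnectomeError(
                f"subnetwork {self.name!r}: unresolvable regions {missing}"
            )
        left = np.array([pairs[r][0] for r in self.region_names], dtype=int)
        right = np.array([pairs[r][1] for r in self.region_names], dtype=int)
        return left, right


@functools.lru_cache(maxsize=1)
def _fixtures() -> dict[str, tuple[str, ...]]:
    with resources.files("semiconn.data").joinpath("subnetworks.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {k: tuple(v) for k, v in raw.items()}


def language_network() -> SubnetworkDefinition:
    """The 13-region bilateral language network."""
    return SubnetworkDefinition("language", _fixtures()["language"])


def subcortical_network() -> SubnetworkDefinition:
    """The conventional AAL subcortical set (an interpretation; see docs)."""
    return SubnetworkDefinition("subcortical", _fixtures()["subcortical"])


def whole_brain(regions: RegionTable) -> SubnetworkDefinition:
    """All bilateral base regions of a table."""
    bases = tuple(b for b, _, _ in regions.homologous_pairs())
    return SubnetworkDefinition("whole_brain", bases)


def default_subnetworks(regions: RegionTable) -> list[SubnetworkDefinition]:
    """The three networks analysed: whole brain, language, subcortical.

    On non-AAL (synthetic) region tables the named lists cannot resolve, so
    synthetic stand-ins of matching sizes (the first 13 and next 6 base
    regions) are substituted to keep the three-network analysis exercised.
    """
    nets = [whole_brain(regions)]
    try:
        lang = language_network()
        lang.resolve(regions)
        sub = subcortical_network()
        sub.resolve(regions)
        nets += [lang, sub]
    except ConnectomeError:
        bases = [b for b, _, _ in regions.homologous_pairs()]
        n_lang, n_sub = min(13, len(bases)), min(6, len(bases))
        nets += [
            SubnetworkDefinition("language_synthetic", tuple(bases[:n_lang])),
            SubnetworkDefinition(
                "subcortical_synthetic", tuple(bases[n_lang : n_lang + n_sub] or bases[:n_sub])
            ),
        ]
    return nets


def bai_vol(
    v: VolumeSet, net: SubnetworkDefinition, regions: RegionTable
) -> float:
    """Left/right ratio of ICV-normalised volume sums over a subnetwork.

    Always positive; exactly 1 under mirrored volumes with equal ICVs, and
    invariant to rescaling all volumes and ICVs by one constant.
    """
    if len(v.volumes) != regions.n:
        raise ConnectomeError("volume vector does not match the region table")
    left, right = net.resolve(regions)
    left_sum = float((v.volumes[left] / v.icv_left).sum())
    right_sum = float((v.volumes[right] / v.icv_right).sum())
    if right_sum == 0:
        raise ConnectomeError("zero right-hemisphere volume sum")
    return left_sum / right_sum
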