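"""Decompose a fitted potential into contributions from source sub-regions.

Because K(x, y) = sum_i b_i(x) b_i(y) is a sum over basis sources, any
partition of the sources into regions splits the kernel additively,
K = K1 + K2, and the contribution of region T to the potential is

    V1(x) = K1(x, .) (K + lambda I)^-1 V,   K1(x, x_j) = sum_{i in T} b_i(x) b_i(x_j).

The full-data fit is always used; only the cross-kernel is restricted.
Basis sources falling outside every named region are collected in an
implicit ``margin`` region reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .forward import potential_basis_matrix
from .geometry import EvokedPotential
from .kcsd import BasisConfig, KcsdFit, interp_potential

#: Name of the implicit region collecting basis sources outside all named
#: regions (typically the anti-edge-effect margin zone).
MARGIN_REGION = "margin"


@dataclass
class RegionPartition:
    """Disjoint assignment of every basis source to exactly one region."""

    basis: BasisConfig
    member_indices: dict  # region name -> np.ndarray of basis indices

    def __post_init__(self) -> None:
        counts = sum(len(v) for v in self.member_indices.values())
        all_idx = np.sort(np.concatenate([
            np.asarray(v, dtype=int) for v in self.member_indices.values()
        ])) if counts else np.array([], dtype=int)
        if counts != self.basis.n_sources or not np.array_equal(
            all_idx, np.arange(self.basis.n_sources)
        ):
            raise ValidationError(
                "member_indices must partition all basis sources exactly once"
            )

    def size(self, region_name: str) -> int:
        return len(self.member_indices[region_name])


def partition_basis(basis: BasisConfig, regions, strict: bool = False) -> RegionPartition:
    """Assign each basis source to the first listed region containing its center.

    Boundary centers (exactly on a shared face) go to the region listed
    first — deterministic.  Centers covered by no region are collected under
    :data:`MARGIN_REGION`; with ``strict=True`` they raise instead, listing
    the orphan centers.
    """
    assigned = np.full(basis.n_sources, -1, dtype=int)
    for k, region in enumerate(regions):
        inside = region.contains(basis.centers)
        assigned[(assigned == -1) & inside] = k
    member = {
        region.name: np.flatnonzero(assigned == k) for k, region in enumerate(regions)
    }
    orphans = np.flatnonzero(assigned == -1)
    if orphans.size:
        if strict:
            raise ValidationError(
                f"{orphans.size} basis centers are covered by no region, e.g. "
                f"{basis.centers[orphans[:5]].tolist()}"
            )
        member[MARGIN_REGION] = orphans
    return RegionPartition(basis=basis, member_indices=member)


def region_contribution(
    fit: KcsdFit, partition: RegionPartition, region_name: str, points: np.ndarray
) -> np.ndarray:
    """Potential contribution (mV) of one region's sources at ``points``, (P, T)."""
    if region_name not in partition.member_indices:
        raise KeyError(f"region {region_name!r} not present in partition")
    idx = partition.member_indices[region_name]
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if idx.size == 0:
        return np.zeros((pts.shape[0], fit.beta.shape[1]))
    kernels = fit.kernels
    Bp = potential_basis_matrix(
        pts, kernels.basis.centers[idx], kernels.basis.width, kernels.medium
    )  # (P, L)
    K1 = Bp @ kernels.B[:, idx].T  # (P, N)
    return K1 @ fit.beta


def contribution_summary(
    fit: KcsdFit, partition: RegionPartition, ep: EvokedPotential
) -> dict:
    """Per-region potential traces at the measurement electrodes plus residual.

    Returns ``{region: (n_active, T) mV, ..., "residual": measured - total}``.
    The region traces sum exactly to the kernel-interpolated potential at the
    electrodes, so regions + residual = measured EP identically.
    """
    pts = ep.grid.active_positions
    out = {
        name: region_contribution(fit, partition, name, pts)
        for name in partition.member_indices
    }
    total = interp_potential(fit, pts)
    out["residual"] = ep.values - total
    return out
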