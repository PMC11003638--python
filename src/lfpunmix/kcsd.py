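"""Kernel current-source-density engine.

Given measured potentials V at N electrodes and M Gaussian basis sources,
the kernel K_jk = sum_i b_i(x_j) b_i(x_k) interpolates the potential,
beta = (K + lambda I)^-1 V, and the cross-kernel
K~(x, x_j) = sum_i b~_i(x) b_i(x_j) maps the coefficients into CSD space:

    C(x)  = K~(x, .) (K + lambda I)^-1 V
    V*(x) = sum_j beta_j K(x, x_j)

One regularization parameter is used for all time samples; the symmetric
factorization of (K + lambda I) is computed once and reused across time
columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .exceptions import ValidationError
from .forward import basis_matrix, csd_basis_matrix, potential_basis_matrix
from .geometry import ElectrodeGrid, EvokedPotential, Medium, Region

log = logging.getLogger(__name__)


@dataclass
class BasisConfig:
    """Set of M unit-current Gaussian basis sources sharing one width."""

    centers: np.ndarray  # (M, 3) mm
    width: float  # R, mm
    region_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] < 1 or self.centers.shape[1] != 3:
            raise ValidationError("basis centers must form a nonempty (M, 3) array")
        if not self.width > 0:
            raise ValidationError(f"basis width must be > 0, got {self.width}")
        if not self.region_labels:
            self.region_labels = [""] * len(self.centers)
        if len(self.region_labels) != len(self.centers):
            raise ValidationError("region_labels length must equal number of centers")

    @property
    def n_sources(self) -> int:
        return self.centers.shape[0]


@dataclass
class KernelSet:
    """Electrode-space kernel K = B B^T plus the ingredients to rebuild it.

    ``B`` is the (n_active, M) forward matrix b_i(x_j); it is kept so cross
    kernels at arbitrary points and region-restricted kernels can be formed
    without re-evaluating the forward model at the electrodes.
    """

    K: np.ndarray
    B: np.ndarray
    basis: BasisConfig
    grid: ElectrodeGrid
    medium: Medium

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = self.grid.n_active
        if self.K.shape != (n, n):
            raise ValidationError(f"K must be ({n}, {n}), got {self.K.shape}")
        scale = np.abs(self.K).max() or 1.0
        if not np.allclose(self.K, self.K.T, rtol=1e-10, atol=1e-10 * scale):
            raise ValidationError("kernel matrix must be symmetric")


@dataclass
class KcsdFit:
    """Regularized fit: per-time-sample coefficients beta and chosen lambda."""

    kernels: KernelSet
    lam: float
    beta: np.ndarray  # (n_active, T)
    times: np.ndarray  # (T,) ms

    @property
    def alpha(self) -> np.ndarray:
        """Source-space coefficients alpha_i = sum_j beta_j b_i(x_j), (M, T)."""
        return self.kernels.B.T @ self.beta


# ---------------------------------------------------------------------------
# Basis placement
# ---------------------------------------------------------------------------


def _axis_lattice(lo: float, hi: float, spacing: float) -> np.ndarray:
    """1D lattice with exact ``spacing`` centred in [lo, hi].

    Degenerate axes (extent < spacing) get a single point at the midplane.
    When the spacing divides the extent the faces are included.
    """
    extent = hi - lo
    n = int(np.floor(extent / spacing + 1e-9)) + 1
    if n <= 1:
        return np.array([0.5 * (lo + hi)])
    offset = 0.5 * (extent - (n - 1) * spacing)
    return lo + offset + spacing * np.arange(n)


def place_basis(region: Region, spacing: float, width: float) -> BasisConfig:
    """Tile every cuboid of ``region`` with a regular lattice of basis sources."""
    if not spacing > 0:
        raise ValidationError(f"spacing must be > 0, got {spacing}")
    if not width > 0:
        raise ValidationError(f"width must be > 0, got {width}")
    centers = []
    for box in region.cuboids:
        axes = [_axis_lattice(box[0, d], box[1, d], spacing) for d in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        centers.append(np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]))
    centers = np.concatenate(centers, axis=0)
    return BasisConfig(
        centers=centers, width=width, region_labels=[region.name] * len(centers)
    )


def expand_with_margin(region: Region, margin: float) -> Region:
    """Region with every cuboid grown by ``margin`` mm on all six faces."""
    if margin < 0:
        raise ValidationError(f"margin must be >= 0, got {margin}")
    grown = [np.array([box[0] - margin, box[1] + margin]) for box in region.cuboids]
    return Region(name=region.name, cuboids=grown)


# ---------------------------------------------------------------------------
# Kernels and fitting
# ---------------------------------------------------------------------------


def build_kernels(basis: BasisConfig, grid: ElectrodeGrid, medium: Medium) -> KernelSet:
    """Construct K = B B^T from the forward matrix of unit basis sources."""
    B = basis_matrix(basis, grid, medium)
    K = B @ B.T
    K = 0.5 * (K + K.T)  # kill roundoff asymmetry
    return KernelSet(K=K, B=B, basis=basis, grid=grid, medium=medium)


def _factor(kernels: KernelSet, lam: float):
    K = kernels.K
    try:
        return cho_factor(K + lam * np.eye(K.shape[0]), lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"K + lambda*I is numerically singular for lambda={lam}; "
            "use lambda > 0 to regularize a rank-deficient kernel"
        ) from exc


def fit(ep: EvokedPotential, kernels: KernelSet, lam: float) -> KcsdFit:
    """Solve (K + lambda I) beta = V for every time column of ``ep``."""
    if ep.grid is not kernels.grid and ep.grid.n_active != kernels.grid.n_active:
        raise ValidationError("EP grid does not match the kernel grid")
    if lam < 0:
        raise ValidationError(f"lambda must be >= 0, got {lam}")
    cho = _factor(kernels, lam)
    beta = cho_solve(cho, ep.values)
    return KcsdFit(kernels=kernels, lam=float(lam), beta=beta, times=ep.times)


def estimate_csd(fit_: KcsdFit, points: np.ndarray) -> np.ndarray:
    """Evaluate the estimated CSD (uA/mm^3) at ``points``: (P, T) array.

    Implements C(x) = K~(x, .) beta with the cross-kernel built from the
    CSD-space profiles b~_i(x).  Warns when points fall outside the span of
    the basis (bounding box of the centers inflated by one width).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    basis = fit_.kernels.basis
    lo = basis.centers.min(axis=0) - basis.width
    hi = basis.centers.max(axis=0) + basis.width
    if np.any((pts < lo) | (pts > hi)):
        warnings.warn(
            "some evaluation points lie outside the basis-covered region; "
            "CSD estimates there are extrapolations",
            stacklevel=2,
        )
    Ctil = csd_basis_matrix(pts, basis.centers, basis.width)  # (P, M)
    Ktil = Ctil @ fit_.kernels.B.T  # (P, N)
    return Ktil @ fit_.beta


def interp_potential(fit_: KcsdFit, points: np.ndarray) -> np.ndarray:
    """Kernel-interpolated potential V*(x) = sum_j beta_j K(x, x_j), (P, T) mV."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    kernels = fit_.kernels
    Bp = potential_basis_matrix(
        pts, kernels.basis.centers, kernels.basis.width, kernels.medium
    )
    return (Bp @ kernels.B.T) @ fit_.beta


def default_lambda_candidates(kernels: KernelSet, n: int = 16) -> np.ndarray:
    """Log-spaced lambda grid over [1e-6, 1e+1] x trace(K)/N (scale-free)."""
    scale = np.trace(kernels.K) / kernels.K.shape[0]
    return scale * np.logspace(-6, 1, n)


def _lcurve_choice(rho: np.ndarray, eta: np.ndarray, lams: np.ndarray) -> float:
    """Maximum-curvature corner of the (log rho, log eta) curve.

    Curvature is computed by finite differences with log(lambda) as the
    curve parameter; ties break toward larger lambda.
    """
    x = np.log(rho)
    y = np.log(eta)
    t = np.log(lams)
    dx = np.gradient(x, t)
    dy = np.gradient(y, t)
    ddx = np.gradient(dx, t)
    ddy = np.gradient(dy, t)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dx * ddy - dy * ddx) / denom
    kappa[~np.isfinite(kappa)] = -np.inf
    best = np.max(kappa)
    # tie-break toward larger lambda: last index attaining the maximum
    idx = np.flatnonzero(kappa >= best - 1e-12 * max(abs(best), 1.0))[-1]
    return float(lams[idx])


def select_lambda(
    ep: EvokedPotential,
    kernels: KernelSet,
    method: str = "lcurve",
    candidates=None,
) -> float:
    """Choose the regularization parameter from a candidate grid.

    ``lcurve`` picks the corner (maximum curvature) of the residual-norm /
    solution-norm curve; ``cv`` minimizes leave-one-electrode-out prediction
    error averaged over time samples.  The returned value is always a member
    of ``candidates``.
    """
    if candidates is None:
        candidates = default_lambda_candidates(kernels)
    lams = np.asarray(candidates, dtype=float)
    if lams.size == 1:
        return float(lams[0])
    if np.any(lams <= 0) or np.any(np.diff(lams) <= 0):
        raise ValidationError("lambda candidates must be positive and sorted")
    K, V = kernels.K, ep.values

    if method == "lcurve":
        rho = np.empty(lams.size)
        eta = np.empty(lams.size)
        for i, lam in enumerate(lams):
            beta = cho_solve(_factor(kernels, lam), V)
            rho[i] = np.linalg.norm(K @ beta - V)
            eta[i] = np.linalg.norm(beta)
        floor = 1e-300
        if np.ptp(rho) <= 1e-12 * max(rho.max(), floor):
            log.warning(
                "degenerate L-curve (flat residuals); returning smallest candidate"
            )
            return float(lams[0])
        return _lcurve_choice(np.maximum(rho, floor), np.maximum(eta, floor), lams)

    if method == "cv":
        n = K.shape[0]
        errs = np.empty(lams.size)
        for i, lam in enumerate(lams):
            sse = 0.0
            for j in range(n):
                keep = np.arange(n) != j
                sub = K[np.ix_(keep, keep)] + lam * np.eye(n - 1)
                beta_j = np.linalg.solve(sub, V[keep])
                pred = K[j, keep] @ beta_j
                sse += np.sum((pred - V[j]) ** 2)
            errs[i] = sse / (n * V.shape[1])
        best = errs.min()
        idx = np.flatnonzero(errs <= best * (1 + 1e-12))[-1]
        return float(lams[idx])

    raise ValidationError(f"unknown lambda selection method {method!r}")


# ---------------------------------------------------------------------------
# Fit persistence
# ---------------------------------------------------------------------------


def write_fit(fit_: KcsdFit, path, provenance: dict | None = None) -> None:
    """Store beta, lambda, basis and grid so a fit can be re-evaluated later."""
    with h5py.File(path, "w") as f:
        f.create_dataset("beta", data=fit_.beta)
        f.create_dataset("times", data=fit_.times)
        f.attrs["lambda"] = fit_.lam
        f.attrs["conductivity"] = fit_.kernels.medium.conductivity
        b = f.create_group("basis")
        b.create_dataset("centers", data=fit_.kernels.basis.centers)
        b.attrs["width"] = fit_.kernels.basis.width
        b.create_dataset(
            "region_labels",
            data=np.array(fit_.kernels.basis.region_labels, dtype="S"),
        )
        g = f.create_group("grid")
        g.create_dataset(
            "channel_ids",
            data=np.array([str(c) for c in fit_.kernels.grid.channel_ids], dtype="S"),
        )
        g.create_dataset("positions", data=fit_.kernels.grid.positions)
        g.create_dataset("broken", data=fit_.kernels.grid.broken.astype(np.uint8))
        for key, val in (provenance or {}).items():
            f.attrs[f"provenance_{key}"] = val


def read_fit(path) -> KcsdFit:
    with h5py.File(path, "r") as f:
        beta = f["beta"][()]
        times = f["times"][()]
        lam = float(f.attrs["lambda"])
        medium = Medium(conductivity=float(f.attrs["conductivity"]))
        basis = BasisConfig(
            centers=f["basis/centers"][()],
            width=float(f["basis"].attrs["width"]),
            region_labels=[s.decode() for s in f["basis/region_labels"][()]],
        )
        grid = ElectrodeGrid(
            channel_ids=[c.decode() for c in f["grid/channel_ids"][()]],
            positions=f["grid/positions"][()],
            broken=f["grid/broken"][()].astype(bool),
        )
    kernels = build_kernels(basis, grid, medium)
    return KcsdFit(kernels=kernels, lam=lam, beta=beta, times=times)
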