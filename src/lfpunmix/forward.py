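"""Forward model: potentials of 3D Gaussian current sources in an infinite
homogeneous medium.

A basis source is an isotropic Gaussian current-source-density profile with
standard deviation ``R`` (mm) and unit total current (1 uA).  Its potential
has the closed form

    V(r) = 1 / (4 pi sigma) * erf(r / (sqrt(2) R)) / r      [mV]

with the finite limit ``V(0) = sqrt(2/pi) / (4 pi sigma R)``.  The closed
form is the production path; numerical quadrature of the defining integral
serves as an independent test oracle only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import erf

from .exceptions import ValidationError
from .geometry import ElectrodeGrid, Medium, UNIT_FACTOR

_SQRT2 = np.sqrt(2.0)
_GAUSS_NORM = (2.0 * np.pi) ** 1.5


@dataclass(frozen=True)
class GaussianSource:
    """Isotropic 3D Gaussian current source.

    Parameters
    ----------
    center
        Location of the profile centre, mm.
    width
        Standard deviation R of the Gaussian profile, mm.  Must be > 0.
    amplitude
        Total current (volume integral of the CSD profile), uA.  Negative
        amplitude denotes a current sink.
    """

    center: tuple
    width: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValidationError(f"source width must be > 0, got {self.width}")
        if not np.isfinite(self.amplitude):
            raise ValidationError("source amplitude must be finite")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


def unit_potential(r: np.ndarray, width: float, conductivity: float) -> np.ndarray:
    """Potential (mV) of a unit-current Gaussian source at radius ``r`` mm.

    Safe at r = 0 where the series limit sqrt(2/pi)/R is used.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    pref = UNIT_FACTOR / (4.0 * np.pi * conductivity)
    small = r < 1e-10 * width
    rr = np.where(small, 1.0, r)  # avoid 0/0; overwritten below
    out = erf(rr / (_SQRT2 * width)) / rr
    out[small] = np.sqrt(2.0 / np.pi) / width
    return pref * out


def unit_csd(r: np.ndarray, width: float) -> np.ndarray:
    """CSD profile (uA/mm^3) of a unit-current Gaussian source at radius r."""
    r = np.asarray(r, dtype=float)
    return np.exp(-0.5 * (r / width) ** 2) / (_GAUSS_NORM * width**3)


def gaussian_source_potential(src: GaussianSource, medium: Medium, x) -> np.ndarray:
    """Potential V(x) in mV generated by ``src`` at point(s) ``x``.

    ``x`` may be a single 3-vector or an (P, 3) array; the return value is a
    scalar or (P,) array accordingly.
    """
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    r = np.linalg.norm(pts - np.asarray(src.center), axis=1)
    v = src.amplitude * unit_potential(r, src.width, medium.conductivity)
    return v[0] if np.ndim(x) == 1 else v


def potential_basis_matrix(
    points: np.ndarray, centers: np.ndarray, width: float, medium: Medium
) -> np.ndarray:
    """Matrix of unit-source potentials b_i evaluated at ``points``.

    Entry (p, i) is the potential of unit-current basis source i at point p.
    """
    r = cdist(np.atleast_2d(points), np.atleast_2d(centers))
    return unit_potential(r, width, medium.conductivity)


def csd_basis_matrix(points: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    """Matrix of unit-source CSD profiles b~_i evaluated at ``points``."""
    r = cdist(np.atleast_2d(points), np.atleast_2d(centers))
    return unit_csd(r, width)


def basis_matrix(basis, grid: ElectrodeGrid, medium: Medium) -> np.ndarray:
    """Forward-model matrix b_i(x_j), active electrodes x basis sources.

    Basis sources are unit-amplitude by convention; amplitudes live in the
    coefficient vectors of a fit.  Broken channels are excluded.
    """
    if len(basis.centers) < 1:
        raise ValidationError("basis must contain at least one source")
    return potential_basis_matrix(
        grid.active_positions, basis.centers, basis.width, medium
    )
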