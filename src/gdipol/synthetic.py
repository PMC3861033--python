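"""Generators for every input the pipeline needs: initial perturbations,
parametric membrane caps, and microscopy-style line-scan profiles.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import Discretization, SystemState, uniform_state
from .params import ModelParameters
from .reactions import HomogeneousState

__all__ = [
    "PerturbationSpec", "lattice_noise_function",
    "random_lattice_perturbation", "broad_cap_perturbation",
    "synthetic_membrane_cap", "synthetic_linescan", "LineScanProfile",
]

_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class PerturbationSpec:
    """How to disturb the homogeneous state.

    ``random_lattice``: i.i.d. uniform[-1, 1] values on a cubic lattice
    (default spacing 1 um) interpolated trilinearly to the membrane,
    scaling every membrane species by (1 + amplitude * f).
    ``broad_cap``: a faint cap linear in one Cartesian coordinate,
    changing sign at the cell center.
    """

    kind: str = "random_lattice"          # "random_lattice" | "broad_cap"
    amplitude: float = 0.01
    lattice_spacing: float = 1.0
    seed: int = 0
    cap_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.kind not in ("random_lattice", "broad_cap"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude >= 1:
            raise ValueError("amplitude >= 1 would break positivity")
        if self.lattice_spacing <= 0:
            raise ValueError("lattice spacing must be > 0")


def lattice_noise_function(spec: PerturbationSpec, R: float):
    """Trilinear interpolant of cube-lattice noise; |f| <= 1 everywhere."""
    rng = np.random.default_rng(spec.seed)
    a = spec.lattice_spacing
    n = int(np.ceil(R / a)) + 2
    vals = rng.uniform(-1.0, 1.0, size=(2 * n + 1,) * 3)

    def f(xyz: np.ndarray) -> np.ndarray:
        g = xyz / a + n                      # lattice coordinates
        i0 = np.floor(g).astype(int)
        frac = g - i0
        out = np.zeros(xyz.shape[:-1])
        for dx in (0, 1):
            wx = frac[..., 0] if dx else 1.0 - frac[..., 0]
            for dy in (0, 1):
                wy = frac[..., 1] if dy else 1.0 - frac[..., 1]
                for dz in (0, 1):
                    wz = frac[..., 2] if dz else 1.0 - frac[..., 2]
                    out += wx * wy * wz * vals[
                        i0[..., 0] + dx, i0[..., 1] + dy, i0[..., 2] + dz
                    ]
        return out

    return f


def random_lattice_perturbation(
    spec: PerturbationSpec,
    p: ModelParameters,
    base: HomogeneousState,
    disc: Discretization,
) -> SystemState:
    """Membrane species scaled by (1 + amplitude * f(x)); cytosol untouched."""
    state = uniform_state(disc, base)
    f = lattice_noise_function(spec, p.R)
    fac = 1.0 + spec.amplitude * f(p.R * disc.grid.points())
    state.m = state.m * fac[None, :, :]
    return state


def broad_cap_perturbation(
    spec: PerturbationSpec,
    p: ModelParameters,
    base: HomogeneousState,
    disc: Discretization,
) -> SystemState:
    """Membrane species scaled by (1 + amplitude * cos(angle to cap))."""
    d = np.asarray(spec.cap_direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("cap_direction must be a nonzero vector")
    d = d / nrm
    state = uniform_state(disc, base)
    cosang = disc.grid.points() @ d          # (x . d)/R on the surface
    state.m = state.m * (1.0 + spec.amplitude * cosang)[None, :, :]
    return state


def synthetic_membrane_cap(
    background: float,
    height: float,
    angular_sigma: float,
    center: tuple[float, float, float],
    grid,
) -> np.ndarray:
    """Axisymmetric Gaussian cap in polar angle on a SphereGrid.

    ``field = background + height * exp(-theta^2 / (2 sigma^2))`` with
    theta the angle to ``center``; the closed-form FWHM along a great
    circle is ``R * 2 sqrt(2 ln 2) * angular_sigma``.
    """
    if not (0.0 < angular_sigma < math.pi / 2):
        raise ValueError("angular_sigma must be in (0, pi/2)")
    d = np.asarray(center, dtype=float)
    d = d / np.linalg.norm(d)
    cosang = np.clip(grid.points() @ d, -1.0, 1.0)
    theta = np.arccos(cosang)
    return background + height * np.exp(-(theta**2) / (2.0 * angular_sigma**2))


@dataclass(frozen=True)
class LineScanProfile:
    """Arclength/intensity samples along a membrane contour."""

    arclength: np.ndarray    # um, strictly increasing
    intensity: np.ndarray    # arbitrary units

    def __post_init__(self):
        s = np.asarray(self.arclength, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if s.ndim != 1 or s.shape != i.shape:
            raise ValueError("arclength and intensity must be matching 1-D arrays")
        if np.any(np.diff(s) <= 0):
            raise ValueError("arclength must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "arclength", s)
        object.__setattr__(self, "intensity", i)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.arclength, self.intensity]),
                   delimiter=",", header="arclength_um,intensity", comments="")

    @classmethod
    def from_csv(cls, path) -> "LineScanProfile":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arclength=data[:, 0], intensity=data[:, 1])


def synthetic_linescan(
    true_fwhm: float,
    background: float = 100.0,
    amplitude: float = 200.0,
    noise_sd: float = 0.0,
    n_points: int = 128,
    seed: int = 0,
    R: float = 3.95,
    center: float | None = None,
) -> LineScanProfile:
    """Noisy Gaussian cap on an equatorial membrane contour of length 2 pi R.

    Emulates a manually drawn membrane line scan through a polarity cap:
    a Gaussian of full width ``true_fwhm`` on a constant background with
    additive i.i.d. Gaussian noise of standard deviation ``noise_sd``.
    """
    if n_points < 16:
        raise ValueError("need at least 16 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    length = 2.0 * math.pi * R
    s = np.linspace(0.0, length, n_points)
    s0 = 0.5 * length if center is None else center
    sigma = true_fwhm / _FWHM_FACTOR
    signal = background + amplitude * np.exp(-((s - s0) ** 2) / (2.0 * sigma**2))
    return LineScanProfile(arclength=s, intensity=signal + rng.normal(0.0, noise_sd, n_points)
                           if noise_sd > 0 else signal)
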