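"""Reaction terms, boundary fluxes and the homogeneous steady state.

Membrane species (index order used throughout the package):

    0: mT  -- Cdc42-GTP            (um^-2)
    1: mD  -- Cdc42-GDP            (um^-2)
    2: mB  -- free membrane Bem1   (um^-2)
    3: mBG -- Bem1-Cdc24 complex   (um^-2)

Cytosolic species:

    0: cD  -- Cdc42-GDP (in complex with the GDI)  (um^-3)
    1: cB  -- Bem1                                 (um^-3)
    2: cG  -- Cdc24                                (um^-3)

The cytosol carries no bulk reactions (pure diffusion); all chemistry
happens on the membrane and in the attachment/detachment fluxes through
it.  For each protein pool the membrane source terms and the boundary
uptake flux balance pointwise, so total copy numbers are conserved by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import ModelParameters

__all__ = [
    "MT", "MD", "MB", "MBG", "CD", "CB", "CG",
    "reaction_terms", "boundary_fluxes", "wellmixed_rhs",
    "HomogeneousState", "homogeneous_steady_state", "membrane_fractions_uniform",
]

MT, MD, MB, MBG = 0, 1, 2, 3
CD, CB, CG = 0, 1, 2


def _check_nonneg(m: np.ndarray, c: np.ndarray) -> None:
    if np.any(np.asarray(m) < 0) or np.any(np.asarray(c) < 0):
        raise ValueError("negative concentration passed to reaction terms")


def boundary_fluxes(m, c_at_R, p: ModelParameters, check: bool = True):
    """Net attachment flux (molecules um^-2 s^-1) of each protein pool.

    ``m`` has leading axis 4 (membrane species), ``c_at_R`` leading axis 3
    (cytosolic species evaluated at the membrane).  Positive flux moves
    protein from cytosol to membrane.  Returns an array with leading
    axis 3 ordered (Cdc42, Bem1, Cdc24).
    """
    m = np.asarray(m, dtype=float)
    c = np.asarray(c_at_R, dtype=float)
    if check:
        _check_nonneg(m, c)
    jD = (p.beta2 + p.beta1 * m[MBG]) * c[CD] - p.beta3 * m[MD]
    jB = p.gamma1 * m[MT] * c[CB] - p.gamma2 * m[MB]
    jG = p.delta1 * m[MB] * c[CG] - p.delta2 * m[MBG]
    return np.stack([jD, jB, jG])


def reaction_terms(m, c_at_R, p: ModelParameters, check: bool = True):
    """Membrane source terms (um^-2 s^-1) for the four membrane species.

    GEF-catalysed exchange acts with rate ``alpha2 + alpha1*mBG`` on
    membrane Cdc42-GDP; GEF-mediated attachment (``beta1*mBG``) deposits
    cytosolic Cdc42-GDP directly in GTP form; the GDI extracts only the
    GDP form (``beta3`` on mD).
    """
    m = np.asarray(m, dtype=float)
    c = np.asarray(c_at_R, dtype=float)
    if check:
        _check_nonneg(m, c)
    exch = p.alpha2 + p.alpha1 * m[MBG]          # nucleotide-exchange rate on mD
    f_mT = p.beta1 * m[MBG] * c[CD] + exch * m[MD] - p.alpha3 * m[MT]
    f_mD = p.beta2 * c[CD] + p.alpha3 * m[MT] - exch * m[MD] - p.beta3 * m[MD]
    f_mB = (p.gamma1 * m[MT] * c[CB] - p.gamma2 * m[MB]
            - p.delta1 * m[MB] * c[CG] + p.delta2 * m[MBG])
    f_mBG = p.delta1 * m[MB] * c[CG] - p.delta2 * m[MBG]
    return np.stack([f_mT, f_mD, f_mB, f_mBG])


def wellmixed_rhs(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Two-compartment (well-mixed) ODE right-hand side.

    ``y = (mT, mD, mB, mBG, cD, cB, cG)``.  The cytosol loses what the
    membrane gains, weighted by the area/volume ratio.
    """
    m, c = y[:4], y[4:]
    f = reaction_terms(m, c, p, check=False)
    j = boundary_fluxes(m, c, p, check=False)
    return np.concatenate([f, -(p.area / p.volume) * j])


@dataclass(frozen=True)
class HomogeneousState:
    """Spatially uniform steady state (the unpolarized branch)."""

    m: np.ndarray          # (mT, mD, mB, mBG), um^-2
    c: np.ndarray          # (cD, cB, cG), um^-3
    residual: float        # max |rhs| relative to species scale

    @property
    def mT(self) -> float: return float(self.m[MT])
    @property
    def mD(self) -> float: return float(self.m[MD])
    @property
    def mB(self) -> float: return float(self.m[MB])
    @property
    def mBG(self) -> float: return float(self.m[MBG])
    @property
    def cD(self) -> float: return float(self.c[CD])
    @property
    def cB(self) -> float: return float(self.c[CB])
    @property
    def cG(self) -> float: return float(self.c[CG])

    def membrane_fractions(self, p: ModelParameters) -> tuple[float, float, float]:
        return membrane_fractions_uniform(self.m, p)

    def cdc42gtp_fraction(self, p: ModelParameters) -> float:
        """Membrane Cdc42-GTP as a fraction of total cellular Cdc42."""
        return float(self.m[MT] * p.area / p.N42)


def membrane_fractions_uniform(m, p: ModelParameters) -> tuple[float, float, float]:
    """(Cdc42, Bem1, Cdc24) membrane fractions of a uniform state."""
    A = p.area
    return (
        float((m[MT] + m[MD]) * A / p.N42),
        float((m[MB] + m[MBG]) * A / p.NB),
        float(m[MBG] * A / p.N24),
    )


def homogeneous_steady_state(
    p: ModelParameters,
    tol: float = 1e-10,
    t_relax: float = 2e5,
) -> HomogeneousState:
    """Unpolarized steady state satisfying the conservation constraints.

    The stable unpolarized branch is selected operationally: the
    well-mixed ODE system is relaxed from the all-cytosolic state, and
    the result is polished with a Newton root solve of the four membrane
    balances plus the three conservation constraints.
    """
    V, A = p.volume, p.area
    totals = np.array([p.N42, p.NB, p.N24])
    y0 = np.concatenate([np.zeros(4), totals / V])

    sol = solve_ivp(
        lambda t, y: wellmixed_rhs(y, p),
        (0.0, t_relax), y0, method="LSODA", rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"well-mixed relaxation failed: {sol.message}")
    y_relax = sol.y[:, -1]

    def residuals(y: np.ndarray) -> np.ndarray:
        m, c = y[:4], y[4:]
        f = reaction_terms(m, c, p, check=False)
        cons = np.array([
            (m[MT] + m[MD]) * A + c[CD] * V - p.N42,
            (m[MB] + m[MBG]) * A + c[CB] * V - p.NB,
            m[MBG] * A + c[CG] * V - p.N24,
        ])
        return np.concatenate([f, cons / V])

    res = root(residuals, y_relax, method="hybr", tol=1e-13)
    y = res.x if res.success else y_relax
    y = np.where(np.abs(y) < 1e-30, 0.0, y)

    scale = np.maximum(np.abs(y), totals.max() / V)
    rel = float(np.max(np.abs(residuals(y)) / scale.max()))
    if rel > tol:
        raise RuntimeError(
            f"homogeneous steady state did not converge: relative residual {rel:.3e} "
            f"(root solver: {res.message})"
        )
    if np.any(y < -1e-12):
        raise RuntimeError("homogeneous steady state has negative concentrations")
    return HomogeneousState(m=np.maximum(y[:4], 0.0), c=np.maximum(y[4:], 0.0), residual=rel)
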