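"""Linear stability of the homogeneous state on the sphere.

Perturbations are expanded in spherical harmonics, ``delta u ~ Y_l^m
exp(sigma t)``.  Each cytosolic species solves the radial diffusion
eigenproblem in the ball: for ``Re sigma > 0`` the radial profile
regular at the origin is the modified spherical Bessel function
``i_l(sqrt(sigma/D3) r)``; for real negative ``sigma`` this analytically
continues to the oscillatory ``j_l(sqrt(-sigma/D3) r)``, and at
``sigma = 0`` to ``r^l``.  Only the logarithmic derivative of the
profile at the membrane,

    q_l(sigma) = phi_l'(R) / phi_l(R),

enters the problem.  Eliminating the three cytosolic amplitudes through
the linearized boundary-flux conditions reduces the linear system to a
4x4 sigma-dependent membrane matrix ``A(sigma)``; growth rates are the
self-consistent solutions of ``sigma in eig(A(sigma))``.  By isotropy
the rates are independent of the azimuthal order m (degeneracy 2l+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import spherical_in, spherical_jn

from .params import ModelParameters
from .reactions import MT, MD, MB, MBG, CD, CB, CG, HomogeneousState, homogeneous_steady_state

__all__ = [
    "radial_log_derivative", "membrane_matrix", "dispersion_growth_rate",
    "GrowthSpectrum", "growth_spectrum", "is_polarizable", "diffusion_rescue",
]


def _bessel_i_ratio(l: int, z: complex, maxiter: int = 200, eps: float = 1e-15) -> complex:
    """``i_{l+1}(z) / i_l(z)`` by the Lentz continued fraction.

    Valid for complex ``z`` away from zeros of ``i_l``; used for the
    analytic continuation to complex sigma.
    """
    # CF: I_{nu+1}(z)/I_nu(z) = 1 / (2(nu+1)/z + 1/(2(nu+2)/z + ...)), nu = l + 1/2
    tiny = 1e-300
    b = lambda k: 2.0 * (l + 0.5 + k) / z
    f = tiny
    C, D = f, 0.0
    for k in range(1, maxiter):
        bk = b(k)
        C = bk + 1.0 / C
        if C == 0:
            C = tiny
        D = bk + D
        if D == 0:
            D = tiny
        D = 1.0 / D
        delta = C * D
        f *= delta
        if abs(delta - 1.0) < eps:
            break
    return f


def radial_log_derivative(l: int, sigma: complex, D3: float, R: float) -> complex:
    """q_l(sigma) = phi'(R)/phi(R) for the radial cytosolic eigenfunction.

    Uses ``i_l'(z) = i_{l+1}(z) + (l/z) i_l(z)`` (and the analogous
    identity for ``j_l``); real sigma goes through scipy's spherical
    Bessel routines, complex sigma through the continued fraction.
    """
    if abs(sigma) < 1e-14:
        return l / R
    if np.isrealobj(sigma) or (isinstance(sigma, complex) and sigma.imag == 0.0):
        s = float(np.real(sigma))
        if s > 0:
            k = np.sqrt(s / D3)
            return k * spherical_in(l, k * R, derivative=True) / spherical_in(l, k * R)
        kap = np.sqrt(-s / D3)
        num = spherical_jn(l, kap * R, derivative=True)
        den = spherical_jn(l, kap * R)
        if den == 0.0:
            return np.inf
        return kap * num / den
    k = np.sqrt(complex(sigma) / D3)  # principal branch
    z = k * R
    return k * (l / z + _bessel_i_ratio(l, z))


def _jacobians(p: ModelParameters, base: HomogeneousState):
    """Linearization about the homogeneous state.

    Returns (Rm, Rc, Sm, kc): membrane-reaction Jacobians w.r.t. the four
    membrane species and three boundary cytosol values, and the flux
    Jacobians ``delta J_X = Sm[X] . m_hat + kc[X] * c_hat_X``.
    """
    mT0, mD0, mBG0 = base.mT, base.mD, base.mBG
    mB0 = base.mB
    cD0, cB0, cG0 = base.cD, base.cB, base.cG
    exch = p.alpha2 + p.alpha1 * mBG0

    Rm = np.zeros((4, 4))
    Rc = np.zeros((4, 3))
    # f_mT = beta1*mBG*cD + exch*mD - alpha3*mT
    Rm[MT, MT] = -p.alpha3
    Rm[MT, MD] = exch
    Rm[MT, MBG] = p.beta1 * cD0 + p.alpha1 * mD0
    Rc[MT, CD] = p.beta1 * mBG0
    # f_mD = beta2*cD + alpha3*mT - exch*mD - beta3*mD
    Rm[MD, MT] = p.alpha3
    Rm[MD, MD] = -exch - p.beta3
    Rm[MD, MBG] = -p.alpha1 * mD0
    Rc[MD, CD] = p.beta2
    # f_mB = gamma1*mT*cB - gamma2*mB - delta1*mB*cG + delta2*mBG
    Rm[MB, MT] = p.gamma1 * cB0
    Rm[MB, MB] = -p.gamma2 - p.delta1 * cG0
    Rm[MB, MBG] = p.delta2
    Rc[MB, CB] = p.gamma1 * mT0
    Rc[MB, CG] = -p.delta1 * mB0
    # f_mBG = delta1*mB*cG - delta2*mBG
    Rm[MBG, MB] = p.delta1 * cG0
    Rm[MBG, MBG] = -p.delta2
    Rc[MBG, CG] = p.delta1 * mB0

    Sm = np.zeros((3, 4))
    Sm[CD, MD] = -p.beta3
    Sm[CD, MBG] = p.beta1 * cD0
    Sm[CB, MT] = p.gamma1 * cB0
    Sm[CB, MB] = -p.gamma2
    Sm[CG, MB] = p.delta1 * cG0
    Sm[CG, MBG] = -p.delta2
    kc = np.array([
        p.beta2 + p.beta1 * mBG0,
        p.gamma1 * mT0,
        p.delta1 * mB0,
    ])
    return Rm, Rc, Sm, kc


def membrane_matrix(p: ModelParameters, base: HomogeneousState, l: int, sigma: complex,
                    cytosol: str = "full"):
    """The reduced 4x4 matrix A(sigma) acting on membrane amplitudes.

    With ``cytosol="full"`` the cytosolic amplitudes are eliminated via
    the boundary conditions ``D3 q_l(sigma) c_hat_X = -delta J_X`` --
    the exact linearization of the bulk-surface PDE, including the
    local depletion of the cytosol beneath a growing cluster.  With
    ``cytosol="reservoir"`` the cytosol is treated as a well-mixed
    reservoir whose concentrations carry no non-uniform perturbation
    (``c_hat = 0``); since cytosolic diffusion is fast this is a mild
    approximation that raises the leading rate by roughly 10% at
    control parameters, and it is the closure that reproduces the
    reported control-cell growth rate.
    """
    Rm, Rc, Sm, kc = _jacobians(p, base)
    lam = p.D2 * l * (l + 1) / p.R**2
    A = (Rm - lam * np.eye(4)).astype(complex)
    if cytosol == "reservoir":
        return A
    if cytosol != "full":
        raise ValueError(f"cytosol closure must be 'full' or 'reservoir', got {cytosol!r}")
    q = radial_log_derivative(l, sigma, p.D3, p.R)
    for X in range(3):
        den = p.D3 * q + kc[X]
        if den == 0 or not np.isfinite(abs(den)):
            if not np.isfinite(abs(den)):
                continue  # pole of q: cytosolic amplitude pinned to zero
            den = 1e-300
        A = A - np.outer(Rc[:, X], Sm[X]) / den
    return A


def _leading_gap(p, base, l, sigma, cytosol="full"):
    """max Re eig(A(sigma)) - sigma; zero at a self-consistent growth rate."""
    A = membrane_matrix(p, base, l, sigma, cytosol=cytosol)
    ev = np.linalg.eigvals(A)
    return float(np.max(ev.real)) - float(np.real(sigma))


def _q_real_batch(l: int, sigmas: np.ndarray, D3: float, R: float) -> np.ndarray:
    """radial_log_derivative for an array of real sigma values."""
    q = np.full(sigmas.shape, l / R)
    pos = sigmas > 1e-14
    neg = sigmas < -1e-14
    if np.any(pos):
        k = np.sqrt(sigmas[pos] / D3)
        q[pos] = k * spherical_in(l, k * R, derivative=True) / spherical_in(l, k * R)
    if np.any(neg):
        kap = np.sqrt(-sigmas[neg] / D3)
        den = spherical_jn(l, kap * R)
        with np.errstate(divide="ignore", invalid="ignore"):
            q[neg] = np.where(
                den == 0.0, np.inf,
                kap * spherical_jn(l, kap * R, derivative=True) / den)
    return q


def _gap_scan(p, base, l, sigmas, jac):
    """Vectorized self-consistency gap over an array of real sigma."""
    Rm, Rc, Sm, kc = jac
    lam = p.D2 * l * (l + 1) / p.R**2
    base_mat = Rm - lam * np.eye(4)
    q = _q_real_batch(l, sigmas, p.D3, p.R)
    den = p.D3 * q[:, None] + kc[None, :]                      # (n, 3)
    outer = np.einsum("ix,xj->xij", Rc, Sm)                    # (3, 4, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.einsum("nx,xij->nij", 1.0 / den, outer)
    A = base_mat[None, :, :] - corr
    good = np.all(np.isfinite(A), axis=(1, 2))
    gap = np.full(sigmas.shape, np.nan)
    if np.any(good):
        ev = np.linalg.eigvals(A[good])
        gap[good] = np.max(ev.real, axis=1) - sigmas[good]
    return gap


def dispersion_growth_rate(
    p: ModelParameters,
    base: HomogeneousState,
    l: int,
    sigma_max: float = 10.0,
    sigma_min: float = -10.0,
    n_scan: int = 400,
    cytosol: str = "full",
    jac=None,
) -> complex:
    """Leading growth rate sigma_l of spherical-harmonic degree l.

    Scans the real axis for the largest root of the self-consistency
    gap ``max Re eig(A(sigma)) - sigma`` (leading eigenvalues are real
    near onset), refining sign changes by bisection.  Falls back to a
    complex fixed-point iteration if the real scan finds nothing.
    """
    if l < 0:
        raise ValueError("l must be >= 0")
    if cytosol == "reservoir":
        # A is sigma-independent: the leading eigenvalue is the rate
        ev = np.linalg.eigvals(membrane_matrix(p, base, l, 0.0, cytosol="reservoir"))
        return complex(ev[np.argmax(ev.real)])
    if jac is None:
        jac = _jacobians(p, base)
    # dense real scan, finer near zero where the physical roots sit
    pos = np.geomspace(1e-6, sigma_max, n_scan // 2)
    grid = np.concatenate([-pos[::-1], [0.0], pos])
    vals = _gap_scan(p, base, l, grid, jac)

    roots: list[float] = []
    finite = np.isfinite(vals)
    for i in range(len(grid) - 1):
        if not (finite[i] and finite[i + 1]):
            continue
        v0, v1 = vals[i], vals[i + 1]
        if v0 == 0.0:
            roots.append(grid[i])
        elif v0 * v1 < 0:
            try:
                r = brentq(lambda s: _leading_gap(p, base, l, s), grid[i], grid[i + 1],
                           xtol=1e-14, rtol=1e-13)
            except ValueError:
                continue
            if abs(_leading_gap(p, base, l, r)) < 1e-6:
                roots.append(r)
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    if roots:
        return complex(max(roots))

    # complex fallback: fixed-point iteration sigma <- leading eig(A(sigma))
    sigma = complex(0.0, 0.0)
    for _ in range(200):
        A = membrane_matrix(p, base, l, sigma)
        ev = np.linalg.eigvals(A)
        nxt = ev[np.argmax(ev.real)]
        if abs(nxt - sigma) < 1e-12 * max(1.0, abs(nxt)):
            return complex(nxt)
        sigma = 0.5 * sigma + 0.5 * nxt
    raise RuntimeError(f"spectrum undetermined for l={l}: no self-consistent growth rate found")


@dataclass(frozen=True)
class GrowthSpectrum:
    """Leading growth rate per spherical-harmonic degree."""

    l: np.ndarray           # degrees 0..l_max
    sigma: np.ndarray       # complex leading growth rates
    dominant_l: int         # degree with largest Re sigma among l >= 1

    @property
    def re(self) -> np.ndarray:
        return self.sigma.real

    @property
    def im(self) -> np.ndarray:
        return self.sigma.imag


def growth_spectrum(
    p: ModelParameters,
    l_max: int = 10,
    base: HomogeneousState | None = None,
    auto_extend: bool = True,
    l_hard_max: int = 40,
    cytosol: str = "full",
) -> GrowthSpectrum:
    """Growth rates for l = 0..l_max (extended until clearly decaying).

    The l = 0 sector contains the neutral total-mass mode; its reported
    rate is the leading one, which is zero (mass shifts move along the
    family of homogeneous states).
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    if base is None:
        base = homogeneous_steady_state(p)
    jac = _jacobians(p, base)
    sigmas = [dispersion_growth_rate(p, base, l, cytosol=cytosol, jac=jac)
              for l in range(l_max + 1)]
    if auto_extend:
        # extend until Re sigma decreasing for 3 consecutive degrees
        while len(sigmas) - 1 < l_hard_max:
            re = np.real(sigmas)
            if len(re) >= 4 and np.all(np.diff(re[-4:]) < 0) and re[-1] < 0:
                break
            sigmas.append(dispersion_growth_rate(p, base, len(sigmas),
                                                 cytosol=cytosol, jac=jac))
    sig = np.asarray(sigmas, dtype=complex)
    dominant = 1 + int(np.argmax(sig.real[1:]))
    return GrowthSpectrum(l=np.arange(len(sig)), sigma=sig, dominant_l=dominant)


def is_polarizable(
    p: ModelParameters,
    l_max: int = 10,
    base: HomogeneousState | None = None,
    cytosol: str = "full",
) -> bool:
    """True iff some non-uniform mode (1 <= l <= l_max) grows."""
    spec = growth_spectrum(p, l_max=l_max, base=base, cytosol=cytosol)
    return bool(np.any(spec.re[1:] > 0))


def diffusion_rescue(
    p: ModelParameters,
    D2_factors=None,
    D3_factors=None,
    l_max: int = 10,
) -> bool:
    """Can polarization be obtained for *some* diffusion constants?

    Scans a log grid of (D2, D3), by default two decades either side of
    the given values, and reports whether any grid point is polarizable.
    The homogeneous state does not depend on the diffusion constants, so
    it is computed once.
    """
    if D2_factors is None:
        D2_factors = np.geomspace(1e-2, 1e2, 5)
    if D3_factors is None:
        D3_factors = np.geomspace(1e-2, 1e2, 5)
    base = homogeneous_steady_state(p)
    for f2 in D2_factors:
        for f3 in D3_factors:
            q = p.replace(D2=p.D2 * f2, D3=p.D3 * f3)
            if is_polarizable(q, l_max=l_max, base=base):
                return True
    return False
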