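"""Real spherical-harmonic transforms on a Gauss-Legendre x uniform grid.

A pseudospectral workhorse for the membrane fields: analysis and
synthesis between values on an (nlat x nlon) grid and orthonormal
spherical-harmonic coefficients a[l, m] (Condon-Shortley phase,
``f = sum_lm a_lm Y_lm`` with ``a_{l,-m} = (-1)^m conj(a_lm)`` for real
fields).  The latitude nodes are Gauss-Legendre in x = cos(theta), so
analysis of fields band-limited to the dealiased product degree is
exact; the default grid (nlat ~ 3(L+1)/2, nlon ~ 3(L+1)) implements
3/2-rule padding for the quadratic reaction nonlinearities.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SphereGrid"]


def _legendre_tables(L: int, x: np.ndarray) -> list[np.ndarray]:
    """Normalized associated Legendre functions P~_l^m at nodes x.

    Returns a list over m of arrays (len(x), L - m + 1) holding
    P~_l^m(x) for l = m..L, normalized so that Y_lm = P~_l^m e^{im phi}
    is orthonormal on the sphere.
    """
    x = np.asarray(x, dtype=float)
    s = np.sqrt(1.0 - x * x)
    tables: list[np.ndarray] = []
    pmm = np.full_like(x, 1.0 / np.sqrt(4.0 * np.pi))
    for m in range(L + 1):
        cols = np.empty((x.size, L - m + 1))
        cols[:, 0] = pmm
        if L - m >= 1:
            cols[:, 1] = np.sqrt(2.0 * m + 3.0) * x * pmm
        for l in range(m + 2, L + 1):
            a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
            b = np.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
            cols[:, l - m] = a * (x * cols[:, l - m - 1] - b * cols[:, l - m - 2])
        tables.append(cols)
        if m < L:  # seed next diagonal, with Condon-Shortley phase
            pmm = -np.sqrt((2.0 * m + 3.0) / (2.0 * m + 2.0)) * s * pmm
    return tables


class SphereGrid:
    """Quadrature grid and transform pair for truncation degree L."""

    def __init__(self, L: int = 32, R: float = 1.0, nlat: int | None = None,
                 nlon: int | None = None):
        if L < 1:
            raise ValueError("L must be >= 1")
        self.L = L
        self.R = float(R)
        self.nlat = nlat if nlat is not None else int(np.ceil(1.5 * (L + 1))) + 1
        self.nlon = nlon if nlon is not None else 2 * int(np.ceil(1.5 * (L + 1)))
        if self.nlat < L + 1 or self.nlon < 2 * L + 1:
            raise ValueError("grid too coarse for requested truncation")
        x, w = np.polynomial.legendre.leggauss(self.nlat)
        self.x = x                      # cos(theta), ascending
        self.w = w                      # Gauss-Legendre weights
        self.theta = np.arccos(x)       # colatitude per row
        self.phi = 2.0 * np.pi * np.arange(self.nlon) / self.nlon
        self._dphi = 2.0 * np.pi / self.nlon
        self._plm = _legendre_tables(L, x)
        # zero-padded (m, nlat, l) tensor so both transforms reduce to one
        # batched matmul over m
        pfull = np.zeros((L + 1, self.nlat, L + 1))
        for m in range(L + 1):
            pfull[m, :, m:] = self._plm[m]
        self._pfull = np.ascontiguousarray(pfull)
        self._pfull_t = np.ascontiguousarray(np.swapaxes(pfull, 1, 2))
        ls = np.arange(L + 1)
        self.l_values = ls
        self.laplacian_eigenvalues = -ls * (ls + 1.0) / self.R**2

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def area_weights(self) -> np.ndarray:
        """dA per grid point (um^2), shape (nlat, nlon); sums to 4 pi R^2."""
        return np.broadcast_to(
            (self.R**2 * self._dphi) * self.w[:, None], (self.nlat, self.nlon)
        )

    def points(self) -> np.ndarray:
        """Cartesian unit vectors of the grid points, shape (nlat, nlon, 3)."""
        st = np.sin(self.theta)[:, None]
        return np.stack(
            [st * np.cos(self.phi)[None, :],
             st * np.sin(self.phi)[None, :],
             np.broadcast_to(self.x[:, None], (self.nlat, self.nlon))],
            axis=-1,
        )

    def integrate(self, f: np.ndarray) -> np.ndarray:
        """Surface integral of grid field(s) over the sphere of radius R."""
        return (self.R**2 * self._dphi) * np.einsum("j,...jk->...", self.w, f)

    # -- transforms --------------------------------------------------------

    def analyze(self, f: np.ndarray) -> np.ndarray:
        """Grid field(s) (..., nlat, nlon) -> coefficients (..., L+1, L+1).

        ``a[..., l, m]`` holds the coefficient of Y_l^m for 0 <= m <= l;
        entries with m > l are zero.
        """
        f = np.asarray(f, dtype=float)
        batch = f.shape[:-2]
        G = np.fft.rfft(f, axis=-1)[..., : self.L + 1] * self._dphi
        G *= self.w[:, None]
        # (m, B2, nlat) @ (m, nlat, l) -> (m, B2, l), real and imag stacked
        X = np.moveaxis(G, -1, 0).reshape(self.L + 1, -1, self.nlat)
        Y = np.stack([X.real, X.imag], axis=1) @ self._pfull[:, None]   # (m, 2, B, l)
        Y = Y[:, 0] + 1j * Y[:, 1]
        out = np.moveaxis(Y, 0, -1)                            # (B, l, m)
        return np.ascontiguousarray(out.reshape(batch + (self.L + 1, self.L + 1)))

    def synthesize(self, a: np.ndarray) -> np.ndarray:
        """Coefficients (..., L+1, L+1) -> grid field(s) (..., nlat, nlon)."""
        a = np.asarray(a, dtype=complex)
        batch = a.shape[:-2]
        X = np.moveaxis(a, -1, 0).reshape(self.L + 1, -1, self.L + 1)  # (m, B, l)
        Y = np.stack([X.real, X.imag], axis=1) @ self._pfull_t[:, None]  # (m, 2, B, nlat)
        Hm = np.moveaxis(Y[:, 0] + 1j * Y[:, 1], 0, -1)                  # (B, nlat, m)
        H = np.zeros(batch + (self.nlat, self.nlon // 2 + 1), dtype=complex)
        H[..., : self.L + 1] = Hm.reshape(batch + (self.nlat, self.L + 1))
        return np.fft.irfft(H * self.nlon, n=self.nlon, axis=-1)

    def evaluate(self, a: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Evaluate a coefficient set at arbitrary (theta, phi) points."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        plm = _legendre_tables(self.L, np.cos(theta))
        vals = np.zeros(a.shape[:-2] + theta.shape, dtype=complex)
        for m in range(self.L + 1):
            term = np.einsum("...l,jl->...j", a[..., m:, m], plm[m]) * np.exp(1j * m * phi)
            vals += term if m == 0 else term + np.conj(term)
        return vals.real

    def filter_to(self, f: np.ndarray, L_cut: int) -> np.ndarray:
        """Spectrally truncate grid field(s) to degrees l <= L_cut."""
        a = self.analyze(f)
        a[..., min(L_cut + 1, self.L + 1):, :] = 0.0
        return self.synthesize(a)

    def mean(self, f: np.ndarray) -> np.ndarray:
        return self.integrate(f) / (4.0 * np.pi * self.R**2)
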