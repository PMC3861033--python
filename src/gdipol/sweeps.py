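"""Parameter-scan engines: phase diagrams and final-cluster-width curves.

``capability_sweep`` maps polarization capability (from the linear
stability analysis), the unpolarized membrane Cdc42-GTP fraction and a
diffusion-rescue flag over a 2-D parameter grid.  ``fwhm_sweep`` runs
the full nonlinear dynamics to steady state along a 1-D parameter axis
and records the final cluster width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import Discretization, run_to_steady_state
from .metrics import cluster_stats
from .params import ModelParameters
from .reactions import homogeneous_steady_state
from .stability import diffusion_rescue, growth_spectrum
from .synthetic import PerturbationSpec, random_lattice_perturbation

__all__ = ["SweepGrid", "capability_sweep", "cdc42gtp_vs_parameter", "fwhm_sweep"]


@dataclass
class SweepGrid:
    """Tidy table of per-cell sweep results plus axis definitions."""

    axes: dict[str, np.ndarray]
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def log_axis(p: ModelParameters, name: str, lo: float = 1e-2, hi: float = 1e1,
             n: int = 21) -> np.ndarray:
    """Log-spaced values of one parameter around its current value."""
    return getattr(p, name) * np.geomspace(lo, hi, n)


def capability_sweep(
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    p: ModelParameters,
    l_max: int = 10,
    rescue: bool = True,
    rescue_grid: int = 4,
    cytosol: str = "full",
) -> SweepGrid:
    """Polarization capability over a 2-D parameter plane.

    Per cell: the homogeneous state, whether any non-uniform mode grows
    (``polarizable``), the membrane Cdc42-GTP fraction of the
    unpolarized state, and (optionally) whether polarization can be
    rescued by moving the diffusion constants over +/- two decades.
    Per-cell failures are recorded in the ``error`` column, not raised.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    rows = []
    for v1 in vals1:
        for v2 in vals2:
            row = {name1: float(v1), name2: float(v2),
                   "polarizable": None, "cdc42gtp_fraction": np.nan,
                   "dominant_l": None, "rescued_by_diffusion": None, "error": ""}
            try:
                q = p.replace(**{name1: float(v1), name2: float(v2)})
                base = homogeneous_steady_state(q)
                spec = growth_spectrum(q, l_max=l_max, base=base, cytosol=cytosol)
                pol = bool(np.any(spec.re[1:] > 0))
                row["polarizable"] = pol
                row["cdc42gtp_fraction"] = base.cdc42gtp_fraction(q)
                row["dominant_l"] = spec.dominant_l
                if rescue:
                    row["rescued_by_diffusion"] = pol or diffusion_rescue(
                        q,
                        D2_factors=np.geomspace(1e-2, 1e2, rescue_grid),
                        D3_factors=np.geomspace(1e-2, 1e2, rescue_grid),
                        l_max=l_max,
                    )
            except Exception as exc:  # per-cell failures are findings, not fatal
                row["error"] = str(exc)
            rows.append(row)
    return SweepGrid(axes={name1: np.asarray(vals1), name2: np.asarray(vals2)},
                     table=pd.DataFrame(rows))


def cdc42gtp_vs_parameter(name: str, values, p: ModelParameters) -> pd.DataFrame:
    """Unpolarized-state membrane Cdc42-GTP fraction along one axis."""
    rows = []
    for v in values:
        q = p.replace(**{name: float(v)})
        row = {name: float(v), "cdc42gtp_fraction": np.nan, "error": ""}
        try:
            row["cdc42gtp_fraction"] = homogeneous_steady_state(q).cdc42gtp_fraction(q)
        except Exception as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def fwhm_sweep(
    name: str,
    values,
    p: ModelParameters,
    L: int = 16,
    nr: int = 16,
    dt: float = 0.5,
    seed: int = 1,
    tol: float = 1e-5,
    t_max: float = 2e4,
    continuation: bool = True,
) -> SweepGrid:
    """Final-state cluster FWHM along a 1-D parameter axis.

    Each cell runs the nonlinear dynamics to steady state from a 1%
    random-lattice perturbation (or, with ``continuation``, from the
    previous cell's polarized state, which shortens the transient) and
    measures the final cluster.  Unpolarized or non-converged cells are
    flagged.
    """
    rows = []
    prev_state = None
    for v in values:
        q = p.replace(**{name: float(v)})
        row = {name: float(v), "polarized": False, "converged": False,
               "fwhm_um": np.nan, "height": np.nan, "n_clusters": 0, "error": ""}
        try:
            disc = Discretization(q, L=L, nr=nr)
            base = homogeneous_steady_state(q)
            if continuation and prev_state is not None:
                init = prev_state.copy()
                init.disc = disc
            else:
                init = random_lattice_perturbation(
                    PerturbationSpec(seed=seed), q, base, disc)
            final, info = run_to_steady_state(q, init, tol=tol, t_max=t_max, dt=dt)
            row["converged"] = info["converged"]
            row["polarized"] = info["polarized"]
            if info["polarized"]:
                st = cluster_stats(final.cdc42_membrane_field(), disc.grid)
                row["fwhm_um"] = st.fwhm if st.fwhm is not None else np.nan
                row["height"] = st.height
                row["n_clusters"] = st.n_clusters
                prev_state = final if continuation else None
            else:
                prev_state = None
        except Exception as exc:
            row["error"] = str(exc)
            prev_state = None
        rows.append(row)
    return SweepGrid(axes={name: np.asarray(values)}, table=pd.DataFrame(rows))
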