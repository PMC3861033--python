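"""Model parameters for the GDI-mediated Cdc42 polarization model.

The model tracks three polarity proteins of budding yeast -- the GTPase
Cdc42, its scaffold Bem1 and its GEF Cdc24 -- exchanging between the
plasma membrane (a sphere of radius ``R``) and the cytosol (the enclosed
ball).  All internal units are micrometres, seconds and molecule counts;
membrane concentrations are molecules/um^2 and cytosolic concentrations
molecules/um^3.

Kinetic coefficients
--------------------
alpha1 : GEF-catalysed nucleotide exchange, rate ``alpha1 * mBG`` (um^2/s)
alpha2 : intrinsic nucleotide exchange of membrane Cdc42-GDP (1/s)
alpha3 : GAP-mediated GTP hydrolysis (1/s)
beta1  : GEF-mediated attachment of cytosolic Cdc42-GDP, deposited in
         GTP form, rate ``beta1 * mBG`` (um^3/s)
beta2  : background attachment of cytosolic Cdc42-GDP (um/s)
beta3  : GDI-mediated extraction of membrane Cdc42-GDP (1/s)
gamma1 : Cdc42-GTP-dependent Bem1 attachment (um^3/s)
gamma2 : Bem1 detachment (1/s)
delta1 : Cdc24 binding to membrane Bem1 (um^3/s)
delta2 : Cdc24 release from the membrane complex (1/s)
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["ModelParameters", "control_parameters", "PARAM_NAMES"]

PARAM_NAMES = (
    "D2", "D3", "R", "N42", "NB", "N24",
    "alpha1", "alpha2", "alpha3",
    "beta1", "beta2", "beta3",
    "gamma1", "gamma2", "delta1", "delta2",
)


@dataclass(frozen=True)
class ModelParameters:
    """The 16 constants defining one model cell.

    ``alpha2`` is stored in 1/s (the literature value of 0.12/min
    converts to 0.002/s).
    """

    D2: float      # membrane diffusion constant, um^2/s
    D3: float      # cytosolic diffusion constant, um^2/s
    R: float       # cell radius, um
    N42: float     # total Cdc42 copies
    NB: float      # total Bem1 copies
    N24: float     # total Cdc24 copies
    alpha1: float  # um^2/s
    alpha2: float  # 1/s
    alpha3: float  # 1/s
    beta1: float   # um^3/s
    beta2: float   # um/s
    beta3: float   # 1/s
    gamma1: float  # um^3/s
    gamma2: float  # 1/s
    delta1: float  # um^3/s
    delta2: float  # 1/s

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"parameter {name} must be positive and finite, got {v!r}")

    @property
    def area(self) -> float:
        """Membrane area 4*pi*R^2 (um^2)."""
        return 4.0 * math.pi * self.R**2

    @property
    def volume(self) -> float:
        """Cytosolic volume (4/3)*pi*R^3 (um^3)."""
        return (4.0 / 3.0) * math.pi * self.R**3

    def replace(self, **kwargs: float) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def scaled(self, name: str, factor: float) -> "ModelParameters":
        """Return a copy with one parameter multiplied by ``factor``."""
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
        return self.replace(**{name: getattr(self, name) * factor})

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def to_yaml(self, path: str | Path) -> None:
        header = (
            "# Model parameters. Units: um, s, molecules.\n"
            "# D2/D3 um^2/s; R um; N* copy numbers; alpha1 um^2/s; alpha2, alpha3,\n"
            "# beta3, gamma2, delta2 1/s; beta1, gamma1, delta1 um^3/s; beta2 um/s.\n"
        )
        Path(path).write_text(header + yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of parameter names to values")
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(data)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})


def control_parameters() -> ModelParameters:
    """The control-cell parameter set (alpha2 converted to 1/s)."""
    return ModelParameters(
        D2=0.03,
        D3=11.0,
        R=3.95,
        N42=3000.0,
        NB=6500.0,
        N24=1000.0,
        alpha1=0.2,
        alpha2=0.12 / 60.0,
        alpha3=1.0,
        beta1=0.266,
        beta2=0.28,
        beta3=1.0,
        gamma1=0.2667,
        gamma2=0.35,
        delta1=0.00297,
        delta2=0.35,
    )
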