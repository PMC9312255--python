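"""Physical properties of tissues, blood and catheter materials.

Houses the material library (electrical conductivity at 500 kHz, thermal
conductivity, density, specific heat, tissue water mass fraction) together
with the temperature-dependent constitutive laws used by the electro-thermal
solver:

* electrical conductivity rising linearly at 1.5 %/degC above the 37 degC
  reference and collapsing by two orders of magnitude across the 99-101 degC
  vaporization band;
* an enthalpy-based apparent volumetric heat capacity that represents the
  latent heat of water vaporization as a narrow 99-100 degC band;
* an optionally anisotropic thermal conductivity tensor for muscle fibers
  lying parallel to the tissue surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "TissueProperties",
    "BloodProperties",
    "PhaseChangeModel",
    "ArrheniusParams",
    "MaterialLibrary",
    "load_default_library",
    "electrical_conductivity",
    "apparent_heat_capacity",
    "volumetric_enthalpy",
    "thermal_conductivity_tensor",
]

T_REF = 37.0  # degC, reference for sigma and enthalpy
SIGMA_TEMP_COEFF = 0.015  # fractional rise of sigma per degC


@dataclass(frozen=True)
class TissueProperties:
    """Constant material properties of one solid material.

    ``water_mass_fraction`` is only meaningful for biological tissue; it is
    ``None`` for the metal electrode and the polymer catheter shaft.
    ``k_transverse``/``k_longitudinal`` are the optional anisotropic thermal
    conductivities (transverse = perpendicular to the tissue surface,
    longitudinal = along the muscle fibers, parallel to the surface).
    """

    name: str
    sigma_ref: float  # S/m at 37 degC, 500 kHz
    k: float  # W/(m K)
    rho: float  # kg/m^3
    c: float  # J/(kg K)
    water_mass_fraction: Optional[float] = None
    k_transverse: Optional[float] = None
    k_longitudinal: Optional[float] = None

    def __post_init__(self) -> None:
        for field in ("sigma_ref", "k", "rho", "c"):
            value = getattr(self, field)
            if not (value > 0.0 and math.isfinite(value)):
                raise ValueError(f"{self.name}: {field} must be strictly positive")
        if self.water_mass_fraction is not None and not (
            0.0 < self.water_mass_fraction < 1.0
        ):
            raise ValueError(f"{self.name}: water_mass_fraction must lie in (0, 1)")
        has_t = self.k_transverse is not None
        has_l = self.k_longitudinal is not None
        if has_t != has_l:
            raise ValueError(
                f"{self.name}: anisotropy requires both k_transverse and k_longitudinal"
            )
        if has_t and abs(0.5 * (self.k_transverse + self.k_longitudinal) - self.k) > 1e-12:
            raise ValueError(
                f"{self.name}: mean of directional conductivities must equal isotropic k"
            )

    @property
    def rho_c(self) -> float:
        """Volumetric heat capacity rho*c in J/(m^3 K)."""
        return self.rho * self.c


@dataclass(frozen=True)
class BloodProperties:
    """Blood is an electrical conductor only; its temperature is never solved,
    so it carries no thermal fields and its conductivity stays constant."""

    sigma: float = 0.748  # S/m

    def __post_init__(self) -> None:
        if not self.sigma > 0.0:
            raise ValueError("blood sigma must be positive")


@dataclass(frozen=True)
class PhaseChangeModel:
    """Water-vaporization model constants.

    The latent heat of the tissue is ``Hw_vol * water_mass_fraction`` and is
    released across the [T_lo, T_hi] band via the apparent heat capacity;
    electrical conductivity falls by ``drop_factor`` between ``sigma_drop_lo``
    and ``sigma_drop_hi``.
    """

    Hw_vol: float = 2.161e9  # J/m^3: 2256 kJ/kg * 958 kg/m^3 at 100 degC
    T_lo: float = 99.0  # degC
    T_hi: float = 100.0  # degC
    sigma_drop_lo: float = 99.0  # degC
    sigma_drop_hi: float = 101.0  # degC
    drop_factor: float = 100.0

    @property
    def delta_T(self) -> float:
        return self.T_hi - self.T_lo

    def tissue_latent_heat(self, props: TissueProperties) -> float:
        """Volumetric latent heat H_t = H_w * C in J/m^3."""
        if props.water_mass_fraction is None:
            return 0.0
        return self.Hw_vol * props.water_mass_fraction


@dataclass(frozen=True)
class ArrheniusParams:
    """First-order thermal-damage kinetics: dOmega/dt = A exp(-Ea/(R T))."""

    A: float = 7.39e39  # 1/s
    Ea: float = 2.577e5  # J/mol
    R: float = 8.3143  # J/(mol K)


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    return T


def electrical_conductivity(
    props: TissueProperties, T, phase: PhaseChangeModel = PhaseChangeModel()
):
    """Electrical conductivity sigma(T) in S/m (scalar or array ``T`` in degC).

    Linear +1.5 %/degC relative to the 37 degC reference up to 99 degC, then a
    log-linear collapse by two orders of magnitude across [99, 101] degC
    (vaporization-induced desiccation), constant at the collapsed value above.
    """
    T = _check_temperature(T)
    sigma_99 = props.sigma_ref * (1.0 + SIGMA_TEMP_COEFF * (phase.sigma_drop_lo - T_REF))
    lin = props.sigma_ref * (1.0 + SIGMA_TEMP_COEFF * (T - T_REF))
    frac = np.clip(
        (T - phase.sigma_drop_lo) / (phase.sigma_drop_hi - phase.sigma_drop_lo), 0.0, 1.0
    )
    collapsed = sigma_99 * phase.drop_factor ** (-frac)
    out = np.where(T <= phase.sigma_drop_lo, lin, collapsed)
    return out if out.ndim else float(out)


def volumetric_enthalpy(
    props: TissueProperties, T, phase: PhaseChangeModel = PhaseChangeModel()
):
    """Tissue enthalpy per unit volume h(T) in J/m^3, zero at 37 degC.

    Sensible heat with hydrated rho*c below 99 degC, the latent plateau
    spread over [99, 100] degC, and dehydrated rho*c (taken identical to
    hydrated) above 100 degC.  Defined for all T < 99 degC (not only above
    37 degC) so the 25 degC irrigated zone is representable.
    """
    T = _check_temperature(T)
    rc = props.rho_c
    Ht = phase.tissue_latent_heat(props)
    h_lo = rc * (T - T_REF)
    h_band = rc * (phase.T_lo - T_REF) + Ht * (T - phase.T_lo) / phase.delta_T
    h_hi = rc * (phase.T_lo - T_REF) + Ht + rc * (T - phase.T_hi)
    out = np.where(T <= phase.T_lo, h_lo, np.where(T <= phase.T_hi, h_band, h_hi))
    return out if out.ndim else float(out)


def apparent_heat_capacity(
    props: TissueProperties, T, phase: PhaseChangeModel = PhaseChangeModel()
):
    """Apparent volumetric heat capacity dh/dT in J/(m^3 K).

    rho*c outside the phase-change band; H_t/Delta_T inside (99, 100] degC.
    """
    T = _check_temperature(T)
    rc = props.rho_c
    Ht = phase.tissue_latent_heat(props)
    in_band = (T > phase.T_lo) & (T <= phase.T_hi)
    out = np.where(in_band, Ht / phase.delta_T if Ht > 0 else rc, rc)
    return out if out.ndim else float(out)


def thermal_conductivity_tensor(props: TissueProperties, anisotropic: bool = False):
    """Thermal conductivity as a 3x3 diagonal tensor in W/(m K).

    Isotropic: k*I.  Anisotropic (fibers along x, parallel to the tissue
    surface): diag(k_longitudinal, k_transverse, k_transverse) with the
    transverse value along the tissue-depth axis (z) and in-plane across the
    fibers (y).
    """
    if not anisotropic:
        return np.diag([props.k, props.k, props.k])
    if props.k_transverse is None or props.k_longitudinal is None:
        raise ValueError(f"{props.name}: directional conductivities not set")
    return np.diag([props.k_longitudinal, props.k_transverse, props.k_transverse])


@dataclass(frozen=True)
class MaterialLibrary:
    """The material set of the ablation models."""

    myocardium: TissueProperties
    striated_muscle: TissueProperties
    electrode: TissueProperties
    shaft: TissueProperties
    blood: BloodProperties

    def tissue(self, name: str) -> TissueProperties:
        key = name.lower()
        if key in ("myocardium", "bh", "beating_heart"):
            return self.myocardium
        if key in ("striated_muscle", "tm", "thigh_muscle"):
            return self.striated_muscle
        raise KeyError(f"unknown tissue {name!r}")


def load_default_library() -> MaterialLibrary:
    """Load the packaged material library (values as printed, SI units)."""
    text = resources.files("rfasim").joinpath("data/materials.yaml").read_text()
    raw = yaml.safe_load(text)
    mats = {
        name: TissueProperties(name=name, **fields)
        for name, fields in raw["materials"].items()
    }
    return MaterialLibrary(
        myocardium=mats["myocardium"],
        striated_muscle=mats["striated_muscle"],
        electrode=mats["electrode_pt_ir"],
        shaft=mats["catheter_polyurethane"],
        blood=BloodProperties(sigma=float(raw["blood"]["sigma"])),
    )
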