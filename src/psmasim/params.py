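"""Model constants, unit conversion, and per-tissue parameter lookup.

All downstream modules work in one canonical unit system:

* length        cm
* time          s
* pressure      Pa
* concentration nmol per litre of interstitial fluid

Published values for this class of model mix mmHg with Pa and minutes with
hours; every constant is converted once, at load time, and the canonical unit
of each field is recorded in :data:`ParameterSet.UNITS`.  Configuration files
and overrides are written in the *conventional* units of the physiology
literature (documented per key in :data:`CONFIG_UNITS`) and converted by
:func:`load_parameters`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError, ValidationError

__all__ = [
    "MMHG_TO_PA",
    "AVOGADRO",
    "TissueFlowParams",
    "ParameterSet",
    "convert_pressure",
    "load_parameters",
    "SCENARIO_RECEPTOR_DENSITY",
]

#: 1 mmHg in Pa (exact conventional factor).
MMHG_TO_PA = 133.322

AVOGADRO = 6.02214076e23

#: Tumor-scenario receptor densities, nmol/L.
SCENARIO_RECEPTOR_DENSITY = {"tumor1": 50.0, "tumor2": 500.0, "tumor3": 200.0}

_PRESSURE_FACTORS = {"Pa": 1.0, "mmHg": MMHG_TO_PA}


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between Pa and mmHg (1 mmHg = 133.322 Pa)."""
    try:
        f_from = _PRESSURE_FACTORS[from_unit]
        f_to = _PRESSURE_FACTORS[to_unit]
    except KeyError as exc:
        raise ConfigurationError(
            f"unknown pressure unit {exc.args[0]!r}; expected one of {sorted(_PRESSURE_FACTORS)}"
        ) from None
    return value * (f_from / f_to)


@dataclass(frozen=True)
class TissueFlowParams:
    """Interstitial-flow constants of one tissue class, in canonical units.

    ``K`` is the composite Darcy mobility k/mu of the tissue, ``Lp`` the
    hydraulic conductivity of the microvessel wall, ``lymph_conductance`` the
    lumped lymphatic drainage coefficient Lp_L*(S_L/V).  Tumor tissue carries
    no functional lymphatics, so its ``lymph_conductance`` is zero.
    """

    K: float                  # cm^2 / (Pa s)
    Lp: float                 # cm / (Pa s)
    lymph_conductance: float  # 1 / (Pa s)
    p_B: float                # vascular pressure, Pa
    p_L: float                # intralymphatic pressure, Pa
    S_V: float                # vessel surface per tissue volume, 1/cm
    pi_B: float               # plasma osmotic pressure, Pa
    pi_i: float               # interstitial osmotic pressure, Pa
    sigma_s: float            # osmotic reflection coefficient

    @property
    def p_equilibrium(self) -> float:
        """Starling zero-filtration pressure p_B - sigma_s*(pi_B - pi_i), Pa."""
        return self.p_B - self.sigma_s * (self.pi_B - self.pi_i)

    def validate(self, name: str) -> None:
        for field in ("K", "Lp", "p_B", "S_V", "pi_B", "pi_i"):
            if getattr(self, field) <= 0.0:
                raise ValidationError(f"{name}.{field} must be strictly positive")
        if self.p_L < 0.0:
            raise ValidationError(f"{name}.p_L must be non-negative")
        if self.lymph_conductance < 0.0:
            raise ValidationError(f"{name}.lymph_conductance must be non-negative")
        if not 0.0 <= self.sigma_s <= 1.0:
            raise ValidationError(f"{name}.sigma_s must lie in [0, 1]")


@dataclass(frozen=True)
class ParameterSet:
    """All physiological and kinetic constants in canonical units (cm, s, Pa, nmol/L)."""

    D_eff: float                    # free-ligand diffusion coefficient, cm^2/s
    receptor_density_tumor: float   # nmol/L
    receptor_density_normal_factor: float  # dimensionless
    f1: float                       # occupied-receptor degradation sorting fraction
    f2: float                       # free-receptor degradation sorting fraction
    FVc: float                      # fractional cellular volume
    FVi: float                      # fractional interstitial volume
    alpha: float                    # plasma clearance rate, 1/s
    lambda_lu177: float             # physical decay rate of 177Lu, 1/s
    k_int: float                    # internalization rate of occupied receptors, 1/s
    k_on: float                     # association rate, L/(nmol s)
    k_off: float                    # dissociation rate, 1/s
    k_rel: float                    # release rate of internalized ligand, 1/s
    k_deg: float                    # lysosomal receptor degradation rate, 1/s
    k_ec: float                     # constitutive endocytosis rate, 1/s
    k_rec: float                    # endosomal recycling rate, 1/s
    k_syn: float                    # ligand-induced synthesis rate, 1/s
    P: float                        # vessel wall solute permeability, cm/s
    R_f: float                      # retardation coefficient, dimensionless
    V_r: float                      # constitutive receptor synthesis, nmol/(L s)
    sigma_f: float                  # filtration reflection coefficient
    tumor: TissueFlowParams
    normal: TissueFlowParams
    plasma_volume: float            # L

    #: Canonical unit of every scalar field (documentation + sanity aid).
    UNITS = {
        "D_eff": "cm^2/s",
        "receptor_density_tumor": "nmol/L",
        "receptor_density_normal_factor": "1",
        "f1": "1",
        "f2": "1",
        "FVc": "1",
        "FVi": "1",
        "alpha": "1/s",
        "lambda_lu177": "1/s",
        "k_int": "1/s",
        "k_on": "L/(nmol s)",
        "k_off": "1/s",
        "k_rel": "1/s",
        "k_deg": "1/s",
        "k_ec": "1/s",
        "k_rec": "1/s",
        "k_syn": "1/s",
        "P": "cm/s",
        "R_f": "1",
        "V_r": "nmol/(L s)",
        "sigma_f": "1",
        "plasma_volume": "L",
    }

    def __post_init__(self) -> None:
        positive = (
            "D_eff", "receptor_density_tumor", "receptor_density_normal_factor",
            "alpha", "lambda_lu177", "k_int", "k_on", "k_off", "k_rel",
            "k_deg", "k_ec", "k_rec", "k_syn", "P", "R_f", "V_r",
            "plasma_volume", "FVc", "FVi",
        )
        for field in positive:
            if getattr(self, field) <= 0.0:
                raise ValidationError(f"parameter {field!r} must be strictly positive")
        for field in ("sigma_f", "f1", "f2"):
            if not 0.0 <= getattr(self, field) <= 1.0:
                raise ValidationError(f"parameter {field!r} must lie in [0, 1]")
        if abs(self.FVc + self.FVi - 1.0) > 1e-12:
            raise ValidationError("FVc + FVi must equal 1")
        self.tumor.validate("tumor")
        self.normal.validate("normal")
        half_life_days = math.log(2.0) / self.lambda_lu177 / 86400.0
        if not 5.0 < half_life_days < 9.0:
            raise ValidationError(
                f"lambda_lu177 implies a half-life of {half_life_days:.2f} d, "
                "far from the physical 177Lu half-life"
            )

    @property
    def receptor_density_normal(self) -> float:
        """Normal-tissue receptor density, nmol/L."""
        return self.receptor_density_normal_factor * self.receptor_density_tumor

    def receptor_density(self, tissue: str) -> float:
        if tissue == "tumor":
            return self.receptor_density_tumor
        if tissue == "normal":
            return self.receptor_density_normal
        raise ConfigurationError(f"unknown tissue class {tissue!r}")

    def flow(self, tissue: str) -> TissueFlowParams:
        if tissue == "tumor":
            return self.tumor
        if tissue == "normal":
            return self.normal
        raise ConfigurationError(f"unknown tissue class {tissue!r}")

    def replace(self, **canonical_overrides) -> "ParameterSet":
        """Return a copy with canonical-unit fields replaced (no conversion)."""
        return dataclasses.replace(self, **canonical_overrides)


# --- loading ---------------------------------------------------------------

_PER_MIN = 1.0 / 60.0
_PER_H = 1.0 / 3600.0


def _mmhg_inv(x: float) -> float:  # quantities "per mmHg" -> "per Pa"
    return x / MMHG_TO_PA


#: Configuration keys, their conventional unit, and the conversion applied to
#: reach canonical units.  Config files / CLI overrides use these units.
CONFIG_UNITS: Mapping[str, tuple[str, float]] = {
    "D_eff": ("cm^2/s", 1.0),
    "receptor_density_tumor": ("nmol/L", 1.0),
    "receptor_density_normal_factor": ("1", 1.0),
    "f1": ("1", 1.0),
    "f2": ("1", 1.0),
    "FVc": ("1", 1.0),
    "FVi": ("1", 1.0),
    "alpha": ("1/h", _PER_H),
    "lambda_lu177": ("1/min", _PER_MIN),
    "k_int": ("1/min", _PER_MIN),
    "k_on": ("L/(nmol min)", _PER_MIN),
    "k_off": ("1/min", _PER_MIN),
    "k_rel": ("1/min", _PER_MIN),
    "k_deg": ("1/s", 1.0),
    "k_ec": ("1/min", _PER_MIN),
    "k_rec": ("1/min", _PER_MIN),
    "k_syn": ("1/min", _PER_MIN),
    "P": ("cm/s", 1.0),
    "R_f": ("1", 1.0),
    "V_r": ("mol/(m^3 s)", 1.0e6),   # mol/(m^3 s) -> nmol/(L s)
    "sigma_f": ("1", 1.0),
    "plasma_volume": ("L", 1.0),
}

_FLOW_CONFIG_UNITS: Mapping[str, tuple[str, float]] = {
    "K": ("cm^2/(mmHg s)", 1.0 / MMHG_TO_PA),
    "Lp": ("cm/(mmHg s)", 1.0 / MMHG_TO_PA),
    "lymph_conductance": ("1/(mmHg s)", 1.0 / MMHG_TO_PA),
    "p_B": ("mmHg", MMHG_TO_PA),
    "p_L": ("mmHg", MMHG_TO_PA),
    "S_V": ("1/cm", 1.0),
    "pi_B": ("mmHg", MMHG_TO_PA),
    "pi_i": ("mmHg", MMHG_TO_PA),
    "sigma_s": ("1", 1.0),
}

#: Default scalar values in the conventional units of :data:`CONFIG_UNITS`.
_SCALAR_DEFAULTS = {
    "D_eff": 8.7e-7,
    "receptor_density_normal_factor": 0.1,
    "f1": 0.5,
    "f2": 0.5,
    "FVc": 0.61,
    "FVi": 0.39,
    "alpha": 0.0521,
    "lambda_lu177": 7.15e-5,
    "k_int": 0.001,
    "k_on": 0.046,
    "k_off": 0.046,
    "k_rel": 2.0e-4,
    "k_deg": 2.9891e-4,
    "k_ec": 0.007,
    "k_rec": 0.15,
    "k_syn": 0.0118,
    "P": 3.3e-4,
    "R_f": 1.0,
    "V_r": 1.2e-22,
    "sigma_f": 0.9,
    "plasma_volume": 3.0,
}

#: Per-tissue flow defaults in the conventional units of :data:`_FLOW_CONFIG_UNITS`.
_FLOW_DEFAULTS = {
    "normal": {
        "K": 8.53e-9,
        "Lp": 0.36e-7,
        "lymph_conductance": 1.33e-5,
        "p_B": 15.6,
        "p_L": 0.0,
        "S_V": 70.0,
        "pi_B": 20.0,
        "pi_i": 10.0,
        "sigma_s": 0.91,
    },
    "tumor": {
        "K": 4.13e-8,
        "Lp": 2.80e-7,
        "lymph_conductance": 0.0,   # no functional lymphatics in tumor
        "p_B": 15.6,
        "p_L": 0.0,
        "S_V": 200.0,
        "pi_B": 20.0,
        "pi_i": 15.0,
        "sigma_s": 0.82,
    },
}

_POSITIVE_CONFIG_KEYS = {
    k for k in CONFIG_UNITS
    if k not in ("receptor_density_normal_factor",)
} - {"f1", "f2", "sigma_f"}


def load_parameters(
    config: Mapping | str | Path | None = None,
    scenario: str = "tumor1",
) -> ParameterSet:
    """Build a :class:`ParameterSet` from defaults, a scenario, and overrides.

    Parameters
    ----------
    config
        Mapping of overrides (or path to a YAML file containing one) in the
        conventional units listed in :data:`CONFIG_UNITS`.  Per-tissue flow
        constants live under ``tumor:`` / ``normal:`` sub-mappings using the
        units of the flow table (pressures in mmHg, conductivities per mmHg).
    scenario
        ``tumor1`` / ``tumor2`` / ``tumor3`` select the corresponding tumor
        receptor density (50 / 500 / 200 nmol/L); ``custom`` requires an
        explicit ``receptor_density_tumor`` entry in *config*.
    """
    if isinstance(config, (str, Path)):
        with open(config, "r") as fh:
            config = yaml.safe_load(fh) or {}
    config = dict(config or {})

    if scenario not in (*SCENARIO_RECEPTOR_DENSITY, "custom"):
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; expected one of "
            f"{sorted(SCENARIO_RECEPTOR_DENSITY)} or 'custom'"
        )

    scalars = dict(_SCALAR_DEFAULTS)
    if scenario != "custom":
        scalars["receptor_density_tumor"] = SCENARIO_RECEPTOR_DENSITY[scenario]
    flow = {t: dict(v) for t, v in _FLOW_DEFAULTS.items()}

    for key, value in config.items():
        if key in ("tumor", "normal"):
            if not isinstance(value, Mapping):
                raise ConfigurationError(f"config section {key!r} must be a mapping")
            for fkey, fval in value.items():
                if fkey not in _FLOW_CONFIG_UNITS:
                    raise ConfigurationError(
                        f"unknown flow parameter {key}.{fkey!r}"
                    )
                flow[key][fkey] = float(fval)
        elif key in CONFIG_UNITS:
            scalars[key] = float(value)
        else:
            raise ConfigurationError(f"unknown parameter {key!r}")

    if "receptor_density_tumor" not in scalars:
        raise ConfigurationError(
            "scenario 'custom' requires an explicit receptor_density_tumor"
        )

    for key, value in scalars.items():
        if key in _POSITIVE_CONFIG_KEYS and value <= 0.0:
            raise ValidationError(f"parameter {key!r} must be strictly positive")

    canon = {k: v * CONFIG_UNITS[k][1] for k, v in scalars.items()}
    tissues = {}
    for tissue, block in flow.items():
        tissues[tissue] = TissueFlowParams(
            **{k: v * _FLOW_CONFIG_UNITS[k][1] for k, v in block.items()}
        )
    return ParameterSet(tumor=tissues["tumor"], normal=tissues["normal"], **canon)
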