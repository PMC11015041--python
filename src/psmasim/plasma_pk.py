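"""Vascular input function: plasma concentration for bolus and infusion dosing.

A one-compartment description: a bolus of ``A`` nmol distributed over plasma
volume ``V`` clears mono-exponentially at rate ``alpha``,

    C_p(t) = (A / V) exp(-alpha t).

A constant-rate infusion of the same amount over duration ``T`` gives

    C_p(t) = A / (V alpha T) (1 - exp(-alpha t)),                 t < T
    C_p(t) = A / (V alpha T) (exp(alpha T) - 1) exp(-alpha t),    t >= T

which is continuous at ``t = T`` and integrates to the same total plasma
exposure A/(V alpha).  Only a fraction of the administered peptide carries the
radiolabel; the labeled ("hot") and unlabeled ("cold") ligands share the same
clearance, so the split is a fixed proportion of C_p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["AdministrationProtocol", "plasma_concentration"]

_MIN_TO_S = 60.0


@dataclass(frozen=True)
class AdministrationProtocol:
    """How the ligand is administered.

    Times are in minutes, amounts in nmol, clearance ``alpha`` in 1/h (the
    conventional unit for this constant).
    """

    amount_total: float                 # nmol, labeled + unlabeled
    labeled_fraction: float = 0.10
    mode: str = "bolus"                 # "bolus" | "infusion"
    infusion_duration: float = 60.0     # min, used when mode == "infusion"
    plasma_volume: float = 3.0          # L
    alpha: float = 0.0521               # 1/h

    def __post_init__(self) -> None:
        if self.amount_total < 0.0:
            raise ValidationError("amount_total must be non-negative")
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ValidationError("labeled_fraction must lie in (0, 1]")
        if self.mode not in ("bolus", "infusion"):
            raise ValidationError(f"unknown administration mode {self.mode!r}")
        if self.mode == "infusion" and self.infusion_duration <= 0.0:
            raise ValidationError("infusion_duration must be positive")
        if self.plasma_volume <= 0.0 or self.alpha <= 0.0:
            raise ValidationError("plasma_volume and alpha must be positive")

    @property
    def c_p0(self) -> float:
        """Reference plasma concentration A/V, nmol/L."""
        return self.amount_total / self.plasma_volume

    @property
    def alpha_per_min(self) -> float:
        return self.alpha / 60.0

    @property
    def plasma_auc(self) -> float:
        """Total plasma exposure integral of C_p over [0, inf), nmol min / L."""
        return self.amount_total / (self.plasma_volume * self.alpha_per_min)


def plasma_concentration(
    protocol: AdministrationProtocol, t: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled and unlabeled plasma concentration at time ``t`` (minutes).

    Returns ``(C_p_labeled, C_p_unlabeled)`` in nmol/L, each with the shape
    of ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValidationError("t must be non-negative")
    a = protocol.alpha_per_min
    c0 = protocol.c_p0
    if protocol.mode == "bolus":
        cp = c0 * np.exp(-a * t)
    else:
        T = protocol.infusion_duration
        scale = c0 / (a * T)
        rising = scale * -np.expm1(-a * t)
        washout = scale * np.expm1(a * T) * np.exp(-a * t)
        cp = np.where(t < T, rising, washout)
    return protocol.labeled_fraction * cp, (1.0 - protocol.labeled_fraction) * cp
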