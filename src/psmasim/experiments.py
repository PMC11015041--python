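"""Parameter sweeps and administration comparisons on surrogate phantoms.

The patient geometries behind the published sweep figures are not available,
so the named tumor scenarios run on spherical surrogates (default 0.5 cm
radius in a 2 cm normal-tissue cube at 0.1 cm spacing) carrying the
scenario's receptor density.  Sweep conclusions are reported as ratios,
orderings and argmax locations, which are the geometry-robust quantities;
absolute TIA values scale with tumor volume and are surrogate-specific.

All members of a sweep share one phantom and one steady flow solve and are
integrated together as a batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .darcy_flow import FlowField
from .errors import ConfigurationError, ValidationError
from .params import ParameterSet, load_parameters
from .phantom import Phantom, make_spherical_phantom
from .plasma_pk import AdministrationProtocol
from .transport import BatchMember, SimulationResult, run_batch

__all__ = [
    "SweepSpec",
    "TIAResult",
    "SweepResult",
    "surrogate_phantom",
    "run_sweep",
    "compare_bolus_infusion",
    "carrier_addition_experiment",
]

SWEEP_VARIABLES = (
    "receptor_density",   # nmol/L
    "k_rec",              # 1/min
    "amount_total",       # nmol
    "labeled_fraction",   # dimensionless
    "mode",               # "bolus" | "infusion"
)

#: Ranges studied for each sweep variable (inclusive).
DEFAULT_RANGES = {
    "receptor_density": (10.0, 500.0),
    "k_rec": (1e-4, 1e-1),
    "amount_total": (100.0, 1000.0),
    "labeled_fraction": (0.01, 0.10),
}


def surrogate_phantom(
    tumor_radius: float = 0.5,
    domain_half_width: float = 1.0,
    spacing: float = 0.1,
) -> Phantom:
    """Default spherical tumor surrogate used by the sweep experiments."""
    return make_spherical_phantom(tumor_radius, domain_half_width, spacing)


@dataclass(frozen=True)
class SweepSpec:
    """One-variable sweep description.

    ``values`` are in the conventional unit of the variable (see
    :data:`SWEEP_VARIABLES`).  ``scenario`` picks the tumor receptor density
    unless the sweep variable is ``receptor_density`` itself.
    """

    variable: str
    values: tuple
    scenario: str = "tumor1"
    amount_total: float = 100.0
    labeled_fraction: float = 0.10
    mode: str = "bolus"
    infusion_duration: float = 60.0
    k_rec_per_min: float | None = None
    enforce_ranges: bool = True

    def __post_init__(self) -> None:
        if self.variable not in SWEEP_VARIABLES:
            raise ConfigurationError(
                f"unknown sweep variable {self.variable!r}; "
                f"expected one of {SWEEP_VARIABLES}"
            )
        if not self.values:
            raise ConfigurationError("sweep needs at least one value")
        if self.enforce_ranges and self.variable in DEFAULT_RANGES:
            lo, hi = DEFAULT_RANGES[self.variable]
            for v in self.values:
                if not lo <= float(v) <= hi:
                    raise ValidationError(
                        f"{self.variable} value {v} outside studied range [{lo}, {hi}]"
                    )


@dataclass
class TIAResult:
    """Integral summaries of one simulation member."""

    tia_tumor: float              # MBq min
    tia_normal: float             # MBq min
    auc_by_species: dict          # nmol min / L, tumor volume average
    peak_times: dict              # min
    c_p0: float                   # nmol/L

    @classmethod
    def from_result(cls, result: SimulationResult, member: int) -> "TIAResult":
        return cls(
            tia_tumor=float(result.tia("tumor")[member]),
            tia_normal=float(result.tia("normal")[member]),
            auc_by_species={
                k: float(v[member]) for k, v in result.auc_by_species("tumor").items()
            },
            peak_times={
                k: float(v[member]) for k, v in result.peak_times("tumor").items()
            },
            c_p0=float(result.c_p0[member]),
        )


@dataclass
class SweepResult:
    """Sweep table plus the raw batch result."""

    spec: SweepSpec
    table: pd.DataFrame           # one row per value: value, tia_tumor, tia_normal, ...
    result: SimulationResult

    @property
    def argmax_value(self):
        """Sweep value with the largest tumor TIA."""
        return self.table.loc[self.table["tia_tumor"].idxmax(), "value"]

    def fold_change(self, low, high) -> float:
        """TIA(high) / TIA(low) between two swept values."""
        t = self.table.set_index("value")["tia_tumor"]
        return float(t.loc[high] / t.loc[low])


def _members_for(spec: SweepSpec, params: ParameterSet) -> list[BatchMember]:
    members = []
    for v in spec.values:
        amount = spec.amount_total
        labeled = spec.labeled_fraction
        mode = spec.mode
        k_rec = spec.k_rec_per_min
        density = None
        if spec.variable == "amount_total":
            amount = float(v)
        elif spec.variable == "labeled_fraction":
            labeled = float(v)
        elif spec.variable == "mode":
            mode = str(v)
        elif spec.variable == "k_rec":
            k_rec = float(v)
        elif spec.variable == "receptor_density":
            density = float(v)
        protocol = AdministrationProtocol(
            amount_total=amount,
            labeled_fraction=labeled,
            mode=mode,
            infusion_duration=spec.infusion_duration,
            plasma_volume=params.plasma_volume,
            alpha=params.alpha * 3600.0,
        )
        members.append(
            BatchMember(
                protocol=protocol,
                k_rec_per_min=k_rec,
                receptor_density=density,
                label=f"{spec.variable}={v}",
            )
        )
    return members


def run_sweep(
    spec: SweepSpec,
    phantom: Phantom | None = None,
    params: ParameterSet | None = None,
    flow: FlowField | None = None,
    t_end_h: float = 50.0,
    dt_min: float = 0.1,
    output_every_min: float = 5.0,
) -> SweepResult:
    """Run a one-variable sweep as a single shared-flow batch.

    Returns a tidy table with one row per swept value (tumor and normal TIA
    in MBq min plus per-species tumor AUCs) and the underlying batch result.
    """
    params = params or load_parameters(scenario=spec.scenario)
    phantom = phantom or surrogate_phantom()
    members = _members_for(spec, params)
    result = run_batch(
        phantom,
        params,
        members,
        t_end_h=t_end_h,
        dt_min=dt_min,
        output_every_min=output_every_min,
        flow=flow,
    )
    tia_t = result.tia("tumor")
    tia_n = result.tia("normal")
    aucs = result.auc_by_species("tumor")
    rows = []
    for i, v in enumerate(spec.values):
        row = {
            "value": v,
            "tia_tumor": tia_t[i],
            "tia_normal": tia_n[i],
        }
        row.update({f"auc_{k}": aucs[k][i] for k in aucs})
        rows.append(row)
    return SweepResult(spec=spec, table=pd.DataFrame(rows), result=result)


def compare_bolus_infusion(
    amount_total: float = 100.0,
    labeled_fraction: float = 0.10,
    infusion_duration: float = 60.0,
    scenario: str = "tumor1",
    phantom: Phantom | None = None,
    params: ParameterSet | None = None,
    flow: FlowField | None = None,
    t_end_h: float = 50.0,
    dt_min: float = 0.1,
) -> dict:
    """Bolus vs. continuous infusion of the same amount on one phantom.

    Returns per-mode :class:`TIAResult` summaries plus per-compartment peak
    concentrations in tumor and normal tissue.
    """
    spec = SweepSpec(
        variable="mode",
        values=("bolus", "infusion"),
        scenario=scenario,
        amount_total=amount_total,
        labeled_fraction=labeled_fraction,
        infusion_duration=infusion_duration,
    )
    sweep = run_sweep(
        spec, phantom=phantom, params=params, flow=flow, t_end_h=t_end_h, dt_min=dt_min
    )
    result = sweep.result
    out = {"sweep": sweep}
    for i, mode in enumerate(("bolus", "infusion")):
        out[mode] = TIAResult.from_result(result, i)
        out[f"{mode}_peaks_tumor"] = {
            k: float(v[i].max()) for k, v in result.tumor_mean.items()
        }
        out[f"{mode}_peaks_normal"] = {
            k: float(v[i].max()) for k, v in result.normal_mean.items()
        }
    return out


def carrier_addition_experiment(
    labeled_amount: float = 10.0,
    carrier_amount: float = 100.0,
    scenario: str = "tumor1",
    phantom: Phantom | None = None,
    params: ParameterSet | None = None,
    flow: FlowField | None = None,
    t_end_h: float = 50.0,
    dt_min: float = 0.1,
) -> dict:
    """Pure labeled dose vs. the same labeled dose plus unlabeled carrier.

    Reports tumor TIA for both administrations and their relative change.
    Absolute TIA values depend on the surrogate tumor volume; the relative
    change is the geometry-robust quantity.
    """
    params = params or load_parameters(scenario=scenario)
    phantom = phantom or surrogate_phantom()
    total = labeled_amount + carrier_amount
    members = [
        BatchMember(
            protocol=AdministrationProtocol(
                amount_total=labeled_amount,
                labeled_fraction=1.0,
                plasma_volume=params.plasma_volume,
                alpha=params.alpha * 3600.0,
            ),
            label="pure labeled",
        ),
        BatchMember(
            protocol=AdministrationProtocol(
                amount_total=total,
                labeled_fraction=labeled_amount / total,
                plasma_volume=params.plasma_volume,
                alpha=params.alpha * 3600.0,
            ),
            label="labeled + carrier",
        ),
    ]
    result = run_batch(phantom, params, members, t_end_h=t_end_h, dt_min=dt_min, flow=flow)
    tia = result.tia("tumor")
    return {
        "tia_pure_labeled": float(tia[0]),
        "tia_with_carrier": float(tia[1]),
        "relative_change": float(tia[1] / tia[0] - 1.0),
        "result": result,
    }
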