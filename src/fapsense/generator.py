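"""Synthetic plate-reader data with the structure the analyses assume.

Each well couples a lagged logistic growth curve to the mechanistic FapR/RFP
cascade.  Induction enters through saturating (Hill) maps: IPTG sets the
construct's malonyl-CoA production rate vm, arabinose sets the FapR pool F.
Measurement noise is multiplicative Gaussian (plate-reader noise scales with
signal), clipped at zero.  A fixed seed and design reproduce the plate
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .cascade import SensorParams, simulate_sensor_cascade
from .constructs import REFERENCE_MODEL2, mechanistic_params
from .errors import InvalidParameterError
from .growth import GrowthParams, logistic_derivative, logistic_growth
from .plate import PlateTimeSeries, Well

__all__ = [
    "InductionMap",
    "induction_to_rate",
    "WellSpec",
    "DepletionScenario",
    "PlateDesign",
    "generate_plate",
    "default_design",
    "DEFAULT_IPTG_DOSES_MM",
]

#: IPTG concentration series (mM) used for sensor characterization.
DEFAULT_IPTG_DOSES_MM = (0.01, 0.1, 0.3, 0.6, 1.0, 10.0)

#: working arabinose concentration (%) for FapR expression
DEFAULT_ARABINOSE_PCT = 0.01


@dataclass(frozen=True)
class InductionMap:
    """Monotone Hill map from inducer concentration to a rate or pool size.

    output = basal + vmax * c^n / (kh^n + c^n); bounded by basal + vmax.
    """

    basal: float
    vmax: float
    kh: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.basal < 0 or self.vmax < 0:
            raise InvalidParameterError("basal and vmax must be >= 0")
        if not self.kh > 0:
            raise InvalidParameterError(f"kh must be > 0, got {self.kh}")
        if not self.n >= 1:
            raise InvalidParameterError(f"Hill exponent must be >= 1, got {self.n}")


def induction_to_rate(inducer: float, imap: InductionMap) -> float:
    """Evaluate the Hill map at a single inducer concentration."""
    if inducer < 0:
        raise InvalidParameterError(f"inducer concentration must be >= 0, got {inducer}")
    if inducer == 0:
        return imap.basal
    cn = inducer**imap.n
    return imap.basal + imap.vmax * cn / (imap.kh**imap.n + cn)


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    construct: str
    iptg_mm: float
    arabinose_pct: float = DEFAULT_ARABINOSE_PCT
    substrate: bool = False
    replicate: int = 1


@dataclass(frozen=True)
class DepletionScenario:
    """Stationary-phase arabinose-depletion scenario (off by default).

    Once the culture passes ``od_threshold`` the FapR pool drops to
    ``factor`` times its level (arabinose consumed once glucose runs out, so
    repressor expression stops).  Within the mass-action cascade — which has
    no basal-transcription term — a smaller FapR pool lowers the
    complex-mediated signal; the scenario perturbs the late trajectory as a
    mechanism switch for robustness studies, it does not reproduce the
    derepression surge real cultures show after this transition.
    """

    od_threshold: float = 0.9
    factor: float = 0.1


@dataclass(frozen=True)
class PlateDesign:
    """Everything needed to simulate one plate deterministically."""

    wells: tuple
    growth: GrowthParams
    sensors: Mapping[str, SensorParams]
    iptg_maps: Mapping[str, InductionMap]
    ara_map: InductionMap
    n_times: int = 240
    ts: float = 12.0
    noise_sigma: float = 0.02
    substrate_factors: Mapping[str, float] = field(default_factory=dict)
    depletion: Optional[DepletionScenario] = None

    def __post_init__(self) -> None:
        if len(self.wells) == 0:
            raise InvalidParameterError("plate design has no wells")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise sigma must be >= 0")
        if not (self.ts > 0 and self.n_times >= 2):
            raise InvalidParameterError("need ts > 0 and at least two time points")
        object.__setattr__(self, "wells", tuple(self.wells))

    @property
    def time_min(self) -> np.ndarray:
        return np.arange(self.n_times) * self.ts


def generate_plate(design: PlateDesign, seed: int) -> PlateTimeSeries:
    """Simulate every well of ``design`` and add measurement noise.

    With ``noise_sigma = 0`` the output equals the noise-free simulation
    exactly; identical seed and design give identical output.
    """
    rng = np.random.default_rng(seed)
    t = design.time_min
    x_clean = logistic_growth(design.growth, t)
    dx = logistic_derivative(design.growth, t)

    wells = []
    for spec in design.wells:
        if spec.construct not in design.sensors:
            raise InvalidParameterError(f"no sensor parameters for construct {spec.construct!r}")
        vm = induction_to_rate(spec.iptg_mm, design.iptg_maps[spec.construct])
        if spec.substrate:
            vm *= design.substrate_factors.get(spec.construct, 1.0)
        f = induction_to_rate(spec.arabinose_pct, design.ara_map)
        sensor = replace(design.sensors[spec.construct], vm=vm, f=f)
        f_series = None
        if design.depletion is not None:
            f_series = np.where(
                x_clean < design.depletion.od_threshold, f, f * design.depletion.factor
            )
        result = simulate_sensor_cascade(sensor, x_clean, t, dbiomass=dx, f_series=f_series)
        od = x_clean * (1.0 + design.noise_sigma * rng.standard_normal(t.size))
        rfp = result.r * (1.0 + design.noise_sigma * rng.standard_normal(t.size))
        wells.append(
            Well(
                well_id=spec.well_id,
                construct=spec.construct,
                iptg_mm=spec.iptg_mm,
                arabinose_pct=spec.arabinose_pct,
                substrate=spec.substrate,
                replicate=spec.replicate,
                od=np.clip(od, 0.0, None),
                rfp=np.clip(rfp, 0.0, None),
            )
        )
    return PlateTimeSeries(time_min=t, wells=tuple(wells))


def _well_ids():
    for row in "ABCDEFGH":
        for col in range(1, 13):
            yield f"{row}{col}"


def default_design(
    constructs=tuple(REFERENCE_MODEL2),
    iptg_doses=DEFAULT_IPTG_DOSES_MM,
    replicates: int = 3,
    noise_sigma: float = 0.02,
    n_times: int = 240,
    ts: float = 12.0,
    substrate: bool = False,
    substrate_factors: Mapping[str, float] | None = None,
    growth: GrowthParams | None = None,
    arabinose_pct: float = DEFAULT_ARABINOSE_PCT,
) -> PlateDesign:
    """Characterization layout: constructs x IPTG doses x replicates.

    The default (5 constructs, 6 doses, 3 replicates) fills 90 wells of a
    96-well plate; the last 6 wells carry an empty-vector control (basal
    production only).  Per construct, only vm varies with IPTG — the time
    constants are construct properties — so the generated truth has a
    dose-dependent gain and dose-independent dynamics.
    """
    if growth is None:
        growth = GrowthParams(x0=0.05, xmax=1.2, mu=0.01, lag=60.0)
    sensors = {name: mechanistic_params(name) for name in constructs}
    iptg_maps = {}
    for name in constructs:
        vm_ref = sensors[name].vm  # the 1 mM-class reference rate
        basal = 0.05 * vm_ref
        # saturating increment chosen so the map hits vm_ref at 1 mM
        vmax = (vm_ref - basal) * (0.3 + 1.0) / 1.0
        iptg_maps[name] = InductionMap(basal=basal, vmax=vmax, kh=0.3, n=1.0)
    # arabinose -> FapR pool; 1 uM at the working 0.01%
    ara_map = InductionMap(basal=0.1, vmax=1.8, kh=0.01, n=1.0)

    ids = _well_ids()
    wells = [
        WellSpec(
            well_id=next(ids),
            construct=name,
            iptg_mm=dose,
            arabinose_pct=arabinose_pct,
            substrate=substrate,
            replicate=rep,
        )
        for name in constructs
        for dose in iptg_doses
        for rep in range(1, replicates + 1)
    ]
    n_controls = 96 - len(wells)
    if n_controls > 0 and len(constructs) == 5 and len(iptg_doses) == 6 and replicates == 3:
        control = mechanistic_params(tuple(constructs)[0])
        sensors["empty_vector"] = control
        iptg_maps["empty_vector"] = InductionMap(
            basal=0.05 * control.vm, vmax=0.0, kh=0.3, n=1.0
        )
        for rep, dose in enumerate(DEFAULT_IPTG_DOSES_MM, start=1):
            wells.append(
                WellSpec(
                    well_id=next(ids),
                    construct="empty_vector",
                    iptg_mm=dose,
                    substrate=substrate,
                    replicate=1,
                )
            )
    return PlateDesign(
        wells=tuple(wells),
        growth=growth,
        sensors=sensors,
        iptg_maps=iptg_maps,
        ara_map=ara_map,
        n_times=n_times,
        ts=ts,
        noise_sigma=noise_sigma,
        substrate_factors=dict(substrate_factors or {}),
    )
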