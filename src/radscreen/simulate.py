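"""Synthetic plate screens with known ground truth.

The generator emulates a drug x radiation combination screen in 384-well
plates: blank wells, untreated controls, a multi-point drug concentration
series, radiation-only arms, the full combination grid, duplicate wells per
condition, and several independent experiments.

Ground truth:

* drug-only survival follows a Hill curve
  ``floor + (1 - floor) / (1 + (c / ec50)^h)``;
* radiation-only survival follows the linear-quadratic model
  ``exp(-alpha*D - beta*D^2)``;
* combination survival is ``S_drug * S_rad * rho`` where the interaction
  factor rho multiplies survival directly — rho = 1 is exact Bliss
  additivity, rho < 1 synergy — so the pipeline's mean interaction ratio
  estimates rho itself and parameter recovery is a sharp test.

Measurement noise is multiplicative log-normal per well (fluorescence noise
is scale-proportional) plus a shared per-experiment log-normal factor; the
per-experiment factor cancels exactly in interaction ratios, as it does in a
real paired design. Clonogenic wells emit Poisson colony counts with mean
``plating_cells * S``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .plate_io import Assay, Condition, Culture, ExperimentSet, Role, WellRecord

__all__ = [
    "HillParams",
    "LQParams",
    "DesignParams",
    "NoiseParams",
    "SimulationConfig",
    "drug_survival",
    "radiation_survival",
    "combination_survival",
    "default_config",
    "config_from_dict",
    "simulate_screen",
]


@dataclass(frozen=True)
class HillParams:
    """Sigmoidal drug-only survival: ec50 in µM, hill_slope > 0, and a
    survival floor in [0, 1) for drugs that never kill the full population."""

    ec50: float
    hill_slope: float = 1.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be > 0")
        if not 0 <= self.floor < 1:
            raise ValueError("floor must be in [0, 1)")


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic radiation survival S(D) = exp(-alpha*D - beta*D^2).

    alpha may come out negative when the pair is calibrated from measured
    two-point survival data (survival then exceeds 1 slightly at very low
    doses); the doses actually simulated should sit in the calibrated range.
    """

    alpha: float  # Gy^-1
    beta: float  # Gy^-2

    @classmethod
    def from_survival_points(
        cls, d1: float, s1: float, d2: float, s2: float
    ) -> "LQParams":
        """Solve the 2x2 linear system for (alpha, beta) so the curve passes
        exactly through (d1, s1) and (d2, s2)."""
        if d1 <= 0 or d2 <= 0 or d1 == d2:
            raise ValueError("need two distinct positive doses")
        if not (0 < s1 <= 1 and 0 < s2 <= 1):
            raise ValueError("survival fractions must be in (0, 1]")
        a = np.array([[d1, d1 ** 2], [d2, d2 ** 2]], dtype=float)
        b = -np.log([s1, s2])
        alpha, beta = np.linalg.solve(a, b)
        return cls(alpha=float(alpha), beta=float(beta))

    def survival(self, dose: float) -> float:
        return radiation_survival(dose, self)


def drug_survival(concentration: float, params: HillParams) -> float:
    """Hill-model drug-only survival fraction; 1 at zero concentration,
    params.floor as concentration -> infinity."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        return 1.0
    return params.floor + (1.0 - params.floor) / (
        1.0 + (concentration / params.ec50) ** params.hill_slope
    )


def radiation_survival(dose: float, params: LQParams) -> float:
    """Linear-quadratic survival fraction at ``dose`` Gy."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return math.exp(-params.alpha * dose - params.beta * dose ** 2)


def _nine_point_series(top: float = 100.0) -> tuple[float, ...]:
    # half-log (sqrt-10) dilution steps, highest concentration first
    return tuple(top * 10 ** (-i / 2) for i in range(9))


@dataclass(frozen=True)
class DesignParams:
    """Plate/experiment layout. Defaults mirror the screening design:
    a 9-point concentration series, radiation arms at 4 and 6 Gy, duplicate
    wells per condition, and 5 independent experiments (screens in this
    format run 3-7)."""

    concentrations: tuple[float, ...] = field(default_factory=_nine_point_series)
    doses: tuple[float, ...] = (4.0, 6.0)
    wells_per_condition: int = 2
    n_experiments: int = 5
    blanks_per_plate: int = 6
    controls_per_plate: int = 6
    plating_cells: int = 200  # clonogenic: cells plated per well
    # recorded design metadata (no computational role)
    cells_per_spheroid: int = 10_000
    cells_per_monolayer_well: int = 1_000

    def __post_init__(self) -> None:
        if self.wells_per_condition < 1 or self.n_experiments < 1:
            raise ValueError("wells_per_condition and n_experiments must be >= 1")
        if self.controls_per_plate < 1:
            raise ValueError("need at least one control well per plate")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be > 0")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be > 0")
        if self.plating_cells < 1:
            raise ValueError("plating_cells must be >= 1")


@dataclass(frozen=True)
class NoiseParams:
    """Noise and signal-scale parameters.

    CVs are coefficients of variation of multiplicative log-normal factors
    (zero-mean Gaussian on the log scale, sigma^2 = ln(1 + CV^2)).
    ``spheroid_growth`` is the fold-growth of an untreated spheroid over the
    incubation, visible only in the self-normalized GFP AUTO SI read-out.
    """

    well_cv: float = 0.10
    experiment_cv: float = 0.05
    blank_level: float = 100.0  # AU
    control_signal: float = 10_000.0  # AU above blank, untreated well
    spheroid_growth: float = 2.0

    def __post_init__(self) -> None:
        if self.well_cv < 0 or self.experiment_cv < 0:
            raise ValueError("CVs must be >= 0")
        if not self.control_signal > self.blank_level > 0:
            raise ValueError("need control_signal > blank_level > 0")
        if self.spheroid_growth <= 0:
            raise ValueError("spheroid_growth must be > 0")


InteractionSpec = float | Mapping[str, float] | Callable[[str, float, float], float]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one screen with known ground truth."""

    assay: Assay = Assay.FMCA
    culture: Culture = Culture.SPHEROID
    drugs: Mapping[str, HillParams] = field(
        default_factory=lambda: dict(DEFAULT_DRUGS)
    )
    radiation: LQParams = field(
        default_factory=lambda: SPHEROID_TOTAL_KILL_LQ
    )
    interaction: InteractionSpec = 1.0
    design: DesignParams = field(default_factory=DesignParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError("at least one drug is required")

    # -- ground truth ------------------------------------------------------

    def rho(self, drug: str, concentration: float, dose: float) -> float:
        """Interaction factor for one condition (1 = Bliss-additive)."""
        if callable(self.interaction):
            value = float(self.interaction(drug, concentration, dose))
        elif isinstance(self.interaction, Mapping):
            value = float(self.interaction.get(drug, 1.0))
        else:
            value = float(self.interaction)
        if value <= 0:
            raise ValueError("interaction factor must be > 0")
        return value

    def drug_s(self, drug: str, concentration: float) -> float:
        return drug_survival(concentration, self.drugs[drug])

    def rad_s(self, dose: float) -> float:
        return radiation_survival(dose, self.radiation)

    def survival(self, condition: Condition) -> float:
        """True survival fraction of one condition (drug and/or radiation)."""
        return combination_survival(condition.concentration, condition.dose, self, condition.drug)

    def expected_readout(self, condition: Condition, relative_to_control: bool = False) -> float:
        """Noise-free value the pipeline should recover for this condition.

        Equal to true survival for SI/SF read-outs. For the spheroid GFP
        AUTO SI it includes the untreated fold-growth unless
        ``relative_to_control`` (control-normalized AUTO SI) is requested.
        """
        s = self.survival(condition)
        if (
            self.assay is Assay.GFP
            and self.culture is Culture.SPHEROID
            and not relative_to_control
        ):
            return self.noise.spheroid_growth * s
        return s


def combination_survival(
    concentration: float, dose: float, config: SimulationConfig, drug: str = ""
) -> float:
    """Ground-truth survival S_drug(c) * S_rad(D) * rho(c, D), clipped at 0.

    rho applies only when both treatments are present, so single-agent arms
    stay exactly on their marginal curves and the Bliss interaction ratio of
    the noise-free screen equals rho identically.
    """
    s = 1.0
    if concentration > 0:
        if not drug:
            raise ValueError("a positive concentration needs a drug name")
        s *= config.drug_s(drug, concentration)
    if dose > 0:
        s *= config.rad_s(dose)
    if concentration > 0 and dose > 0:
        s *= config.rho(drug, concentration, dose)
    return max(s, 0.0)


# -- presets calibrated to the screening regime -----------------------------
# Spheroid clonogenic survival solves the LQ curve through SF = 0.361 at
# 4 Gy and 0.0813 at 6 Gy; total-cell-kill read-outs are far less radiation
# sensitive (SI 0.931 spheroid / 0.743 monolayer at 6 Gy), captured as pure
# exponential (beta = 0) declines through those single points.

SPHEROID_CLONOGENIC_LQ = LQParams.from_survival_points(4.0, 0.361, 6.0, 0.0813)
SPHEROID_TOTAL_KILL_LQ = LQParams(alpha=-math.log(0.931) / 6.0, beta=0.0)
MONOLAYER_TOTAL_KILL_LQ = LQParams(alpha=-math.log(0.743) / 6.0, beta=0.0)
# monolayer clonogenic: SF 0.10 at 4 Gy with a conventional alpha/beta of 10
MONOLAYER_CLONOGENIC_LQ = LQParams(
    alpha=-math.log(0.10) / (4.0 + 1.6), beta=-math.log(0.10) / (4.0 + 1.6) / 10.0
)

# An invented three-archetype panel: a drug spheroids resist almost
# completely, a potent drug whose top concentrations fall below the 25%
# drug-only survival filter, and a partial-kill drug active at all tested
# concentrations.
DEFAULT_DRUGS: dict[str, HillParams] = {
    "resistant_drug": HillParams(ec50=5000.0, hill_slope=1.0, floor=0.0),
    "potent_drug": HillParams(ec50=2.0, hill_slope=1.5, floor=0.02),
    "partial_kill_drug": HillParams(ec50=1.0, hill_slope=1.0, floor=0.50),
}


def default_config(
    assay: Assay | str = Assay.FMCA,
    culture: Culture | str = Culture.SPHEROID,
    **overrides,
) -> SimulationConfig:
    """A config with the radiation model preset for the assay/culture pair
    and the default drug panel; keyword overrides replace any field."""
    assay = Assay(assay)
    culture = Culture(culture)
    if assay is Assay.CLONOGENIC:
        lq = SPHEROID_CLONOGENIC_LQ if culture is Culture.SPHEROID else MONOLAYER_CLONOGENIC_LQ
    else:
        lq = SPHEROID_TOTAL_KILL_LQ if culture is Culture.SPHEROID else MONOLAYER_TOTAL_KILL_LQ
    base = SimulationConfig(assay=assay, culture=culture, radiation=lq)
    return replace(base, **overrides) if overrides else base


def config_from_dict(data: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (JSON/YAML) mapping.

    Recognized keys mirror the dataclass fields; ``drugs`` maps name ->
    {ec50, hill_slope, floor}, ``radiation`` is {alpha, beta} or
    {points: [[d1, s1], [d2, s2]]}, ``interaction`` a number or a
    drug -> rho mapping. Unspecified fields take the assay/culture preset.
    """
    data = dict(data)
    assay = data.pop("assay", "fmca")
    culture = data.pop("culture", "spheroid")
    overrides: dict = {}
    if "drugs" in data:
        overrides["drugs"] = {
            name: HillParams(**params) for name, params in data.pop("drugs").items()
        }
    if "radiation" in data:
        rad = data.pop("radiation")
        if "points" in rad:
            (d1, s1), (d2, s2) = rad["points"]
            overrides["radiation"] = LQParams.from_survival_points(d1, s1, d2, s2)
        else:
            overrides["radiation"] = LQParams(**rad)
    if "design" in data:
        design = dict(data.pop("design"))
        for key in ("concentrations", "doses"):
            if key in design:
                design[key] = tuple(float(x) for x in design[key])
        overrides["design"] = DesignParams(**design)
    if "noise" in data:
        overrides["noise"] = NoiseParams(**data.pop("noise"))
    for key in ("interaction", "seed"):
        if key in data:
            overrides[key] = data.pop(key)
    if data:
        raise ValueError(f"unknown simulation config keys: {sorted(data)}")
    return default_config(assay, culture, **overrides)


# -- screen generation ------------------------------------------------------


def _log_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0


def _well_name(index: int) -> str:
    # 384-well coordinates A01..P24, reused cyclically
    index %= 384
    return f"{chr(ord('A') + index // 24)}{index % 24 + 1:02d}"


class _WellCounter:
    def __init__(self) -> None:
        self.i = 0

    def next(self) -> str:
        name = _well_name(self.i)
        self.i += 1
        return name


def _conditions(config: SimulationConfig) -> list[tuple[Role, Condition]]:
    out: list[tuple[Role, Condition]] = []
    for drug in sorted(config.drugs):
        for c in config.design.concentrations:
            out.append((Role.DRUG_ONLY, Condition(drug, float(c), 0.0)))
    for d in config.design.doses:
        out.append((Role.RADIATION_ONLY, Condition("", 0.0, float(d))))
    for drug in sorted(config.drugs):
        for c in config.design.concentrations:
            for d in config.design.doses:
                out.append((Role.COMBINATION, Condition(drug, float(c), float(d))))
    return out


def simulate_screen(
    config: SimulationConfig, seed: int | None = None
) -> ExperimentSet:
    """Generate one full screen as a validated :class:`ExperimentSet`.

    Deterministic for a given config and seed (``seed`` overrides
    ``config.seed``). Fluorescent wells emit
    ``control_signal * S * exp(eps_exp) * exp(eps_well) + blank_level``;
    blanks emit ``blank_level * exp(eps_well)`` (no experiment factor — the
    blank is instrument background, not biology). Spheroid GFP wells emit a
    pre-drug baseline read (timepoint 0 h) and an endpoint read (168 h) for
    the same well. Clonogenic wells emit Poisson colony counts with mean
    ``plating_cells * S`` and no blanks.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sigma_w = _log_sigma(config.noise.well_cv)
    sigma_e = _log_sigma(config.noise.experiment_cv)
    gfp_spheroid = config.assay is Assay.GFP and config.culture is Culture.SPHEROID
    clonogenic = config.assay is Assay.CLONOGENIC
    conditions = _conditions(config)

    def well_factor() -> float:
        return math.exp(rng.normal(0.0, sigma_w)) if sigma_w > 0 else 1.0

    records: list[WellRecord] = []
    for e in range(config.design.n_experiments):
        eid = f"E{e + 1}"
        plate = f"{eid}-P1"
        counter = _WellCounter()
        exp_factor = math.exp(rng.normal(0.0, sigma_e)) if sigma_e > 0 else 1.0

        def emit(role: Role, cond: Condition, s_true: float) -> None:
            well = counter.next()
            if clonogenic:
                mean_count = config.design.plating_cells * s_true
                signal = float(rng.poisson(mean_count))
                records.append(
                    WellRecord(eid, plate, well, role, cond.drug, cond.concentration,
                               cond.dose, config.assay, signal)
                )
            elif gfp_spheroid:
                baseline = config.noise.control_signal * exp_factor * well_factor()
                endpoint = baseline * config.noise.spheroid_growth * s_true * well_factor()
                for tp, sig in ((0.0, baseline), (168.0, endpoint)):
                    records.append(
                        WellRecord(eid, plate, well, role, cond.drug, cond.concentration,
                                   cond.dose, config.assay, sig, timepoint_h=tp)
                    )
            else:
                sig = (
                    config.noise.control_signal * s_true * exp_factor * well_factor()
                    + config.noise.blank_level
                )
                records.append(
                    WellRecord(eid, plate, well, role, cond.drug, cond.concentration,
                               cond.dose, config.assay, sig)
                )

        if not clonogenic and not gfp_spheroid:
            for _ in range(config.design.blanks_per_plate):
                records.append(
                    WellRecord(eid, plate, counter.next(), Role.BLANK, "", 0.0, 0.0,
                               config.assay, config.noise.blank_level * well_factor())
                )
        for _ in range(config.design.controls_per_plate):
            emit(Role.CONTROL, Condition("", 0.0, 0.0), 1.0)
        for role, cond in conditions:
            s_true = config.survival(cond)
            for _ in range(config.design.wells_per_condition):
                emit(role, cond, s_true)

    return ExperimentSet.from_records(config.assay, config.culture, records)
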