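"""Survival read-outs: FMCA survival index, GFP AUTO SI, clonogenic SF.

Three normalizations, one per assay:

* **FMCA SI** — blank-corrected fluorescence of treated wells relative to
  blank-corrected untreated controls on the same plate.
* **AUTO SI** (spheroid GFP) — endpoint spheroid fluorescence relative to the
  *same well* immediately before drug addition. Self-normalized; there is no
  control-well term, so an untreated growing spheroid legitimately scores > 1.
* **Clonogenic SF** — colonies under treatment relative to untreated controls,
  without a plating-efficiency correction.

Duplicate wells are averaged at the raw-signal level within an experiment
before normalization; blanks and controls are pooled per experiment. Each
(experiment, condition) yields exactly one :class:`ViabilityValue`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .plate_io import Assay, Condition, Culture, ExperimentSet, PlateAssemblyError, Role

__all__ = [
    "Readout",
    "ViabilityValue",
    "DegeneratePlateError",
    "InvalidWellError",
    "compute_si_fmca",
    "compute_auto_si",
    "compute_sf",
    "summarize_conditions",
    "viability_frame",
    "interpolate_half_effect",
]


class Readout(str, enum.Enum):
    SI_FMCA = "SI_fmca"
    SI_GFP_MONOLAYER = "SI_gfp_monolayer"
    AUTO_SI_GFP_SPHEROID = "AUTO_SI_gfp_spheroid"
    SF_CLONOGENIC = "SF_clonogenic"


class DegeneratePlateError(ValueError):
    """The experiment's normalization baseline is unusable (control signal at
    or below blank, or zero control colonies): a failed experiment, not a
    zero-survival result."""


class InvalidWellError(ValueError):
    """A single well cannot be normalized (e.g. nonpositive day-0 signal)."""


@dataclass(frozen=True)
class ViabilityValue:
    """One normalized survival value for one condition within one experiment.

    ``value`` is a fraction in [0, inf); values above 1 are legal (treated
    wells can out-grow controls). Display as percent is a rendering concern.
    """

    condition: Condition
    experiment_id: str
    value: float
    n_wells: int
    readout: Readout

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"survival value must be >= 0, got {self.value}")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")


def compute_si_fmca(
    treated_signals: Sequence[float],
    control_signals: Sequence[float],
    blank_signals: Sequence[float],
) -> float:
    """Blank-corrected survival index.

    SI = (mean(treated) - mean(blank)) / (mean(control) - mean(blank)),
    with a negative blank-corrected numerator clipped to 0: low-viability
    wells routinely read below blank plus noise and mean dead, not
    "negative survival". Invariant under common rescaling of all signals.
    """
    if len(control_signals) == 0 or len(blank_signals) == 0:
        raise ValueError("control and blank signal lists must be non-empty")
    m_treated = float(np.mean(treated_signals))
    m_control = float(np.mean(control_signals))
    m_blank = float(np.mean(blank_signals))
    if m_control <= m_blank:
        raise DegeneratePlateError(
            f"mean control signal ({m_control:g}) <= mean blank ({m_blank:g}): "
            "failed experiment"
        )
    return max(m_treated - m_blank, 0.0) / (m_control - m_blank)


def compute_auto_si(signal_day7: float, signal_day0_same_well: float) -> float:
    """Per-well self-normalized survival index: endpoint / pre-drug signal.

    No control-well term by construction; growth of an untreated spheroid
    gives a value above 1.
    """
    if signal_day0_same_well <= 0:
        raise InvalidWellError(
            f"day-0 signal must be > 0, got {signal_day0_same_well}"
        )
    return signal_day7 / signal_day0_same_well


def compute_sf(
    treated_colonies: Sequence[float],
    control_colonies: Sequence[float],
) -> float:
    """Clonogenic survival fraction: mean treated colonies / mean control
    colonies, with no plating-efficiency correction."""
    if len(control_colonies) == 0:
        raise ValueError("control colony list must be non-empty")
    m_control = float(np.mean(control_colonies))
    if m_control <= 0:
        raise DegeneratePlateError("mean control colony count is 0: failed experiment")
    return float(np.mean(treated_colonies)) / m_control


def _readout_for(assay: Assay, culture: Culture) -> Readout:
    if assay is Assay.FMCA:
        return Readout.SI_FMCA
    if assay is Assay.CLONOGENIC:
        return Readout.SF_CLONOGENIC
    if culture is Culture.SPHEROID:
        return Readout.AUTO_SI_GFP_SPHEROID
    return Readout.SI_GFP_MONOLAYER


def _mean_signal(wells) -> float:
    return float(np.mean([w.signal for w in wells]))


def _auto_si_for_wells(wells, experiment_id: str) -> tuple[float, int]:
    """Mean per-well AUTO SI over duplicate wells of one condition.

    Wells are paired by well coordinate; the first timepoint is the pre-drug
    baseline and the last is the endpoint. Intermediate kinetic reads are
    retained in the record but not analyzed.
    """
    by_well: dict[str, list] = {}
    for w in wells:
        by_well.setdefault(w.well, []).append(w)
    ratios = []
    for well_id, reads in by_well.items():
        if len(reads) < 2 or any(r.timepoint_h is None for r in reads):
            raise InvalidWellError(
                f"experiment {experiment_id!r} well {well_id!r}: AUTO SI needs "
                "timepointed day-0 and endpoint reads for the same well"
            )
        reads = sorted(reads, key=lambda r: r.timepoint_h)
        try:
            ratios.append(compute_auto_si(reads[-1].signal, reads[0].signal))
        except InvalidWellError as exc:
            raise InvalidWellError(f"experiment {experiment_id!r} well {well_id!r}: {exc}")
    return float(np.mean(ratios)), len(ratios)


def summarize_conditions(
    experiments: ExperimentSet,
    auto_si_relative_to_control: bool = False,
) -> list[ViabilityValue]:
    """Apply the assay's normalization per (experiment, condition).

    Duplicate wells are averaged at the signal level first; controls and
    blanks are pooled within each experiment. Degenerate-plate errors are
    re-raised tagged with the experiment id.

    ``auto_si_relative_to_control`` re-expresses spheroid GFP AUTO SI
    relative to the same experiment's mean control AUTO SI. This is a
    *derived* quantity (the native AUTO SI definition has no control term);
    it is what interaction scoring should consume, because untreated growth
    otherwise enters every arm of the Bliss ratio once and does not cancel.
    """
    readout = _readout_for(experiments.assay, experiments.culture)
    values: list[ViabilityValue] = []
    for eid in experiments.experiment_ids():
        controls = experiments.control_wells(eid)
        blanks = experiments.blank_wells(eid)
        if not controls:
            raise PlateAssemblyError(f"experiment {eid!r} has no control wells")
        treatment = experiments.treatment_wells(eid)

        if readout is Readout.SI_FMCA or readout is Readout.SI_GFP_MONOLAYER:
            if readout is Readout.SI_FMCA and not blanks:
                raise PlateAssemblyError(f"experiment {eid!r} has no blank wells (FMCA)")
            # GFP monolayer: blank subtraction only when blank wells exist
            blank_signals = [w.signal for w in blanks] if blanks else [0.0]
            control_signals = [w.signal for w in controls]
            for cond, wells in treatment.items():
                try:
                    si = compute_si_fmca([_mean_signal(wells)], control_signals, blank_signals)
                except DegeneratePlateError as exc:
                    raise DegeneratePlateError(f"experiment {eid!r}: {exc}")
                values.append(ViabilityValue(cond, eid, si, len(wells), readout))

        elif readout is Readout.AUTO_SI_GFP_SPHEROID:
            denom = 1.0
            if auto_si_relative_to_control:
                denom, _ = _auto_si_for_wells(controls, eid)
            for cond, wells in treatment.items():
                auto_si, n = _auto_si_for_wells(wells, eid)
                values.append(ViabilityValue(cond, eid, auto_si / denom, n, readout))

        else:  # clonogenic
            control_counts = [w.signal for w in controls]
            for cond, wells in treatment.items():
                try:
                    sf = compute_sf([_mean_signal(wells)], control_counts)
                except DegeneratePlateError as exc:
                    raise DegeneratePlateError(f"experiment {eid!r}: {exc}")
                values.append(ViabilityValue(cond, eid, sf, len(wells), readout))
    return values


def viability_frame(values: Iterable[ViabilityValue]) -> pd.DataFrame:
    """Tidy frame of viability values (one row per experiment x condition)."""
    rows = sorted(values, key=lambda v: (v.condition.sort_key(), v.experiment_id))
    return pd.DataFrame(
        {
            "experiment_id": [v.experiment_id for v in rows],
            "drug": [v.condition.drug for v in rows],
            "concentration_uM": [v.condition.concentration for v in rows],
            "dose_Gy": [v.condition.dose for v in rows],
            "readout": [v.readout.value for v in rows],
            "value": [v.value for v in rows],
            "n_wells": [v.n_wells for v in rows],
        }
    )


def interpolate_half_effect(
    concentrations: Sequence[float],
    values: Sequence[float],
    level: float = 0.5,
) -> float | None:
    """Log-linear interpolation of the concentration where survival crosses
    ``level``. Plumbing only — not a curve fit. Returns None when the series
    never brackets the level.
    """
    pairs = sorted(zip(concentrations, values))
    for (c_lo, v_lo), (c_hi, v_hi) in zip(pairs, pairs[1:]):
        if not (min(v_lo, v_hi) <= level <= max(v_lo, v_hi)):
            continue
        if c_lo <= 0 or c_hi <= 0 or v_lo == v_hi:
            continue
        t = (level - v_lo) / (v_hi - v_lo)
        return float(10 ** (math.log10(c_lo) + t * (math.log10(c_hi) - math.log10(c_lo))))
    return None
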