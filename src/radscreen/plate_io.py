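"""Well-level data model and long-format CSV I/O for plate-based screens.

One row per well, in a tidy single-table schema::

    experiment_id,plate_id,well,role,drug,concentration_uM,dose_Gy,assay,signal,timepoint_h

Plate geometry (the ``well`` coordinate) is carried as metadata only; no
analysis step depends on spatial position. Viability and survival values are
stored internally as fractions; rendering to percent happens in one display
layer only.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from functools import total_ordering
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Role",
    "Assay",
    "Culture",
    "Condition",
    "WellRecord",
    "ExperimentSet",
    "PlateSchemaError",
    "PlateValidationError",
    "PlateAssemblyError",
    "CSV_COLUMNS",
    "read_well_table",
    "write_well_table",
]

CSV_COLUMNS = (
    "experiment_id",
    "plate_id",
    "well",
    "role",
    "drug",
    "concentration_uM",
    "dose_Gy",
    "assay",
    "signal",
    "timepoint_h",
)


class Role(str, enum.Enum):
    """What a well contributes to the analysis."""

    BLANK = "blank"
    CONTROL = "control"
    DRUG_ONLY = "drug_only"
    RADIATION_ONLY = "radiation_only"
    COMBINATION = "combination"


class Assay(str, enum.Enum):
    FMCA = "fmca"
    GFP = "gfp"
    CLONOGENIC = "clonogenic"


class Culture(str, enum.Enum):
    SPHEROID = "spheroid"
    MONOLAYER = "monolayer"


class PlateSchemaError(ValueError):
    """The file does not match the documented long-format schema."""


class PlateValidationError(ValueError):
    """One or more rows violate a well-record invariant.

    The message lists the offending row numbers (1-based, counting the
    header as row 1, as a spreadsheet user would read them).
    """


class PlateAssemblyError(ValueError):
    """Rows are individually valid but do not assemble into experiments
    (e.g. an experiment without untreated control wells)."""


@total_ordering
@dataclass(frozen=True)
class Condition:
    """A (drug, concentration, dose) triple keying one treatment arm.

    Total order: by drug name, then *descending* concentration (tables run
    highest to lowest concentration), then ascending dose.
    """

    drug: str
    concentration: float  # µM
    dose: float  # Gy

    def sort_key(self) -> tuple:
        return (self.drug, -self.concentration, self.dose)

    def __lt__(self, other: "Condition") -> bool:
        if not isinstance(other, Condition):
            return NotImplemented
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        parts = []
        if self.drug:
            parts.append(f"{self.drug} {self.concentration:g} µM")
        if self.dose:
            parts.append(f"{self.dose:g} Gy")
        return " + ".join(parts) or "untreated"


# condition shared by blanks and untreated controls
UNTREATED = Condition(drug="", concentration=0.0, dose=0.0)


@dataclass(frozen=True)
class WellRecord:
    """One well's raw measurement plus its full experimental condition."""

    experiment_id: str
    plate_id: str
    well: str
    role: Role
    drug: str
    concentration: float  # µM
    dose: float  # Gy
    assay: Assay
    signal: float  # AU fluorescence, or colony count for clonogenic
    timepoint_h: float | None = None  # hours since drug addition (GFP kinetics)

    @property
    def condition(self) -> Condition:
        return Condition(self.drug, self.concentration, self.dose)

    def problems(self) -> list[str]:
        """Return invariant violations for this record (empty when valid)."""
        out: list[str] = []
        if self.concentration < 0:
            out.append(f"negative concentration {self.concentration}")
        if self.dose < 0:
            out.append(f"negative dose {self.dose}")
        if self.signal < 0:
            out.append(f"negative signal {self.signal}")
        if self.role in (Role.BLANK, Role.CONTROL):
            if self.concentration != 0 or self.dose != 0:
                out.append(f"{self.role.value} well must have concentration=0 and dose=0")
        elif self.role is Role.DRUG_ONLY:
            if not (self.concentration > 0 and self.dose == 0):
                out.append("drug_only well must have concentration>0 and dose=0")
        elif self.role is Role.RADIATION_ONLY:
            if not (self.concentration == 0 and self.dose > 0):
                out.append("radiation_only well must have concentration=0 and dose>0")
        elif self.role is Role.COMBINATION:
            if not (self.concentration > 0 and self.dose > 0):
                out.append("combination well must have concentration>0 and dose>0")
        if self.assay is Assay.CLONOGENIC and self.signal >= 0:
            if float(self.signal) != int(self.signal):
                out.append(f"clonogenic signal must be an integer colony count, got {self.signal}")
        if self.role is Role.DRUG_ONLY or self.role is Role.COMBINATION:
            if not self.drug:
                out.append(f"{self.role.value} well must name a drug")
        return out


@dataclass
class ExperimentSet:
    """All wells of one assay/culture, grouped by independent experiment.

    ``experiments`` maps experiment_id to that experiment's well records.
    Helper accessors expose the blank/control pools and the
    condition-indexed treatment wells the downstream stages operate on.
    """

    assay: Assay
    culture: Culture
    experiments: dict[str, list[WellRecord]] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        assay: Assay,
        culture: Culture,
        records: Iterable[WellRecord],
        validate: bool = True,
    ) -> "ExperimentSet":
        experiments: dict[str, list[WellRecord]] = {}
        for rec in records:
            experiments.setdefault(rec.experiment_id, []).append(rec)
        obj = cls(assay=assay, culture=culture, experiments=experiments)
        if validate:
            obj.validate()
        return obj

    def validate(self) -> None:
        """Check record invariants and per-experiment assembly rules."""
        bad: list[str] = []
        for eid, wells in self.experiments.items():
            for rec in wells:
                if rec.assay is not self.assay:
                    bad.append(f"{eid}/{rec.well}: assay {rec.assay.value} != set assay {self.assay.value}")
                bad.extend(f"{eid}/{rec.well}: {p}" for p in rec.problems())
        if bad:
            raise PlateValidationError("invalid well records:\n  " + "\n  ".join(bad))
        for eid in self.experiments:
            if not self.control_wells(eid):
                raise PlateAssemblyError(f"experiment {eid!r} has no untreated control wells")
            if self.assay is Assay.FMCA and not self.blank_wells(eid):
                raise PlateAssemblyError(f"experiment {eid!r} has no blank wells (required for FMCA)")
            for cond, wells in self.treatment_wells(eid).items():
                if not wells:
                    raise PlateAssemblyError(f"experiment {eid!r}: condition {cond} has no wells")

    # -- accessors ---------------------------------------------------------

    def experiment_ids(self) -> list[str]:
        return sorted(self.experiments)

    def wells(self, experiment_id: str) -> list[WellRecord]:
        return self.experiments[experiment_id]

    def blank_wells(self, experiment_id: str) -> list[WellRecord]:
        return [w for w in self.experiments[experiment_id] if w.role is Role.BLANK]

    def control_wells(self, experiment_id: str) -> list[WellRecord]:
        return [w for w in self.experiments[experiment_id] if w.role is Role.CONTROL]

    def treatment_wells(self, experiment_id: str) -> dict[Condition, list[WellRecord]]:
        """Condition-indexed drug_only / radiation_only / combination wells,
        in the canonical condition order."""
        grouped: dict[Condition, list[WellRecord]] = {}
        for w in self.experiments[experiment_id]:
            if w.role in (Role.DRUG_ONLY, Role.RADIATION_ONLY, Role.COMBINATION):
                grouped.setdefault(w.condition, []).append(w)
        return dict(sorted(grouped.items()))

    def conditions(self) -> list[Condition]:
        """All distinct treatment conditions across experiments, sorted."""
        seen: set[Condition] = set()
        for eid in self.experiments:
            seen.update(self.treatment_wells(eid))
        return sorted(seen)

    def n_wells(self) -> int:
        return sum(len(v) for v in self.experiments.values())

    # -- frame conversion --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Deterministically ordered tidy frame in the documented schema."""
        role_order = {r: i for i, r in enumerate(Role)}
        rows = []
        for eid in self.experiment_ids():
            for rec in self.experiments[eid]:
                rows.append(rec)
        rows.sort(
            key=lambda r: (
                r.experiment_id,
                r.plate_id,
                role_order[r.role],
                r.condition.sort_key(),
                r.well,
                -1.0 if r.timepoint_h is None else r.timepoint_h,
            )
        )
        if self.assay is Assay.CLONOGENIC:
            signals: list = [int(r.signal) for r in rows]
        else:
            signals = [float(r.signal) for r in rows]
        return pd.DataFrame(
            {
                "experiment_id": [r.experiment_id for r in rows],
                "plate_id": [r.plate_id for r in rows],
                "well": [r.well for r in rows],
                "role": [r.role.value for r in rows],
                "drug": [r.drug for r in rows],
                "concentration_uM": [float(r.concentration) for r in rows],
                "dose_Gy": [float(r.dose) for r in rows],
                "assay": [r.assay.value for r in rows],
                "signal": signals,
                "timepoint_h": [r.timepoint_h for r in rows],
            }
        )


def _parse_enum(kind, raw: str, row: int, errors: list[str]):
    try:
        return kind(raw)
    except ValueError:
        allowed = ", ".join(m.value for m in kind)
        errors.append(f"row {row}: {kind.__name__.lower()} {raw!r} not one of {allowed}")
        return None


def read_well_table(
    path: str | Path,
    culture: Culture | str = Culture.SPHEROID,
    sep: str = ",",
) -> ExperimentSet:
    """Read a long-format well table into a validated :class:`ExperimentSet`.

    The culture (spheroid vs monolayer) is not part of the file schema and
    must be supplied by the caller; it selects the GFP read-out convention
    downstream.

    Raises
    ------
    PlateSchemaError
        Missing required columns or mixed assays in one file.
    PlateValidationError
        Rows violating well invariants; the message lists row numbers.
    PlateAssemblyError
        Experiments lacking control (or, for FMCA, blank) wells.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise PlateSchemaError(f"{path}: missing required columns: {', '.join(missing)}")

    errors: list[str] = []
    records: list[WellRecord] = []
    assays: set[Assay] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # header is row 1
        role = _parse_enum(Role, row.role, rownum, errors)
        assay = _parse_enum(Assay, row.assay, rownum, errors)
        if role is None or assay is None:
            continue
        try:
            conc = float(row.concentration_uM) if row.concentration_uM != "" else 0.0
            dose = float(row.dose_Gy) if row.dose_Gy != "" else 0.0
            signal = float(row.signal)
            tp = float(row.timepoint_h) if row.timepoint_h != "" else None
        except ValueError as exc:
            errors.append(f"row {rownum}: non-numeric field ({exc})")
            continue
        rec = WellRecord(
            experiment_id=row.experiment_id,
            plate_id=row.plate_id,
            well=row.well,
            role=role,
            drug=row.drug,
            concentration=conc,
            dose=dose,
            assay=assay,
            signal=signal,
            timepoint_h=tp,
        )
        problems = rec.problems()
        if problems:
            errors.extend(f"row {rownum}: {p}" for p in problems)
            continue
        assays.add(assay)
        records.append(rec)
    if errors:
        raise PlateValidationError("invalid rows in " + str(path) + ":\n  " + "\n  ".join(errors))
    if len(assays) > 1:
        raise PlateSchemaError(
            f"{path}: mixed assays in one table: {sorted(a.value for a in assays)}"
        )
    assay = assays.pop() if assays else Assay.FMCA
    culture = Culture(culture)
    return ExperimentSet.from_records(assay, culture, records)


def write_well_table(experiment_set: ExperimentSet, path: str | Path) -> None:
    """Write the set as long-format CSV: fixed column order, UTF-8, '.' decimals.

    Row order is deterministic (experiment, plate, role, condition, well,
    timepoint), so identical data always produce byte-identical files.
    """
    df = experiment_set.to_frame()
    df.to_csv(Path(path), index=False, encoding="utf-8")
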