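"""Shared fixtures: programmatic construction of tiny experiment sets."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from radscreen.plate_io import Assay, Condition, Culture, ExperimentSet, Role, WellRecord

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def role_for(condition: Condition) -> Role:
    if condition.concentration > 0 and condition.dose > 0:
        return Role.COMBINATION
    if condition.concentration > 0:
        return Role.DRUG_ONLY
    if condition.dose > 0:
        return Role.RADIATION_ONLY
    return Role.CONTROL


def make_wells(
    experiment_id: str,
    assay: Assay,
    *,
    blanks: tuple[float, ...] = (),
    controls: tuple[float, ...] = (),
    treatments: dict[Condition, tuple[float, ...]] | None = None,
    plate: str | None = None,
) -> list[WellRecord]:
    """One experiment's well records from raw signal tuples."""
    plate = plate or f"{experiment_id}-P1"
    records: list[WellRecord] = []
    i = 0

    def well() -> str:
        nonlocal i
        i += 1
        return f"W{i:03d}"

    for s in blanks:
        records.append(
            WellRecord(experiment_id, plate, well(), Role.BLANK, "", 0.0, 0.0, assay, s)
        )
    for s in controls:
        records.append(
            WellRecord(experiment_id, plate, well(), Role.CONTROL, "", 0.0, 0.0, assay, s)
        )
    for cond, signals in (treatments or {}).items():
        for s in signals:
            records.append(
                WellRecord(
                    experiment_id, plate, well(), role_for(cond),
                    cond.drug, cond.concentration, cond.dose, assay, s,
                )
            )
    return records


@pytest.fixture
def fmca_set() -> ExperimentSet:
    """One FMCA experiment: blank 20, control 1620, a drug arm at half
    survival, a radiation arm, and an exactly Bliss-additive combination."""
    cond_d = Condition("drugX", 10.0, 0.0)
    cond_r = Condition("", 0.0, 6.0)
    cond_o = Condition("drugX", 10.0, 6.0)
    records = make_wells(
        "E1",
        Assay.FMCA,
        blanks=(20.0, 20.0),
        controls=(1600.0, 1640.0),
        treatments={
            cond_d: (800.0, 840.0),  # SI_d = 0.5
            cond_r: (1316.0,),  # SI_r = 0.81
            cond_o: (668.0,),  # SI_o = 0.405 = 0.5 * 0.81
        },
    )
    return ExperimentSet.from_records(Assay.FMCA, Culture.SPHEROID, records)
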