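"""Bliss-independence scoring of drug x radiation interaction.

Under Bliss independence two non-interacting treatments leave a combined
surviving fraction equal to the product of the single-treatment fractions:
``S_e = S_d * S_r``. For each experiment the observed combination survival is
divided by this expectation, giving one interaction ratio per experiment;
ratios below 1 indicate synergy (more kill than independence predicts), above
1 antagonism. Conditions whose drug-only survival does not exceed 25% are
excluded from tabular results: when the drug alone already kills almost
everything, the ratio is numerically unstable and uninformative.

Per condition, the ratios from the independent experiments are averaged and
tested against 1 with a one-sample t-test (two-tailed); no multiple-testing
correction is applied by default, matching the deliberately conservative
"deviation from additivity" reading of Bliss, though a Holm adjustment is
available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plate_io import Condition
from .viability import ViabilityValue

__all__ = [
    "InteractionRecord",
    "UndefinedRatioError",
    "InsufficientReplicatesError",
    "DegenerateVarianceError",
    "PairingError",
    "bliss_expected",
    "interaction_ratio",
    "apply_inclusion_filter",
    "one_sample_t_test",
    "holm_adjust",
    "score_interactions",
    "interaction_frame",
    "render_interaction_table",
]

DEFAULT_THRESHOLD = 0.25
DEFAULT_ALPHA = 0.05


class UndefinedRatioError(ValueError):
    """Expected combination survival is 0 (both single treatments fully
    lethal): the interaction ratio is meaningless."""


class InsufficientReplicatesError(ValueError):
    """A t-test needs at least two replicate values."""


class DegenerateVarianceError(ValueError):
    """All replicate values identical: the t statistic is undefined."""


class PairingError(ValueError):
    """A combination condition has no experiment carrying all three of
    drug-only, radiation-only and combination values."""


@dataclass(frozen=True)
class InteractionRecord:
    """Synergy result for one (drug, concentration, dose) condition.

    ``included`` reflects the drug-only survival filter; excluded conditions
    carry no ratios or statistics and render as "N/A". ``significant`` (the
    table asterisk) and ``synergistic_tendency`` (mean ratio < 1, the table's
    bold) are stored separately; a synergy *call* combines both and is left to
    the reporting layer.
    """

    drug: str
    concentration_rank: int  # 0 = highest concentration of this drug
    concentration: float  # µM
    dose: float  # Gy
    per_experiment_ratios: tuple[float, ...]
    mean_ratio: float | None
    t_statistic: float | None
    p_value: float | None
    n_experiments: int
    included: bool
    significant: bool
    synergistic_tendency: bool

    def __post_init__(self) -> None:
        if not self.included and (
            self.per_experiment_ratios or self.mean_ratio is not None or self.p_value is not None
        ):
            raise ValueError("excluded records must not carry ratios or statistics")


def bliss_expected(effect_drug: float, effect_radiation: float) -> float:
    """Expected combination survival under Bliss independence: the product
    of the single-treatment survival fractions."""
    if effect_drug < 0 or effect_radiation < 0:
        raise ValueError("survival fractions must be >= 0")
    return effect_drug * effect_radiation


def interaction_ratio(observed: float, expected: float) -> float:
    """Observed combination survival over the Bliss expectation."""
    if expected <= 0:
        raise UndefinedRatioError(
            "expected combination survival is 0; ratio undefined"
        )
    return observed / expected


def one_sample_t_test(
    values: Sequence[float], null_mean: float = 1.0
) -> tuple[float, float]:
    """One-sample t-test of mean(values) against ``null_mean``.

    t = (mean - null_mean) / (sd / sqrt(n)) with df = n - 1 and a two-tailed
    p from the t distribution.

    A sample standard deviation below 1e-12 relative to the data scale is
    treated as zero: replicate values identical up to floating rounding carry
    no evidence and must not yield a huge t statistic from rounding residue.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientReplicatesError(f"need >= 2 values, got {n}")
    sd = float(np.std(x, ddof=1))
    scale = max(float(np.max(np.abs(x))), abs(null_mean), 1.0)
    if sd <= 1e-12 * scale:
        raise DegenerateVarianceError("zero sample variance")
    t = (float(np.mean(x)) - null_mean) / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (optional; off by default in scoring)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def apply_inclusion_filter(
    viability: Iterable[ViabilityValue],
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[tuple[str, float], bool]:
    """Flag each (drug, concentration) by whether its mean drug-only survival
    across experiments is strictly above ``threshold``.

    The filter statistic is the across-experiment mean (tables gate whole
    rows); the boundary value itself is excluded.
    """
    sums: dict[tuple[str, float], list[float]] = {}
    for v in viability:
        c = v.condition
        if c.drug and c.concentration > 0 and c.dose == 0:
            sums.setdefault((c.drug, c.concentration), []).append(v.value)
    return {key: float(np.mean(vals)) > threshold for key, vals in sums.items()}


def _concentration_ranks(conditions: Iterable[Condition]) -> dict[tuple[str, float], int]:
    per_drug: dict[str, set[float]] = {}
    for c in conditions:
        per_drug.setdefault(c.drug, set()).add(c.concentration)
    ranks: dict[tuple[str, float], int] = {}
    for drug, concs in per_drug.items():
        for i, conc in enumerate(sorted(concs, reverse=True)):
            ranks[(drug, conc)] = i
    return ranks


def score_interactions(
    viability: Iterable[ViabilityValue],
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    log_ratios: bool = False,
    holm: bool = False,
) -> list[InteractionRecord]:
    """Score every combination condition against Bliss independence.

    For each (drug, concentration, dose) with dose > 0, the drug-only,
    radiation-only and combination survival values are paired *within the
    same experiment*; each experiment contributes one ratio
    observed / (drug_only * radiation_only), and the t-test runs on the
    n-experiment ratios with df = n - 1. Conditions failing the drug-only
    survival filter are emitted with ``included=False`` and no statistics.

    ``log_ratios`` tests log(ratio) against 0 instead (sensitivity analysis;
    the reported mean_ratio stays arithmetic). ``holm`` applies a Holm
    adjustment to the p-values of included conditions before flagging
    significance.
    """
    values = list(viability)
    by_key: dict[tuple[str, str, float, float], float] = {}
    combos: set[Condition] = set()
    for v in values:
        c = v.condition
        by_key[(v.experiment_id, c.drug, c.concentration, c.dose)] = v.value
        if c.drug and c.concentration > 0 and c.dose > 0:
            combos.add(c)
    included_map = apply_inclusion_filter(values, threshold)
    ranks = _concentration_ranks(combos)
    experiment_ids = sorted({v.experiment_id for v in values})

    records: list[InteractionRecord] = []
    pending_p: list[tuple[int, float]] = []  # (record index, p) for holm
    for cond in sorted(combos):
        rank = ranks[(cond.drug, cond.concentration)]
        if not included_map.get((cond.drug, cond.concentration), False):
            records.append(
                InteractionRecord(
                    drug=cond.drug,
                    concentration_rank=rank,
                    concentration=cond.concentration,
                    dose=cond.dose,
                    per_experiment_ratios=(),
                    mean_ratio=None,
                    t_statistic=None,
                    p_value=None,
                    n_experiments=0,
                    included=False,
                    significant=False,
                    synergistic_tendency=False,
                )
            )
            continue
        ratios: list[float] = []
        for eid in experiment_ids:
            d = by_key.get((eid, cond.drug, cond.concentration, 0.0))
            r = by_key.get((eid, "", 0.0, cond.dose))
            o = by_key.get((eid, cond.drug, cond.concentration, cond.dose))
            if d is None or r is None or o is None:
                continue
            ratios.append(interaction_ratio(o, bliss_expected(d, r)))
        if not ratios:
            raise PairingError(
                f"condition {cond}: no experiment carries drug-only, "
                "radiation-only and combination values together"
            )
        mean_ratio = float(np.mean(ratios))
        t_stat: float | None = None
        p_val: float | None = None
        if len(ratios) >= 2:
            try:
                if log_ratios:
                    t_stat, p_val = one_sample_t_test([math.log(x) for x in ratios], 0.0)
                else:
                    t_stat, p_val = one_sample_t_test(ratios, 1.0)
            except DegenerateVarianceError:
                pass  # identical replicate ratios: no test, not significant
        records.append(
            InteractionRecord(
                drug=cond.drug,
                concentration_rank=rank,
                concentration=cond.concentration,
                dose=cond.dose,
                per_experiment_ratios=tuple(ratios),
                mean_ratio=mean_ratio,
                t_statistic=t_stat,
                p_value=p_val,
                n_experiments=len(ratios),
                included=True,
                significant=False,  # set below, after optional Holm
                synergistic_tendency=mean_ratio < 1.0,
            )
        )
        if p_val is not None:
            pending_p.append((len(records) - 1, p_val))

    if holm and pending_p:
        adjusted = holm_adjust([p for _, p in pending_p])
        effective = dict(zip((i for i, _ in pending_p), adjusted))
    else:
        effective = dict(pending_p)
    for idx, p in effective.items():
        if p < alpha:
            records[idx] = replace(records[idx], significant=True)
    return records


def interaction_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    """Machine-readable twin of the rendered table: one row per condition."""
    rows = sorted(records, key=lambda r: (r.drug, r.dose, r.concentration_rank))
    return pd.DataFrame(
        {
            "drug": [r.drug for r in rows],
            "dose_Gy": [r.dose for r in rows],
            "concentration_rank": [r.concentration_rank for r in rows],
            "concentration_uM": [r.concentration for r in rows],
            "n_experiments": [r.n_experiments for r in rows],
            "mean_ratio": [r.mean_ratio for r in rows],
            "t_statistic": [r.t_statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "included": [r.included for r in rows],
            "significant": [r.significant for r in rows],
            "synergistic_tendency": [r.synergistic_tendency for r in rows],
        }
    )


def format_cell(record: InteractionRecord) -> str:
    """One table cell: ratio to 2 decimals, '*' when significant, bold
    (markdown) when the mean ratio is below 1, 'N/A' when excluded."""
    if not record.included:
        return "N/A"
    assert record.mean_ratio is not None
    text = f"{record.mean_ratio:.2f}"
    if record.significant:
        text += "*"
    if record.synergistic_tendency:
        text = f"**{text}**"
    return text


def render_interaction_table(
    records: Iterable[InteractionRecord],
    dose: float | None = None,
) -> str:
    """Publication-style text table: one column per drug (per drug x dose when
    several doses are present), rows from highest to lowest concentration.

    ``dose`` restricts the table to a single radiation dose. Returns the
    table as a plain-text string (tab-separated cells); a machine-readable
    CSV twin comes from :func:`interaction_frame`.
    """
    recs = [r for r in records if dose is None or r.dose == dose]
    if not recs:
        return "ratio\n"
    doses = sorted({r.dose for r in recs})
    multi_dose = len(doses) > 1

    def column(r: InteractionRecord) -> str:
        return f"{r.drug} + {r.dose:g} Gy" if multi_dose else r.drug

    columns: list[str] = []
    cells: dict[tuple[int, str], str] = {}
    max_rank = 0
    for r in sorted(recs, key=lambda r: (r.drug, r.dose, r.concentration_rank)):
        col = column(r)
        if col not in columns:
            columns.append(col)
        cells[(r.concentration_rank, col)] = format_cell(r)
        max_rank = max(max_rank, r.concentration_rank)

    header = ["ratio"] + columns
    lines = ["\t".join(header)]
    for rank in range(max_rank + 1):
        if rank == 0:
            label = "Highest conc."
        elif rank == max_rank:
            label = "Lowest conc."
        else:
            label = ""
        row = [label] + [cells.get((rank, col), "-") for col in columns]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
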