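"""End-to-end pipeline: well table -> viability -> interaction tables.

Outputs per run: a per-experiment viability CSV, an interaction-record CSV,
one rendered text table per radiation dose (plus its CSV twin), optional
dose-response figures, and a run log recording the thresholds, seeds and
versions so that every "N/A" and "*" in the tables is auditable.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .plate_io import Assay, Culture, ExperimentSet, read_well_table, write_well_table
from .simulate import SimulationConfig, simulate_screen
from .synergy import (
    DEFAULT_ALPHA,
    DEFAULT_THRESHOLD,
    interaction_frame,
    render_interaction_table,
    score_interactions,
)
from .viability import Readout, ViabilityValue, summarize_conditions, viability_frame

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "plot_dose_response"]

log = logging.getLogger("radscreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Either ``input_path`` (a well-table CSV) or ``simulation`` (self-test
    mode: generate the screen, then analyze it) must be provided.
    """

    input_path: Path | None = None
    culture: Culture | str = Culture.SPHEROID
    threshold: float = DEFAULT_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    output_dir: Path = Path("radscreen_out")
    log_level: str = "INFO"
    make_plots: bool = True
    simulation: SimulationConfig | None = None
    seed: int | None = None  # simulation seed override (self-test mode)

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.input_path is None and self.simulation is None:
            raise ValueError("either input_path or simulation must be set")


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run read/simulate -> viability -> synergy -> tables; return the map of
    output names to written paths. Any stage error raises
    :class:`PipelineError` naming the stage."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    outputs: dict[str, Path] = {}
    if config.simulation is not None:
        experiment_set = _stage("simulate")(
            simulate_screen, config.simulation, config.seed
        )
        sim_path = outdir / "simulated_wells.csv"
        write_well_table(experiment_set, sim_path)
        outputs["simulated_wells"] = sim_path
    else:
        assert config.input_path is not None
        experiment_set = _stage("read")(
            read_well_table, config.input_path, Culture(config.culture)
        )

    normalize = (
        experiment_set.assay is Assay.GFP
        and experiment_set.culture is Culture.SPHEROID
    )
    values = _stage("viability")(
        summarize_conditions, experiment_set, auto_si_relative_to_control=normalize
    )
    viab_path = outdir / "viability.csv"
    viability_frame(values).to_csv(viab_path, index=False)
    outputs["viability"] = viab_path

    records = _stage("synergy")(
        score_interactions, values, threshold=config.threshold, alpha=config.alpha
    )
    inter_path = outdir / "interactions.csv"
    interaction_frame(records).to_csv(inter_path, index=False)
    outputs["interactions"] = inter_path

    for dose in sorted({r.dose for r in records}):
        text = render_interaction_table(records, dose=dose)
        table_path = outdir / f"interaction_table_{dose:g}Gy.txt"
        table_path.write_text(text, encoding="utf-8")
        outputs[f"table_{dose:g}Gy"] = table_path
        csv_path = outdir / f"interaction_table_{dose:g}Gy.csv"
        interaction_frame([r for r in records if r.dose == dose]).to_csv(
            csv_path, index=False
        )
        outputs[f"table_{dose:g}Gy_csv"] = csv_path

    if config.make_plots:
        figures = _stage("plots")(plot_dose_response, values, outdir)
        for i, p in enumerate(figures):
            outputs[f"figure_{i}"] = p

    log_path = outdir / "run_log.txt"
    lines = [
        f"radscreen {__version__}",
        f"python {sys.version.split()[0]}",
        f"assay: {experiment_set.assay.value}",
        f"culture: {experiment_set.culture.value}",
        f"inclusion threshold (drug-only survival): {config.threshold}",
        f"alpha (two-tailed): {config.alpha}",
        f"auto_si_relative_to_control: {normalize}",
        f"n_experiments: {len(experiment_set.experiment_ids())}",
        f"n_wells: {experiment_set.n_wells()}",
    ]
    if config.simulation is not None:
        seed = config.simulation.seed if config.seed is None else config.seed
        lines.append(f"simulation seed: {seed}")
    log_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    outputs["run_log"] = log_path
    return outputs


def plot_dose_response(
    values: Iterable[ViabilityValue],
    output_dir: Path,
    prefix: str = "dose_response",
) -> list[Path]:
    """Per-drug concentration-response figures, one curve per radiation arm
    (0 Gy = drug only), mean +/- SEM across independent experiments, log
    concentration axis. SEM bars are omitted for single-experiment arms.
    Returns the written paths (empty, with a warning, for empty input)."""
    values = list(values)
    if not values:
        log.warning("plot_dose_response: no viability values, no figure written")
        return []
    df = viability_frame(values)
    df = df[df["drug"] != ""]
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for drug, sub in df.groupby("drug"):
        fig, ax = plt.subplots(figsize=(5, 4))
        for dose, arm in sub.groupby("dose_Gy"):
            g = arm.groupby("concentration_uM")["value"]
            mean = g.mean()
            sem = g.sem()
            n = g.count()
            label = "drug only" if dose == 0 else f"+ {dose:g} Gy"
            x = mean.index.to_numpy()
            y = 100.0 * mean.to_numpy()
            err = 100.0 * sem.to_numpy()
            if (n > 1).all():
                ax.errorbar(x, y, yerr=err, marker="o", capsize=3, label=label)
            else:
                ax.plot(x, y, marker="o", label=label)
        ax.set_xscale("log")
        ax.set_xlabel("concentration (µM)")
        ax.set_ylabel("survival (% of control)")
        ax.set_title(str(drug))
        ax.legend()
        fig.tight_layout()
        path = output_dir / f"{prefix}_{drug}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
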