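"""End-to-end pipeline: (simulate | load) → gate → quantify → titer → recover.

One structured config drives the whole run so any result can be reproduced
from a single file plus a seed.  Every stage writes its own CSV into the
output directory and the final ``summary.json`` echoes every parameter
used together with the headline numbers; no value appears in the summary
that is not also in a stage output file.  Identical config + seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as pio
from .gating import GatePolicy, classify_and_summarize
from .poisson import (
    DropletGeometry,
    lambda_from_concentration,
    lambda_from_negative_fraction,
)
from .recovery import compare_gates, digitize_plate
from .simulate import SimulationConfig, simulate_experiment
from .titer import titer_time_course

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("phagedrop")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``events_path`` (a measured event CSV) or ``simulation``
    (a :class:`SimulationConfig` block, which requires a seed) must supply
    the events.  When simulating, a matched no-phage control (same
    parameters, λ_phg = 0, an offset seed) is generated alongside unless
    disabled — the control is what threshold derivation and false-positive
    accounting run against.
    """

    outdir: str
    events_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    include_no_phage_control: bool = True
    gate: GatePolicy = field(default_factory=GatePolicy)
    geometry: DropletGeometry = field(
        default_factory=lambda: DropletGeometry(volume_pL=18.8)
    )
    quantify_timepoint_h: float = 5.0
    concentration_pfu_per_ml: Optional[float] = None
    plaques_path: Optional[str] = None
    plates_path: Optional[str] = None
    aliquot_volume_uL: float = 8.0
    recovery_dilution: float = 1.0

    def __post_init__(self) -> None:
        if (self.events_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of events_path or a simulation block must be set"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build a config from a YAML file with blocks named after fields."""
        raw = pio.load_yaml(path)
        kwargs = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        if "gate" in kwargs and kwargs["gate"] is not None:
            kwargs["gate"] = GatePolicy(**kwargs["gate"])
        if "geometry" in kwargs and kwargs["geometry"] is not None:
            kwargs["geometry"] = DropletGeometry(**kwargs["geometry"])
        return cls(**kwargs)


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    if echo.get("simulation") is not None:
        echo["simulation"]["timepoints_h"] = list(
            echo["simulation"]["timepoints_h"]
        )
    return echo


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the machine-readable report.

    Writes into ``config.outdir``: ``events.csv`` (and ``truth.csv``) when
    simulating, ``gate_summary.csv``, ``occupancy.csv``, and — when the
    corresponding inputs exist — ``titer.csv`` and ``recovery.csv``, plus
    ``summary.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": _config_echo(config), "stages": {}}

    # ------------------------------------------------------------ events
    with _stage("events"):
        if config.simulation is not None:
            sim = config.simulation
            pop, events = simulate_experiment(sim, sample_id="phage_sample")
            truth_frames = [
                pop.truth_frame(t).assign(timepoint_h=t)
                for t in sim.timepoints_h
            ]
            if config.include_no_phage_control:
                control_cfg = dataclasses.replace(
                    sim, lambda_phage=0.0, seed=sim.seed + 1
                )
                _, control = simulate_experiment(
                    control_cfg, sample_id="no_phage_control"
                )
                events = pd.concat([events, control], ignore_index=True)
            pio.write_event_table(events, outdir / "events.csv")
            pd.concat(truth_frames, ignore_index=True).to_csv(
                outdir / "truth.csv", index=False
            )
            report["stages"]["events"] = {
                "source": "simulation",
                "n_events": int(len(events)),
                "files": ["events.csv", "truth.csv"],
            }
        else:
            events = pio.read_event_table(config.events_path)
            report["stages"]["events"] = {
                "source": config.events_path,
                "n_events": int(len(events)),
                "files": [],
            }

    # -------------------------------------------------------------- gate
    with _stage("gate"):
        control_events = None
        if config.gate.threshold_mode == "from_negative_control":
            mask = (events["condition"] == "no_phage") & (
                events["timepoint_h"] == config.quantify_timepoint_h
            )
            control_events = events.loc[mask]
            if control_events.empty:
                raise ValueError(
                    "threshold_mode='from_negative_control' but no no_phage "
                    f"events at t={config.quantify_timepoint_h} h"
                )
            events = events.loc[~mask]
        summary = classify_and_summarize(events, config.gate, control_events)
        summary.to_csv(outdir / "gate_summary.csv", index=False)
        removed = summary["n_input"].sum() - summary["n_after_size_filter"].sum()
        logger.info(
            "size filter removed %d of %d events", removed, summary["n_input"].sum()
        )
        report["stages"]["gate"] = {
            "threshold_used": float(summary["threshold_used"].iloc[0]),
            "n_input": int(summary["n_input"].sum()),
            "n_removed_by_size_filter": int(removed),
            "fluorescent_fraction_by_group": [
                {
                    "sample_id": r.sample_id,
                    "timepoint_h": float(r.timepoint_h),
                    "fluorescent_fraction": float(r.fluorescent_fraction),
                }
                for r in summary.itertuples(index=False)
            ],
            "files": ["gate_summary.csv"],
        }

    # ---------------------------------------------------------- quantify
    with _stage("quantify"):
        phage_rows = summary[
            (summary["timepoint_h"] == config.quantify_timepoint_h)
            & (summary["sample_id"] != "no_phage_control")
        ]
        estimates = []
        for row in phage_rows.itertuples(index=False):
            p0 = 1.0 - float(row.fluorescent_fraction)
            if p0 <= 0:
                continue
            est = lambda_from_negative_fraction(p0, int(row.n_after_size_filter))
            estimates.append(
                {
                    "sample_id": row.sample_id,
                    "timepoint_h": float(row.timepoint_h),
                    "method": est.method,
                    "lambda_hat": est.lambda_hat,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p0_hat": est.p0_hat,
                    "n_droplets": est.n_droplets,
                    "implied_conc_pfu_per_ml": est.lambda_hat
                    / (config.geometry.volume_pL * 1e-9),
                }
            )
        if config.concentration_pfu_per_ml is not None:
            est = lambda_from_concentration(
                config.concentration_pfu_per_ml, config.geometry
            )
            estimates.append(
                {
                    "sample_id": "titer_input",
                    "timepoint_h": None,
                    "method": est.method,
                    "lambda_hat": est.lambda_hat,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p0_hat": None,
                    "n_droplets": None,
                    "implied_conc_pfu_per_ml": config.concentration_pfu_per_ml,
                }
            )
        occupancy = pd.DataFrame(estimates)
        occupancy.to_csv(outdir / "occupancy.csv", index=False)
        report["stages"]["quantify"] = {
            "estimates": estimates,
            "droplet_volume_pL": config.geometry.volume_pL,
            "files": ["occupancy.csv"],
        }

    # ------------------------------------------------------------- titer
    if config.plaques_path is not None:
        with _stage("titer"):
            plaques = pio.read_plaque_table(config.plaques_path)
            tc = titer_time_course(
                plaques, config.aliquot_volume_uL, config.recovery_dilution
            )
            tc.to_csv(outdir / "titer.csv", index=False)
            report["stages"]["titer"] = {
                "timepoints_h": [float(t) for t in tc["timepoint_h"]],
                "pfu_per_aliquot": [float(v) for v in tc["pfu_per_aliquot"]],
                "files": ["titer.csv"],
            }

    # ----------------------------------------------------------- recover
    if config.plates_path is not None:
        with _stage("recover"):
            plates = pio.read_plate_table(config.plates_path)
            digs = {}
            for gate_label, sub in plates.groupby("gate_label", sort=True):
                digs[gate_label] = digitize_plate(
                    sub[["well", "outcome"]], gate_label
                )
            rec_rows = [
                {
                    "gate_label": d.gate_label,
                    "n_positive": d.n_positive,
                    "n_total": d.n_total,
                    "recovery_rate": d.recovery_rate,
                    "ci_low": d.ci_low,
                    "ci_high": d.ci_high,
                }
                for d in digs.values()
            ]
            pd.DataFrame(rec_rows).to_csv(outdir / "recovery.csv", index=False)
            stage = {"gates": rec_rows, "files": ["recovery.csv"]}
            if {"high_fluorescence", "low_fluorescence"} <= set(digs):
                cmp = compare_gates(
                    digs["high_fluorescence"], digs["low_fluorescence"]
                )
                stage["comparison"] = {
                    "rate_difference": cmp.rate_difference,
                    "ci_low": cmp.ci_low,
                    "ci_high": cmp.ci_high,
                    "fisher_p": cmp.fisher_p,
                }
            report["stages"]["recover"] = stage

    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
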