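"""End-to-end orchestration: parse -> QC -> calibrate -> quantify -> test.

`run_pipeline` executes the stages in fixed order and returns a
:class:`ResultBundle` whose members are plain DataFrames, so the same entry
point serves the command line, scripts and tests.  Every applied default
and every removed replicate is recorded in the run log — opaque filtering
is the main criticism levelled at point-and-click qPCR tools.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import interplate, plate_io, qc, quantify, stats
from .errors import ConfigError
from .plate_io import Experiment, MULTI_PLATE, SINGLE_PLATE


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    inputs: list = field(default_factory=list)
    mode: str = SINGLE_PLATE
    qc: qc.QcConfig = field(default_factory=qc.QcConfig)
    reference_genes: list = field(default_factory=list)
    calibrator: str | None = None
    ipc_sample: str | None = None
    p_adjust: str = "BH"
    moderation: bool = True
    run_stats: bool = True
    output_dir: str | None = None
    plot_formats: tuple = ()

    def validate(self) -> None:
        if not self.reference_genes:
            raise ConfigError("at least one reference gene is required")
        if self.p_adjust not in stats.ADJUST_METHODS:
            raise ConfigError(
                f"p_adjust must be one of {stats.ADJUST_METHODS}"
            )
        if self.mode not in (SINGLE_PLATE, MULTI_PLATE):
            raise ConfigError(f"unknown mode {self.mode!r}")

    def to_yaml(self) -> str:
        doc = {
            "inputs": [str(p) for p in self.inputs],
            "mode": self.mode,
            "sd_threshold": self.qc.sd_threshold,
            "cq_min": self.qc.cq_min,
            "cq_max": self.qc.cq_max,
            "reference_genes": list(self.reference_genes),
            "calibrator": self.calibrator,
            "ipc_sample": self.ipc_sample,
            "p_adjust": self.p_adjust,
            "moderation": self.moderation,
            "output_dir": self.output_dir,
            "plot_formats": list(self.plot_formats),
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        return cls(
            inputs=doc.get("inputs", []),
            mode=doc.get("mode", SINGLE_PLATE),
            qc=qc.QcConfig(
                sd_threshold=doc.get("sd_threshold", 0.3),
                cq_min=doc.get("cq_min", 5.0),
                cq_max=doc.get("cq_max", 35.0),
            ),
            reference_genes=doc.get("reference_genes", []),
            calibrator=doc.get("calibrator"),
            ipc_sample=doc.get("ipc_sample"),
            p_adjust=doc.get("p_adjust", "BH"),
            moderation=doc.get("moderation", True),
            output_dir=doc.get("output_dir"),
            plot_formats=tuple(doc.get("plot_formats") or ()),
        )


@dataclass
class ResultBundle:
    """All tables produced by one pipeline run."""

    experiment: Experiment  # QC'd (and calibrated) well-level data
    raw_summary: pd.DataFrame
    summary: pd.DataFrame
    outliers: qc.OutlierReport
    calibration: interplate.PlateCalibration | None
    delta_cq: pd.DataFrame
    ddcq: pd.DataFrame | None
    tests: pd.DataFrame | None
    log: list


def run_pipeline(
    config: RunConfig, experiment: Experiment | None = None
) -> ResultBundle:
    """Run the full analysis described by ``config``.

    ``experiment`` may be passed directly (e.g. from the simulator) to
    bypass file parsing.  Stage order: parse, Cq cut-off, replicate-SD
    filter, optional inter-plate calibration, replicate aggregation, dCq,
    optional ddCq, optional significance tests.
    """
    config.validate()
    log: list[str] = []
    if experiment is None:
        if not config.inputs:
            raise ConfigError("no input files and no experiment given")
        experiment = plate_io.load_experiment(config.inputs, config.mode)
        log.append(
            f"loaded {len(experiment.data)} wells from "
            f"{len(experiment.plate_ids)} plate(s): {experiment.plate_ids}"
        )
    if config.ipc_sample is None and config.mode == MULTI_PLATE:
        log.append(
            "multi_plate mode without IPC sample: assuming sample "
            "maximization layout, no inter-plate calibration"
        )

    cfg = config.qc
    experiment, outliers = qc.apply_cq_cutoff(
        experiment, cfg.cq_min, cfg.cq_max
    )
    n_cut = outliers.n_removed
    log.append(
        f"Cq cut-off [{cfg.cq_min}, {cfg.cq_max}]: {n_cut} value(s) set missing"
    )
    experiment, outliers = qc.filter_sd_outliers(
        experiment, cfg.sd_threshold, outliers
    )
    log.append(
        f"replicate SD filter (threshold {cfg.sd_threshold}): "
        f"{outliers.n_removed - n_cut} outlier(s) removed, "
        f"{len(outliers.flagged_pairs)} unresolvable pair(s) flagged"
    )
    for entry in outliers.entries.itertuples():
        log.append(
            f"  removed {entry.reason}: plate={entry.plate} well={entry.well} "
            f"sample={entry.sample} target={entry.target} "
            f"rp.num={entry.rp_num} cq={entry.cq:.3f}"
        )
    raw_summary = qc.aggregate_replicates(experiment)

    calibration = None
    if config.ipc_sample is not None:
        experiment, calibration = interplate.calibrate(
            experiment, config.ipc_sample
        )
        log.append(
            f"inter-plate calibration on IPC sample {config.ipc_sample!r}: "
            + ", ".join(
                f"{r.plate}/{r.target}: CF={r.correction_factor:.6f}"
                for r in calibration.table.itertuples()
            )
        )

    summary = qc.aggregate_replicates(experiment, mode=config.mode)
    dcq = quantify.delta_cq(summary, list(config.reference_genes))
    log.append(
        f"dCq normalised to reference gene(s) {list(config.reference_genes)}"
    )

    ddcq = None
    if config.calibrator is not None:
        ddcq = quantify.delta_delta_cq(dcq, config.calibrator)
        log.append(f"ddCq relative to calibrator {config.calibrator!r}")

    tests = None
    if config.run_stats and config.calibrator is not None:
        tests = stats.run_tests(
            experiment,
            list(config.reference_genes),
            config.calibrator,
            method=config.p_adjust,
            moderation=config.moderation,
        )
        log.append(
            f"significance tests vs {config.calibrator!r}, "
            f"{config.p_adjust} adjustment, "
            f"moderation={'on' if config.moderation else 'off'}"
        )
    return ResultBundle(
        experiment=experiment,
        raw_summary=raw_summary,
        summary=summary,
        outliers=outliers,
        calibration=calibration,
        delta_cq=dcq,
        ddcq=ddcq,
        tests=tests,
        log=log,
    )


# Export vocabulary matching the original tool's table headers.
_DCQ_EXPORT = {
    "sample": "Sample",
    "target": "Gene",
    "delta_cq": "dCq",
    "neg_delta_cq": "minus_dCq",
    "sd_delta_cq": "dCq.sd",
    "rq": "RQ",
}
_DDCQ_EXPORT = {
    "sample": "Sample",
    "target": "Gene",
    "ddcq": "ddCq",
    "fc": "FC",
    "fc_sd": "FC.sd",
}
_STATS_EXPORT = {
    "sample": "Sample",
    "target": "Gene",
    "t": "t",
    "p_value": "p.Value",
    "adj_p_value": "adj.P.Value",
    "significance": "significance",
}


def _export(frame: pd.DataFrame, rename: dict, path: Path, display: bool) -> None:
    out = frame[list(rename)].rename(columns=rename)
    if display:
        out = out.round(2)
    out.to_csv(path, index=False)


def export_tables(bundle: ResultBundle, output_dir: str | Path) -> list[Path]:
    """Write every bundle table as CSV (full precision plus 2-digit display).

    Produces ``delta_cq.csv``, ``ddcq.csv``, ``stats.csv``,
    ``outliers.csv``, ``calibration.csv``, ``summary.csv``, ``run.log`` and
    ``*_display.csv`` variants that differ only by rounding.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(name: str, frame: pd.DataFrame, rename: dict | None = None) -> None:
        for display in (False, True):
            path = out / (f"{name}_display.csv" if display else f"{name}.csv")
            if rename:
                _export(frame, rename, path, display)
            else:
                (frame.round(2) if display else frame).to_csv(path, index=False)
            written.append(path)

    emit("delta_cq", bundle.delta_cq, _DCQ_EXPORT)
    if bundle.ddcq is not None:
        emit("ddcq", bundle.ddcq, _DDCQ_EXPORT)
    if bundle.tests is not None and not bundle.tests.empty:
        emit("stats", bundle.tests, _STATS_EXPORT)
    emit("summary", bundle.summary)
    bundle.outliers.to_csv(out / "outliers.csv")
    written.append(out / "outliers.csv")
    if bundle.calibration is not None:
        bundle.calibration.to_csv(out / "calibration.csv")
        written.append(out / "calibration.csv")
    (out / "run.log").write_text("\n".join(bundle.log) + "\n")
    written.append(out / "run.log")
    return written
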