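"""Synthetic plate-export generator with known ground truth.

Emulates a typical relative-quantification design: a control sample C and
one or more test samples, a panel of genes of interest plus stably
expressed reference genes, at least three technical replicates per
(sample, gene), optionally spread over several plates with per-plate Cq
offsets and an inter-plate calibrator (IPC) sample replicated on every
plate.  Under the doubling model, a true fold change f relative to the
control lowers Cq by log2(f), so each well is drawn as

    Cq = base_cq(gene) - log2(fc_true(sample, gene))
         + plate_offset(plate) + Normal(0, replicate_noise_sd)

with reference genes held at fc_true = 1.  A configurable fraction of
replicates is additionally shifted by a fixed number of cycles to mimic
pipetting outliers.  Everything is reproducible from the seed, and ground
truth (true fold changes, injected outliers) is returned as separate
tables so tests never re-derive it from the generator's internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plate_io import (
    COLUMNS,
    Experiment,
    MULTI_PLATE,
    SINGLE_PLATE,
    parse_plate_file,
)

ROW_LETTERS = "ABCDEFGH"


@dataclass
class SimConfig:
    """Design and noise parameters of a simulated experiment.

    Defaults mirror a compact single-plate two-condition study: control C
    and treated T, seven genes of interest with a 4-fold induction in T,
    one reference gene, three technical replicates, no plate offsets and
    no injected outliers.
    """

    n_samples: int = 2
    n_genes: int = 7
    n_reference_genes: int = 1
    n_replicates: int = 3
    n_plates: int = 1
    #: fold change of each non-control sample/GOI pair; scalar or mapping
    #: {(sample, gene): fc}.  The control sample and reference genes are 1.
    true_fold_changes: "float | dict" = 4.0
    base_cq: float = 20.0
    #: spread of deterministic per-gene baseline offsets around base_cq
    gene_baseline_spread: float = 4.0
    replicate_noise_sd: float = 0.05
    plate_offsets: tuple = ()
    outlier_rate: float = 0.0
    outlier_shift: float = 5.0
    ipc_enabled: bool = False
    ipc_sample: str = "IPC"
    #: place every reference-gene well on the first plate regardless of the
    #: sample's plate, producing cross-plate dCq contrasts that are biased
    #: by the plate offsets until inter-plate calibration is applied
    split_reference_plate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_reference_genes", "n_replicates", "n_plates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must be in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return ["C"] + [f"S{i}" for i in range(1, self.n_samples)]

    @property
    def goi(self) -> list[str]:
        return [f"GOI{i + 1}" for i in range(self.n_genes)]

    @property
    def reference_genes(self) -> list[str]:
        return [f"refG{i + 1}" if self.n_reference_genes > 1 else "refG"
                for i in range(self.n_reference_genes)]

    @property
    def plate_ids(self) -> list[str]:
        return [f"plate{i + 1}" for i in range(self.n_plates)]

    def fold_change(self, sample: str, gene: str) -> float:
        if sample == "C" or gene in self.reference_genes:
            return 1.0
        if isinstance(self.true_fold_changes, dict):
            return float(self.true_fold_changes.get((sample, gene), 1.0))
        return float(self.true_fold_changes)


def _well_label(i: int) -> str:
    # fill a 96-well layout row-wise, then wrap to larger indices
    if i < 96:
        return f"{ROW_LETTERS[i // 12]}{i % 12 + 1}"
    return f"X{i + 1}"


def generate_experiment(
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Simulate per-plate well tables plus ground-truth tables.

    Returns ``(plates, truth)`` where ``plates`` maps plate id to a frame
    with columns ``well, sample, target, cq`` (instrument-export shape) and
    ``truth`` holds ``fold_changes`` (sample, gene, fc_true), ``outliers``
    (plate, sample, target, replicate) and ``plate_offsets``.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.goi + config.reference_genes
    base = {
        g: config.base_cq
        + (rng.uniform(-config.gene_baseline_spread, config.gene_baseline_spread)
           if config.gene_baseline_spread > 0 else 0.0)
        for g in genes
    }
    offsets = dict(
        zip(
            config.plate_ids,
            list(config.plate_offsets) + [0.0] * config.n_plates,
        )
    )

    # samples are distributed round-robin across plates; the IPC sample is
    # measured for every gene on every plate
    plate_of = {
        s: config.plate_ids[i % config.n_plates]
        for i, s in enumerate(config.samples)
    }
    plates: dict[str, list[dict]] = {p: [] for p in config.plate_ids}
    outlier_rows: list[dict] = []
    fc_rows: list[dict] = []

    def emit(plate: str, sample: str, gene: str, fc: float) -> None:
        mu = base[gene] - np.log2(fc) + offsets[plate]
        for rep in range(1, config.n_replicates + 1):
            cq = mu + (
                rng.normal(0.0, config.replicate_noise_sd)
                if config.replicate_noise_sd > 0
                else 0.0
            )
            if config.outlier_rate > 0 and rng.random() < config.outlier_rate:
                cq += config.outlier_shift
                outlier_rows.append(
                    {"plate": plate, "sample": sample, "target": gene,
                     "replicate": rep}
                )
            plates[plate].append({"sample": sample, "target": gene, "cq": cq})

    for sample in config.samples:
        for gene in genes:
            fc = config.fold_change(sample, gene)
            plate = (
                config.plate_ids[0]
                if config.split_reference_plate and gene in config.reference_genes
                else plate_of[sample]
            )
            emit(plate, sample, gene, fc)
            if gene not in config.reference_genes or sample == "C":
                fc_rows.append({"sample": sample, "gene": gene, "fc_true": fc})
    if config.ipc_enabled:
        for plate in config.plate_ids:
            for gene in genes:
                emit(plate, config.ipc_sample, gene, 1.0)

    frames = {}
    for plate, rows in plates.items():
        frame = pd.DataFrame(rows)
        frame.insert(0, "well", [_well_label(i) for i in range(len(frame))])
        frames[plate] = frame

    truth = {
        "fold_changes": pd.DataFrame(fc_rows),
        "outliers": pd.DataFrame(
            outlier_rows, columns=["plate", "sample", "target", "replicate"]
        ),
        "plate_offsets": pd.DataFrame(
            [{"plate": p, "offset": o} for p, o in offsets.items()]
        ),
    }
    return frames, truth


def to_experiment(plates: dict[str, pd.DataFrame], mode: str | None = None) -> Experiment:
    """Assemble simulated plate frames directly into an Experiment."""
    if mode is None:
        mode = MULTI_PLATE if len(plates) > 1 else SINGLE_PLATE
    frames = []
    for plate, frame in plates.items():
        f = frame.copy()
        f.insert(0, "plate", plate)
        f["replicate"] = f.groupby(["sample", "target"]).cumcount() + 1
        frames.append(f[COLUMNS])
    return Experiment(pd.concat(frames, ignore_index=True), mode=mode)


def write_fixture_files(
    plates: dict[str, pd.DataFrame],
    out_dir: str | Path,
    delimiter: str = ";",
    decimal: str = ".",
    line_ending: str = "\n",
    header: tuple[str, str, str, str] = ("Well", "Sample", "Target", "Cq"),
) -> list[Path]:
    """Write simulated plates as instrument-style delimited files.

    Supports every dialect the parser reads, including semicolon-delimited
    files with decimal commas and CRLF line endings, for round-trip tests.
    """
    if decimal == "," and delimiter != ";":
        raise ValueError("decimal comma is only supported with ';' delimiter")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for plate, frame in plates.items():
        lines = [delimiter.join(header)]
        for row in frame.itertuples(index=False):
            # repr gives the shortest decimal that round-trips the float
            cq = "" if pd.isna(row.cq) else repr(float(row.cq))
            if decimal == ",":
                cq = cq.replace(".", ",")
            lines.append(delimiter.join([row.well, row.sample, row.target, cq]))
        path = out_dir / f"{plate}.csv"
        path.write_bytes(line_ending.join(lines + [""]).encode("utf-8"))
        paths.append(path)
    return paths
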