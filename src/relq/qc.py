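"""Cq cut-off window and technical-replicate outlier filtering.

Two quality gates precede quantification.  First, Cq values outside a
plausible window (default [5, 35] cycles, closed at both ends) are treated
as not available — very late cycles are dominated by stochastic
amplification and primer dimers, very early ones by pipetting or threshold
artefacts.  Second, the spread of technical replicates is checked against a
standard-deviation threshold (default 0.3 cycles, the replicate-variability
level recommended by the MIQE guidelines): while the sample SD of a
(plate, sample, target) replicate group exceeds the threshold and at least
three values remain, the replicate farthest from the group median is
removed.  With only two survivors no arbitration is possible, so both are
kept and the pair is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .plate_io import Experiment, SINGLE_PLATE, MULTI_PLATE

REASON_CUTOFF = "cutoff"
REASON_SD = "sd_outlier"

OUTLIER_COLUMNS = ["plate", "well", "sample", "target", "rp_num", "cq", "reason"]


@dataclass
class QcConfig:
    """Quality-control parameters.

    Parameters
    ----------
    sd_threshold:
        Maximum tolerated sample SD (cycles) of a technical-replicate group.
    cq_min, cq_max:
        Closed acceptance window for raw Cq values, in cycles.
    """

    sd_threshold: float = 0.3
    cq_min: float = 5.0
    cq_max: float = 35.0

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")
        if not self.cq_min < self.cq_max:
            raise ValueError("cq_min must be < cq_max")


@dataclass
class OutlierReport:
    """Log of removed (or flagged) replicates, one row per event."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=OUTLIER_COLUMNS)
    )
    #: (plate, sample, target) pairs left with 2 divergent replicates that
    #: could not be arbitrated.
    flagged_pairs: list[tuple] = field(default_factory=list)

    def extend(self, rows: list[dict]) -> None:
        if rows:
            new = pd.DataFrame(rows, columns=OUTLIER_COLUMNS)
            self.entries = (
                new
                if self.entries.empty
                else pd.concat([self.entries, new], ignore_index=True)
            )

    @property
    def n_removed(self) -> int:
        return len(self.entries)

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def apply_cq_cutoff(
    experiment: Experiment,
    cq_min: float = 5.0,
    cq_max: float = 35.0,
    report: OutlierReport | None = None,
) -> tuple[Experiment, OutlierReport]:
    """Set Cq values outside the closed window [cq_min, cq_max] to missing.

    Returns a new experiment and the (possibly shared) outlier report with
    one ``cutoff`` entry per discarded value.
    """
    if not cq_min < cq_max:
        raise ValueError("cq_min must be < cq_max")
    report = report if report is not None else OutlierReport()
    exp = experiment.copy()
    out_of_range = exp.data["cq"].notna() & (
        (exp.data["cq"] < cq_min) | (exp.data["cq"] > cq_max)
    )
    rows = [
        {
            "plate": r.plate,
            "well": r.well,
            "sample": r.sample,
            "target": r.target,
            "rp_num": r.replicate,
            "cq": r.cq,
            "reason": REASON_CUTOFF,
        }
        for r in exp.data.loc[out_of_range].itertuples()
    ]
    report.extend(rows)
    exp.data.loc[out_of_range, "cq"] = np.nan
    return exp, report


def _greedy_removal(values: np.ndarray, keep: list[int], sd_threshold: float) -> list[int]:
    """Farthest-from-median removal, one value at a time (large-group path)."""
    removed: list[int] = []
    while len(keep) >= 3:
        kept = values[keep]
        if np.std(kept, ddof=1) <= sd_threshold:
            break
        dev = np.abs(kept - np.median(kept))
        # ties -> later replicate: take the last argmax
        worst = len(dev) - 1 - int(np.argmax(dev[::-1]))
        removed.append(keep.pop(worst))
    return removed


def filter_replicate_outliers(
    cq_values: "list[float] | np.ndarray",
    sd_threshold: float,
) -> tuple[list[float], list[int], bool]:
    """Remove the smallest set of divergent replicates from one group.

    Finds the minimal number of removals after which the sample SD (n-1
    denominator) of the kept values is at or below ``sd_threshold``, while
    keeping at least two values.  Among minimal removal sets the one whose
    removed values deviate most from the group median is chosen, ties going
    to later replicates — for a single removal this is exactly "drop the
    value farthest from the median".  Replicate groups are small, so the
    search is exhaustive (one-at-a-time greedy removal beyond 10 values).
    If only two values survive and their SD still exceeds the threshold,
    both are kept and the group is flagged — two points cannot identify
    which one is divergent.

    Returns ``(kept_values, removed_original_indices, flagged)``.
    """
    values = np.asarray(cq_values, dtype=float)
    keep = [i for i in range(len(values)) if np.isfinite(values[i])]
    removed: list[int] = []
    n = len(keep)
    if n >= 3 and np.std(values[keep], ddof=1) > sd_threshold:
        if n > 10:
            removed = _greedy_removal(values, keep, sd_threshold)
        else:
            med = np.median(values[keep])
            best: tuple | None = None
            for k in range(1, n - 1):
                for combo in combinations(keep, k):
                    kept_idx = [i for i in keep if i not in combo]
                    if (
                        len(kept_idx) > 2
                        and np.std(values[kept_idx], ddof=1) > sd_threshold
                    ):
                        continue
                    # preference: largest total deviation from the group
                    # median, then later replicate indices
                    score = (
                        float(np.sum(np.abs(values[list(combo)] - med))),
                        combo,
                    )
                    if best is None or score > best[0]:
                        best = (score, list(combo))
                if best is not None:
                    break
            if best is not None:
                removed = best[1]
                keep = [i for i in keep if i not in removed]
    flagged = (
        len(keep) == 2 and np.std(values[keep], ddof=1) > sd_threshold
    )
    return [float(values[i]) for i in keep], removed, flagged


def filter_sd_outliers(
    experiment: Experiment,
    sd_threshold: float = 0.3,
    report: OutlierReport | None = None,
) -> tuple[Experiment, OutlierReport]:
    """Apply replicate-SD filtering to every (plate, sample, target) group.

    Removed replicates are set missing in the returned experiment and
    logged with reason ``sd_outlier``; the original rows are retained so
    the report can reference plate and well.
    """
    report = report if report is not None else OutlierReport()
    exp = experiment.copy()
    rows: list[dict] = []
    for key, group in exp.data.groupby(["plate", "sample", "target"], sort=False):
        if group["cq"].notna().sum() == 0:
            continue
        _, removed, flagged = filter_replicate_outliers(
            group["cq"].to_numpy(), sd_threshold
        )
        if flagged:
            report.flagged_pairs.append(key)
        for pos in removed:
            r = group.iloc[pos]
            rows.append(
                {
                    "plate": r["plate"],
                    "well": r["well"],
                    "sample": r["sample"],
                    "target": r["target"],
                    "rp_num": r["replicate"],
                    "cq": r["cq"],
                    "reason": REASON_SD,
                }
            )
            exp.data.loc[group.index[pos], "cq"] = np.nan
    report.extend(rows)
    return exp, report


def aggregate_replicates(experiment: Experiment, mode: str | None = None) -> pd.DataFrame:
    """Average surviving technical replicates into per-group summaries.

    In single-plate mode replicates are averaged within the plate; in
    multi-plate mode (after inter-plate calibration) they are pooled across
    all plates of the experiment.  Returns a frame with columns
    ``sample, target, mean_cq, sd_cq, n_used, n_removed`` (plus ``plate``
    in single-plate mode).  ``sd_cq`` uses the n-1 denominator and is
    missing for groups of fewer than two values; ``mean_cq`` is missing
    exactly when no replicate survived.
    """
    mode = mode or experiment.mode
    keys = (
        ["sample", "target"]
        if mode == MULTI_PLATE
        else ["plate", "sample", "target"]
    )
    rows = []
    for key, group in experiment.data.groupby(keys, sort=False):
        cq = group["cq"].dropna()
        rows.append(
            dict(zip(keys, key))
            | {
                "mean_cq": cq.mean() if len(cq) else np.nan,
                "sd_cq": cq.std(ddof=1) if len(cq) >= 2 else np.nan,
                "n_used": int(len(cq)),
                "n_removed": int(group["cq"].isna().sum()),
            }
        )
    return pd.DataFrame(rows)
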