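"""Inter-plate calibration from a common calibrator sample.

When one sample set spans several qPCR runs, run-to-run differences in
reagents, thermal block and threshold setting shift all Cq values of a
plate.  The remedy (after Hellemans et al.'s inter-run calibration idea) is
to measure one identical sample — the inter-plate calibrator, IPC — on
every plate and use its spread across plates to estimate a per-plate
correction factor:

1. G = geometric mean of all IPC Cq values across all plates (per target,
   or pooled over targets);
2. each IPC replicate's scaling factor s_i = cq_i / G;
3. the plate's correction factor CF_p = arithmetic mean of the s_i measured
   on plate p;
4. every Cq on plate p is divided by CF_p.

The correction is multiplicative on the Cq scale, and CF_p is the mean of
per-replicate ratios, not the ratio of means — the two differ in the third
decimal for noisy IPCs.  Calibrating a single plate is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingIPCError
from .plate_io import Experiment

POOLED = "__pooled__"


@dataclass
class PlateCalibration:
    """Per-plate, per-target correction factors plus audit columns.

    ``table`` has columns ``plate, target, mean_ipc_cq, correction_factor``;
    ``target`` is ``"__pooled__"`` when calibration pooled over targets.
    ``scaling_factors`` retains every per-replicate ratio s_i for audit.
    """

    ipc_sample: str
    table: pd.DataFrame
    geomeans: dict[str, float]
    scaling_factors: pd.DataFrame
    per_target: bool = True

    def factor(self, plate: str, target: str) -> float:
        t = self.table
        if self.per_target:
            row = t[(t["plate"] == plate) & (t["target"] == target)]
            if row.empty:  # target not covered by the IPC -> pooled fallback
                row = t[(t["plate"] == plate) & (t["target"] == POOLED)]
        else:
            row = t[(t["plate"] == plate) & (t["target"] == POOLED)]
        if row.empty:
            raise MissingIPCError(f"no correction factor for plate {plate!r}")
        return float(row["correction_factor"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _layer(ipc: pd.DataFrame, target_label: str) -> tuple[list[dict], list[dict], float]:
    """Compute G, s_i and CF_p for one calibration layer (one target or pooled)."""
    cq = ipc["cq"].to_numpy(dtype=float)
    geomean = float(np.exp(np.mean(np.log(cq))))
    scaling = ipc.assign(target=target_label, scaling_factor=cq / geomean)
    rows = []
    for plate, grp in scaling.groupby("plate", sort=False):
        rows.append(
            {
                "plate": plate,
                "target": target_label,
                "mean_ipc_cq": float(grp["cq"].mean()),
                "correction_factor": float(grp["scaling_factor"].mean()),
            }
        )
    audit = scaling[["plate", "target", "well", "cq", "scaling_factor"]].to_dict(
        "records"
    )
    return rows, audit, geomean


def compute_correction_factors(
    experiment: Experiment,
    ipc_sample: str,
    per_target: bool | None = None,
) -> PlateCalibration:
    """Estimate per-plate correction factors from the IPC sample.

    ``per_target`` defaults to True when the IPC was measured for more than
    one target (calibration per gene), pooled otherwise.  Requires at least
    one non-missing IPC Cq on every plate.  For a single-plate experiment
    the calibration is forced to the exact identity.
    """
    data = experiment.data
    ipc = data[(data["sample"] == ipc_sample) & data["cq"].notna()]
    plates = experiment.plate_ids
    missing = [p for p in plates if p not in set(ipc["plate"])]
    if missing:
        raise MissingIPCError(
            f"IPC sample {ipc_sample!r} has no usable Cq on plate(s) "
            f"{missing}; the calibrator must be run on every plate"
        )

    ipc_targets = list(dict.fromkeys(ipc["target"]))
    if per_target is None:
        per_target = len(ipc_targets) > 1

    if len(plates) == 1:
        # calibrating one plate is the identity by definition
        table = pd.DataFrame(
            [
                {
                    "plate": plates[0],
                    "target": t,
                    "mean_ipc_cq": float(
                        ipc.loc[ipc["target"] == t, "cq"].mean()
                    )
                    if t != POOLED
                    else float(ipc["cq"].mean()),
                    "correction_factor": 1.0,
                }
                for t in (ipc_targets if per_target else []) + [POOLED]
            ]
        )
        return PlateCalibration(
            ipc_sample, table, {POOLED: float(np.exp(np.mean(np.log(ipc["cq"]))))},
            pd.DataFrame(columns=["plate", "target", "well", "cq", "scaling_factor"]),
            per_target,
        )

    rows: list[dict] = []
    audit: list[dict] = []
    geomeans: dict[str, float] = {}
    if per_target:
        for t in ipc_targets:
            sub = ipc[ipc["target"] == t]
            sub_missing = [p for p in plates if p not in set(sub["plate"])]
            if sub_missing:
                # a target the IPC lacks on some plate cannot be calibrated
                # per-target; it will fall back to the pooled factor
                continue
            r, a, g = _layer(sub, t)
            rows += r
            audit += a
            geomeans[t] = g
    r, a, g = _layer(ipc, POOLED)
    rows += r
    audit += a
    geomeans[POOLED] = g
    return PlateCalibration(
        ipc_sample,
        pd.DataFrame(rows),
        geomeans,
        pd.DataFrame(audit),
        per_target,
    )


def apply_calibration(
    experiment: Experiment, calibration: PlateCalibration
) -> Experiment:
    """Divide each Cq by its plate's correction factor.

    Missing values stay missing; the outlier report is untouched.
    """
    exp = experiment.copy()
    factors = np.array(
        [
            calibration.factor(plate, target)
            for plate, target in zip(exp.data["plate"], exp.data["target"])
        ]
    )
    exp.data["cq"] = exp.data["cq"] / factors
    return exp


def calibrate(
    experiment: Experiment, ipc_sample: str, per_target: bool | None = None
) -> tuple[Experiment, PlateCalibration]:
    """Convenience wrapper: estimate factors, then apply them."""
    cal = compute_correction_factors(experiment, ipc_sample, per_target)
    return apply_calibration(experiment, cal), cal
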