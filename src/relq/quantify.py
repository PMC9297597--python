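"""Relative quantification: dCq, relative quantity, ddCq and fold change.

The comparative-Cq (Livak) model assumes near-perfect and equal
amplification efficiencies, so one PCR cycle corresponds to a doubling.
Expression of a target gene in a sample is first normalised to one or more
reference (housekeeping) genes,

    dCq = Cq(target) - Cq(reference),     RQ = 2 ** -dCq,

where the reference value is the arithmetic mean of the reference genes'
mean Cq for that sample.  Larger dCq means lower expression, so the
sign-flipped -dCq is also reported.  Relative to a calibrator sample
(typically the untreated control),

    ddCq = dCq(sample) - dCq(calibrator),     FC = 2 ** -ddCq.

Standard deviations are propagated from technical-replicate spread:
in quadrature on the Cq scale, and first-order (delta method) through the
exponentiation, FC.sd = ln(2) * FC * sd(ddCq).  All stored values keep full
precision; two-digit rounding is display-only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import UnknownCalibratorError, UnknownReferenceError

LN2 = float(np.log(2.0))


def reference_cq(
    cq_summary: pd.DataFrame, reference_genes: list[str]
) -> pd.DataFrame:
    """Per-sample normalisation value from one or more reference genes.

    Returns columns ``sample, ref_cq, sd_ref`` where ``ref_cq`` is the
    arithmetic mean over reference genes of each gene's mean Cq and
    ``sd_ref`` combines the genes' replicate SDs in quadrature,
    sqrt(sum sd_g^2) / k.  A sample missing any reference gene gets a
    missing reference value and a warning naming the gap.
    """
    if not reference_genes:
        raise UnknownReferenceError("at least one reference gene is required")
    targets = set(cq_summary["target"])
    unknown = [g for g in reference_genes if g not in targets]
    if unknown:
        raise UnknownReferenceError(
            f"reference gene(s) {unknown} not among targets {sorted(targets)}"
        )
    k = len(reference_genes)
    rows = []
    for sample, grp in cq_summary.groupby("sample", sort=False):
        sub = grp[grp["target"].isin(reference_genes)]
        means = sub.set_index("target")["mean_cq"].reindex(reference_genes)
        if means.isna().any():
            gaps = list(means.index[means.isna()])
            warnings.warn(
                f"sample {sample!r}: reference gene(s) {gaps} missing or "
                "unmeasured; reference value set missing",
                stacklevel=2,
            )
            rows.append({"sample": sample, "ref_cq": np.nan, "sd_ref": np.nan})
            continue
        sds = sub.set_index("target")["sd_cq"].reindex(reference_genes)
        # single-replicate reference groups have no SD estimate; treat their
        # contribution as zero rather than poisoning the quadrature
        sd = float(np.sqrt(np.nansum(sds.to_numpy() ** 2)) / k)
        rows.append(
            {"sample": sample, "ref_cq": float(means.mean()), "sd_ref": sd}
        )
    return pd.DataFrame(rows)


def delta_cq(
    cq_summary: pd.DataFrame, reference_genes: list[str]
) -> pd.DataFrame:
    """dCq table: one row per (sample, target).

    Columns: ``sample, target, delta_cq, neg_delta_cq, sd_delta_cq, rq``.
    Reference genes' own rows are included (their dCq is 0 when a single
    reference is used).
    """
    ref = reference_cq(cq_summary, reference_genes)
    merged = cq_summary.merge(ref, on="sample", how="left")
    dcq = merged["mean_cq"] - merged["ref_cq"]
    sd_t = merged["sd_cq"].fillna(0.0).where(merged["mean_cq"].notna())
    sd = np.sqrt(sd_t**2 + merged["sd_ref"] ** 2)
    return pd.DataFrame(
        {
            "sample": merged["sample"],
            "target": merged["target"],
            "delta_cq": dcq,
            "neg_delta_cq": -dcq,
            "sd_delta_cq": sd,
            "rq": 2.0 ** (-dcq),
        }
    )


def delta_delta_cq(
    delta_table: pd.DataFrame, calibrator: str
) -> pd.DataFrame:
    """ddCq and fold change relative to a calibrator sample.

    Columns: ``sample, target, calibrator, ddcq, fc, fc_sd``.  The
    calibrator's own rows are exactly ddcq = 0, fc = 1, fc_sd = 0.
    """
    if calibrator not in set(delta_table["sample"]):
        raise UnknownCalibratorError(
            f"calibrator sample {calibrator!r} not found; samples: "
            f"{sorted(set(delta_table['sample']))}"
        )
    cal = delta_table[delta_table["sample"] == calibrator].set_index("target")
    ddcq = np.array(
        [
            row.delta_cq - cal["delta_cq"].get(row.target, np.nan)
            for row in delta_table.itertuples()
        ]
    )
    sd_cal = np.array(
        [cal["sd_delta_cq"].get(row.target, np.nan) for row in delta_table.itertuples()]
    )
    sd_ddcq = np.sqrt(delta_table["sd_delta_cq"].to_numpy() ** 2 + sd_cal**2)
    fc = 2.0 ** (-ddcq)
    out = pd.DataFrame(
        {
            "sample": delta_table["sample"],
            "target": delta_table["target"],
            "calibrator": calibrator,
            "ddcq": ddcq,
            "fc": fc,
            "fc_sd": LN2 * fc * sd_ddcq,
        }
    )
    is_cal = out["sample"] == calibrator
    out.loc[is_cal, ["ddcq", "fc_sd"]] = 0.0
    out.loc[is_cal, "fc"] = 1.0
    return out
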