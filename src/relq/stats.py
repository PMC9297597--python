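"""Significance testing of dCq differences between two conditions.

Each gene is fitted with a two-group linear model on replicate-level dCq
values (one observation per surviving technical replicate), giving a mean
difference, a pooled residual variance and an ordinary t-statistic.  With
few replicates per gene these variance estimates are noisy, so by default
they are stabilised by empirical-Bayes shrinkage toward a common prior —
the moderation scheme of the limma framework: residual variances are
modelled as scaled-F around a prior variance s0^2 with d0 prior degrees of
freedom, the two hyperparameters are estimated by moment-matching the log
residual variances (digamma/trigamma inversion), and each gene's variance
becomes the weighted combination

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

tested against a t distribution with d0 + d_g degrees of freedom.  Setting
d0 = 0 recovers the ordinary t-test exactly.

Sign convention: dCq falls when expression rises, so upregulated genes in
the test condition have negative t.

P values across the genes of one sample-vs-control comparison are adjusted
for multiple testing by Benjamini-Hochberg (FDR, default), Bonferroni or
Holm.  The adjustment procedures are implemented here from their step-up /
step-down definitions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .errors import UnknownControlError, UnknownReferenceError
from .plate_io import Experiment
from .qc import aggregate_replicates
from .quantify import reference_cq

ADJUST_METHODS = ("BH", "bonferroni", "holm")

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class GeneFit:
    """Two-group OLS fit for one gene on replicate-level dCq values."""

    target: str
    effect: float  # mean dCq(sample) - mean dCq(control), cycles
    residual_sd: float
    residual_df: int
    n_sample: int
    n_control: int

    @property
    def se(self) -> float:
        return self.residual_sd * math.sqrt(1 / self.n_sample + 1 / self.n_control)


@dataclass
class ModerationParams:
    """Estimated scaled-F prior for residual variances."""

    prior_df: float  # d0, may be inf
    prior_var: float  # s0^2


def per_replicate_delta_cq(
    experiment: Experiment, reference_genes: list[str]
) -> pd.DataFrame:
    """dCq per surviving technical replicate.

    Each replicate's Cq minus the same sample's reference value taken from
    the matching replicate index (the arithmetic mean over reference genes
    of that replicate's Cq; a reference replicate removed by QC falls back
    to the gene's replicate mean).  Pairing replicate-for-replicate keeps
    the observations independent, so the two-group t-test's standard error
    accounts for reference-gene noise — subtracting a shared reference
    mean instead would leave replicates correlated and understate the SE.
    Returns columns ``plate, sample, target, replicate, delta_cq``.
    """
    if not reference_genes:
        raise UnknownReferenceError("at least one reference gene is required")
    targets = set(experiment.data["target"])
    unknown = [g for g in reference_genes if g not in targets]
    if unknown:
        raise UnknownReferenceError(
            f"reference gene(s) {unknown} not among targets {sorted(targets)}"
        )
    data = experiment.data[experiment.data["cq"].notna()]
    refs = data[data["target"].isin(reference_genes)]
    # per (sample, gene): replicate-index -> cq, plus the gene's mean as
    # the fallback for removed replicates
    by_rep = refs.groupby(["sample", "target", "replicate"])["cq"].mean()
    gene_mean = refs.groupby(["sample", "target"])["cq"].mean()

    def ref_value(sample: str, replicate: int) -> float:
        vals = []
        for g in reference_genes:
            v = by_rep.get((sample, g, replicate))
            if v is None or np.isnan(v):
                v = gene_mean.get((sample, g), np.nan)
            vals.append(v)
        return float(np.mean(vals))

    ref = np.array(
        [ref_value(s, r) for s, r in zip(data["sample"], data["replicate"])]
    )
    out = pd.DataFrame(
        {
            "plate": data["plate"],
            "sample": data["sample"],
            "target": data["target"],
            "replicate": data["replicate"],
            "delta_cq": data["cq"].to_numpy() - ref,
        }
    )
    return out.dropna(subset=["delta_cq"]).reset_index(drop=True)


def fit_gene_models(
    replicate_dcq: pd.DataFrame, sample: str, control: str
) -> list[GeneFit]:
    """Per-target two-group linear fits of replicate dCq values.

    effect = mean(sample) - mean(control); the residual variance is pooled
    across both groups; targets observed in only one group are dropped.
    A group of size one contributes its mean but no residual degrees of
    freedom.
    """
    fits = []
    for target, grp in replicate_dcq.groupby("target", sort=False):
        a = grp.loc[grp["sample"] == sample, "delta_cq"].to_numpy()
        b = grp.loc[grp["sample"] == control, "delta_cq"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        df = len(a) + len(b) - 2
        rss = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
        sd = math.sqrt(rss / df) if df > 0 else 0.0
        fits.append(
            GeneFit(
                target=target,
                effect=float(a.mean() - b.mean()),
                residual_sd=sd,
                residual_df=df,
                n_sample=len(a),
                n_control=len(b),
            )
        )
    return fits


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_moderation(
    variances: np.ndarray, dfs: np.ndarray
) -> ModerationParams:
    """Moment-match a scaled-F prior to observed residual variances.

    Works on log variances: E[log s_g^2] and Var[log s_g^2] under the
    scaled-F model involve digamma/trigamma terms, which are inverted to
    give (d0, s0^2).  Non-positive excess variance of the log variances
    means no evidence of heterogeneity and yields d0 = inf (complete
    shrinkage to s0^2).
    """
    var = np.asarray(variances, dtype=float)
    dfs = np.asarray(dfs, dtype=float)
    ok = (dfs > 0) & np.isfinite(var)
    var, dfs = var[ok], dfs[ok]
    if len(var) < 2:
        raise ValueError("need >= 2 positive-df variances to moderate")
    # offset degenerate zero variances away from zero
    var = np.maximum(var, 0.0)
    med = float(np.median(var))
    if med == 0:
        warnings.warn(
            "more than half of residual variances are exactly zero; "
            "moderation unreliable",
            stacklevel=2,
        )
        med = 1.0
    var = np.maximum(var, 1e-5 * med)
    z = np.log(var)
    e = z - special.digamma(dfs / 2) + np.log(dfs / 2)
    emean = float(e.mean())
    evar = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, dfs / 2)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = math.exp(
            emean + float(special.digamma(d0 / 2)) - math.log(d0 / 2)
        )
    else:
        # no excess spread of the log variances: complete shrinkage
        d0 = math.inf
        s0 = float(var.mean())
    return ModerationParams(prior_df=d0, prior_var=s0)


def moderate_variances(
    fits: list[GeneFit], params: ModerationParams | None = None
) -> tuple[ModerationParams, np.ndarray, np.ndarray]:
    """Shrink per-gene residual variances toward the common prior.

    Returns ``(params, moderated_variances, moderated_dfs)`` aligned with
    ``fits``.  Falls back to no shrinkage (d0 = 0) with a warning if the
    hyperparameter fit is not estimable.
    """
    s2 = np.array([f.residual_sd**2 for f in fits])
    dfs = np.array([f.residual_df for f in fits], dtype=float)
    if params is None:
        try:
            params = estimate_moderation(s2[dfs > 0], dfs[dfs > 0])
        except (ValueError, FloatingPointError):
            warnings.warn(
                "variance moderation not estimable; using ordinary t",
                stacklevel=2,
            )
            params = ModerationParams(prior_df=0.0, prior_var=1.0)
    d0, s0 = params.prior_df, params.prior_var
    if math.isinf(d0):
        mod_var = np.full_like(s2, s0)
        mod_df = np.full_like(dfs, math.inf)
    else:
        mod_var = (d0 * s0 + dfs * s2) / np.where(d0 + dfs > 0, d0 + dfs, 1.0)
        mod_df = d0 + dfs
    return params, mod_var, mod_df


def adjust_pvalues(p_values, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up, Bonferroni, or Holm step-down.

    Input order is preserved in the output; all adjusted values are capped
    at 1 and are >= the raw p values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    adj = np.empty_like(p)
    order = np.argsort(p, kind="stable")
    if method == "BH":
        ranked = p[order] * m / np.arange(1, m + 1)
        adj[order] = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    elif method == "bonferroni":
        adj = np.minimum(1.0, p * m)
    elif method == "holm":
        ranked = p[order] * (m - np.arange(m))
        adj[order] = np.minimum(1.0, np.maximum.accumulate(ranked))
    else:
        raise ValueError(f"unknown method {method!r}; choose from {ADJUST_METHODS}")
    return adj


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def run_tests(
    experiment: Experiment,
    reference_genes: list[str],
    control_sample: str,
    method: str = "BH",
    moderation: bool = True,
) -> pd.DataFrame:
    """Test every non-control sample against the control, per gene.

    Returns columns ``sample, target, effect, t, df, se, p_value,
    adj_p_value, significance``.  Adjustment is applied across the targets
    within each sample-vs-control comparison.
    """
    samples = list(dict.fromkeys(experiment.data["sample"]))
    if control_sample not in samples:
        raise UnknownControlError(
            f"control sample {control_sample!r} not found; samples: {samples}"
        )
    repl = per_replicate_delta_cq(experiment, reference_genes)
    frames = []
    for sample in samples:
        if sample == control_sample:
            continue
        fits = fit_gene_models(repl, sample, control_sample)
        testable = [f for f in fits if f.residual_df >= 1]
        if not testable:
            continue
        if moderation and len(testable) >= 2:
            _, mod_var, mod_df = moderate_variances(testable)
        else:
            mod_var = np.array([f.residual_sd**2 for f in testable])
            mod_df = np.array([f.residual_df for f in testable], dtype=float)
        rows = []
        for f, v, df in zip(testable, mod_var, mod_df):
            se = math.sqrt(v) * math.sqrt(1 / f.n_sample + 1 / f.n_control)
            t = f.effect / se if se > 0 else (0.0 if f.effect == 0 else math.inf * np.sign(f.effect))
            if math.isinf(df):
                p = 2.0 * float(sps.norm.sf(abs(t)))
            else:
                p = 2.0 * float(sps.t.sf(abs(t), df))
            rows.append(
                {
                    "sample": sample,
                    "target": f.target,
                    "effect": f.effect,
                    "t": t,
                    "df": df,
                    "se": se,
                    "p_value": p,
                }
            )
        frame = pd.DataFrame(rows)
        frame["adj_p_value"] = adjust_pvalues(frame["p_value"].to_numpy(), method)
        frame["significance"] = [significance_stars(p) for p in frame["adj_p_value"]]
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=[
                "sample",
                "target",
                "effect",
                "t",
                "df",
                "se",
                "p_value",
                "adj_p_value",
                "significance",
            ]
        )
    return pd.concat(frames, ignore_index=True)
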