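"""Static diagnostic plots: plate heatmap, Cq distributions, dCq/FC charts.

All figures are rendered with matplotlib's non-interactive Agg backend and
written to png/svg.  Relative quantities and fold changes are exponentiated
values, so the fold-change chart uses a logarithmic y axis by default.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


def _well_grid(data: pd.DataFrame) -> tuple[np.ndarray, list[str], list[int]]:
    """Arrange Cq values on a letter-row / number-column plate grid.

    Wells with unparseable labels fall back to an input-order grid of 12
    columns.
    """
    parsed = [WELL_RE.match(str(w)) for w in data["well"]]
    if all(parsed):
        rows = sorted({m.group(1).upper() for m in parsed})
        cols = sorted({int(m.group(2)) for m in parsed})
        grid = np.full((len(rows), len(cols)), np.nan)
        for m, cq in zip(parsed, data["cq"]):
            grid[rows.index(m.group(1).upper()), cols.index(int(m.group(2)))] = cq
        return grid, rows, cols
    n = len(data)
    ncol = 12
    nrow = int(np.ceil(n / ncol))
    grid = np.full((nrow, ncol), np.nan)
    grid.flat[:n] = data["cq"].to_numpy()
    return grid, [str(i + 1) for i in range(nrow)], list(range(1, ncol + 1))


def plate_heatmap(data: pd.DataFrame, ax=None, plate: str | None = None):
    """Heatmap of raw Cq values in their spatial plate arrangement."""
    if plate is not None:
        data = data[data["plate"] == plate]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    grid, rows, cols = _well_grid(data)
    im = ax.imshow(grid, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(cols)), [str(c) for c in cols])
    ax.set_yticks(range(len(rows)), rows)
    ax.set_title(f"Cq plate view{f' — {plate}' if plate else ''}")
    ax.figure.colorbar(im, ax=ax, label="Cq")
    return ax


def cq_density(data: pd.DataFrame, ax=None):
    """Gaussian-kernel density of Cq values, one curve per sample."""
    from scipy.stats import gaussian_kde

    if ax is None:
        _, ax = plt.subplots()
    for sample, grp in data.groupby("sample", sort=False):
        cq = grp["cq"].dropna().to_numpy()
        if len(cq) < 2 or np.ptp(cq) == 0:
            continue
        xs = np.linspace(cq.min() - 1, cq.max() + 1, 200)
        ax.plot(xs, gaussian_kde(cq)(xs), label=str(sample))
    ax.set_xlabel("Cq")
    ax.set_ylabel("density")
    ax.legend(title="sample")
    return ax


def cq_boxplot(data: pd.DataFrame, ax=None):
    """Per-sample boxplot of Cq values."""
    if ax is None:
        _, ax = plt.subplots()
    samples = list(dict.fromkeys(data["sample"]))
    values = [
        data.loc[data["sample"] == s, "cq"].dropna().to_numpy() for s in samples
    ]
    ax.boxplot(values, tick_labels=samples)
    ax.set_ylabel("Cq")
    return ax


def _dot_or_bar(frame, value_col, ylabel, ax, kind, log_y=False):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    targets = list(dict.fromkeys(frame["target"]))
    samples = list(dict.fromkeys(frame["sample"]))
    x = np.arange(len(targets), dtype=float)
    width = 0.8 / max(len(samples), 1)
    for i, sample in enumerate(samples):
        sub = frame[frame["sample"] == sample].set_index("target")
        y = sub[value_col].reindex(targets).to_numpy()
        pos = x + (i - (len(samples) - 1) / 2) * width
        if kind == "bar":
            ax.bar(pos, y, width=width, label=str(sample))
        else:
            ax.plot(pos, y, "o", label=str(sample))
    ax.set_xticks(x, targets, rotation=45, ha="right")
    ax.set_ylabel(ylabel)
    if log_y:
        ax.set_yscale("log")
    ax.legend(title="sample")
    return ax


def neg_delta_cq_plot(delta_table: pd.DataFrame, ax=None, kind: str = "dot"):
    """-dCq per gene and sample (dot plot by default, bar optional)."""
    return _dot_or_bar(delta_table, "neg_delta_cq", "-dCq", ax, kind)


def fold_change_plot(ddcq_table: pd.DataFrame, ax=None, kind: str = "dot", log_y: bool = True):
    """Fold change per gene and sample; y axis logarithmic by default."""
    return _dot_or_bar(ddcq_table, "fc", "fold change", ax, kind, log_y=log_y)


def render_plots(bundle, output_dir, formats=("png",)) -> list[Path]:
    """Render every applicable chart of a result bundle to image files."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(name: str, maker) -> None:
        try:
            ax = maker()
        except Exception as exc:  # plot-level failures must not kill a run
            warnings.warn(f"plot {name!r} skipped: {exc}", stacklevel=2)
            return
        for fmt in formats:
            path = out / f"{name}.{fmt}"
            ax.figure.savefig(path, format=fmt, bbox_inches="tight")
            written.append(path)
        plt.close(ax.figure)

    data = bundle.experiment.data
    for plate in bundle.experiment.plate_ids:
        save(f"plate_heatmap_{plate}", lambda p=plate: plate_heatmap(data, plate=p))
    save("cq_density", lambda: cq_density(data))
    save("cq_boxplot", lambda: cq_boxplot(data))
    save("neg_dcq_dot", lambda: neg_delta_cq_plot(bundle.delta_cq))
    if bundle.ddcq is not None:
        save("fc_dot", lambda: fold_change_plot(bundle.ddcq))
        save("fc_bar", lambda: fold_change_plot(bundle.ddcq, kind="bar"))
    return written
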