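"""Reading instrument Cq export files into a canonical experiment table.

qPCR instrument software exports one delimited text file per plate, one row
per well, with at least a sample name, a target (gene/primer assay) name and
the quantification cycle (Cq, also printed Ct or Cp).  Vendors disagree on
the delimiter, the decimal mark and the column vocabulary, so this module
sniffs the dialect, maps synonymous headers onto canonical names and returns
a tidy table with columns ``plate, well, sample, target, cq, replicate``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateWellError,
    MissingColumnError,
    ModeMismatchError,
    UnparseableFileError,
)

#: Canonical tidy column order used throughout the package.
COLUMNS = ["plate", "well", "sample", "target", "cq", "replicate"]

SINGLE_PLATE = "single_plate"
MULTI_PLATE = "multi_plate"

# Header synonyms, compared after lowercasing and stripping spaces,
# underscores and dots.  Covers qPCRsoft, Bio-Rad CFX, Applied Biosystems
# and Roche LightCycler vocabularies.
SYNONYMS: dict[str, tuple[str, ...]] = {
    "well": ("well", "pos", "position"),
    "sample": ("sample", "samplename", "content", "name"),
    "target": (
        "target",
        "gene",
        "detector",
        "targetname",
        "genename",
        "primer",
        "assay",
    ),
    "cq": ("cq", "ct", "cp", "cqvalue", "ctvalue", "cqmean", "ctmean"),
}

#: Cell contents treated as a missing Cq (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "n/a", "undetermined", "no cq", "-"})


@dataclass(frozen=True)
class Dialect:
    """A sniffed file dialect: field delimiter and decimal mark."""

    delimiter: str
    decimal: str = "."


@dataclass
class Experiment:
    """An ordered collection of well records from one or more plates.

    Attributes
    ----------
    data:
        Tidy frame with columns ``plate, well, sample, target, cq,
        replicate``.  ``replicate`` numbers technical replicates within a
        (plate, sample, target) group in file order, starting at 1.
    mode:
        ``"single_plate"`` or ``"multi_plate"``.
    """

    data: pd.DataFrame
    mode: str = SINGLE_PLATE

    def __post_init__(self) -> None:
        if self.mode not in (SINGLE_PLATE, MULTI_PLATE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == SINGLE_PLATE and self.data["plate"].nunique() > 1:
            raise ModeMismatchError(
                "single_plate mode but multiple plates present: "
                f"{sorted(self.data['plate'].unique())}"
            )

    @property
    def plate_ids(self) -> list[str]:
        """Plate labels in input order."""
        return list(dict.fromkeys(self.data["plate"]))

    @property
    def targets(self) -> list[str]:
        return list(dict.fromkeys(self.data["target"]))

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    def copy(self) -> "Experiment":
        return Experiment(self.data.copy(), self.mode)


def _normalise_header(name: str) -> str:
    return "".join(ch for ch in name.strip().lower() if ch not in " _.\"'")


def detect_dialect(raw_text: str, filename: str = "<string>") -> Dialect:
    """Sniff delimiter and decimal mark from raw file text.

    The delimiter is the candidate (tab, comma, semicolon) that splits the
    header line into the most fields, requiring at least two.  A decimal
    comma is assumed only for semicolon-delimited files whose data cells
    match the ``digits,digits`` pattern — in comma-delimited files that
    pattern is indistinguishable from two fields.
    """
    lines = raw_text.splitlines()
    if not lines or not raw_text.strip():
        raise UnparseableFileError(f"{filename}: empty file")
    header = lines[0]
    counts = {d: len(header.split(d)) for d in ("\t", ",", ";")}
    delimiter = max(counts, key=lambda d: counts[d])
    if counts[delimiter] < 2:
        raise UnparseableFileError(
            f"{filename}: no tab, comma or semicolon splits the header "
            f"into two or more fields"
        )
    decimal = "."
    if delimiter == ";":
        import re

        pat = re.compile(r"^\d+,\d+$")
        cells = (
            cell.strip()
            for line in lines[1:]
            for cell in line.split(";")
        )
        if any(pat.match(c) for c in cells):
            decimal = ","
    return Dialect(delimiter, decimal)


def map_column_names(header_fields: Sequence[str]) -> dict[str, int]:
    """Resolve canonical names {well, sample, target, cq} to column indices.

    Matching is case-insensitive and ignores spaces, underscores and dots.
    ``sample``, ``target`` and ``cq`` are required; ``well`` is optional
    (wells are auto-numbered when absent).  Extra columns are ignored.
    """
    normalised = [_normalise_header(h) for h in header_fields]
    mapping: dict[str, int] = {}
    for canonical, synonyms in SYNONYMS.items():
        for idx, name in enumerate(normalised):
            if name in synonyms and idx not in mapping.values():
                mapping[canonical] = idx
                break
    missing = [k for k in ("sample", "target", "cq") if k not in mapping]
    if missing:
        raise MissingColumnError(
            f"could not resolve required column(s) {missing} from header "
            f"{list(header_fields)}; recognised synonyms: "
            + "; ".join(f"{k}: {v}" for k, v in SYNONYMS.items())
        )
    return mapping


def _parse_cq(cell: object, decimal: str) -> float:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    text = str(cell).strip()
    if text.lower() in MISSING_TOKENS:
        return np.nan
    if decimal == ",":
        text = text.replace(",", ".")
    try:
        return float(text)
    except ValueError:
        return np.nan


def parse_plate_file(
    path: str | Path | io.StringIO,
    plate_id: str | None = None,
) -> pd.DataFrame:
    """Parse one plate export into a tidy record frame.

    Non-numeric Cq cells (``NA``, ``Undetermined``, ``-`` ...) become
    missing.  A numeric Cq <= 0 is physically meaningless and is turned
    missing with a warning.  Row order is preserved; technical replicates
    are numbered in file order within each (sample, target) group.
    """
    if isinstance(path, io.StringIO):
        raw = path.getvalue()
        name = plate_id or "<buffer>"
    else:
        path = Path(path)
        raw = path.read_text(encoding="utf-8-sig")
        name = path.name
    if plate_id is None:
        plate_id = Path(name).stem

    dialect = detect_dialect(raw, filename=name)
    table = pd.read_csv(
        io.StringIO(raw), sep=dialect.delimiter, dtype=str, engine="python"
    )
    colmap = map_column_names(list(table.columns))
    if table.empty:
        warnings.warn(f"{name}: header only, no data rows", stacklevel=2)
        return pd.DataFrame(columns=COLUMNS)

    out = pd.DataFrame(
        {
            "plate": plate_id,
            "sample": table.iloc[:, colmap["sample"]].astype(str).str.strip(),
            "target": table.iloc[:, colmap["target"]].astype(str).str.strip(),
            "cq": [
                _parse_cq(c, dialect.decimal)
                for c in table.iloc[:, colmap["cq"]]
            ],
        }
    )
    if "well" in colmap:
        out.insert(1, "well", table.iloc[:, colmap["well"]].astype(str).str.strip())
    else:
        out.insert(1, "well", [f"W{i + 1}" for i in range(len(out))])

    dupes = out["well"][out["well"].duplicated()]
    if not dupes.empty:
        raise DuplicateWellError(
            f"{name}: duplicate well label(s) {sorted(set(dupes))}"
        )

    nonpositive = out["cq"].notna() & (out["cq"] <= 0)
    if nonpositive.any():
        warnings.warn(
            f"{name}: {int(nonpositive.sum())} Cq value(s) <= 0 treated as "
            "missing",
            stacklevel=2,
        )
        out.loc[nonpositive, "cq"] = np.nan

    out["replicate"] = out.groupby(["sample", "target"]).cumcount() + 1
    return out[COLUMNS]


def load_experiment(
    paths: Iterable[str | Path],
    mode: str = SINGLE_PLATE,
) -> Experiment:
    """Load one or more plate files into an :class:`Experiment`.

    The plate label defaults to the file name stem; duplicate stems get an
    ordinal suffix so that plate labels stay unique and reproducible.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input files given")
    if mode == SINGLE_PLATE and len(paths) > 1:
        raise ModeMismatchError(
            f"single_plate mode accepts exactly one file, got {len(paths)}"
        )
    seen: dict[str, int] = {}
    frames = []
    for p in paths:
        stem = p.stem
        if stem in seen:
            seen[stem] += 1
            plate_id = f"{stem}_{seen[stem]}"
        else:
            seen[stem] = 1
            plate_id = stem
        frames.append(parse_plate_file(p, plate_id=plate_id))
    data = pd.concat(frames, ignore_index=True)
    return Experiment(data, mode=mode)


def write_experiment_csv(experiment: Experiment, path: str | Path) -> None:
    """Export the canonical tidy table (UTF-8, comma, point decimal)."""
    experiment.data.drop(columns=["replicate"]).to_csv(path, index=False)
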