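"""Reading, validation and writing of the screen's tabular formats.

The deposited screen is a long-format table with one row per assay well and
columns ``Bait_ECD``, ``Prey_ECD`` and ``Abs_650_nm``: the bait receptor
ectodomain coated on the plate, the prey ectodomain applied in solution, and
the colorimetric readout at 650 nm.  Orientation matters — the well (A, B)
with A as bait is a different measurement from (B, A) — so the assembled
matrix is never assumed symmetric.

Matrices (absorbance, residuals, scores) are plain :class:`pandas.DataFrame`
objects with bait identifiers on the index and prey identifiers on the
columns; missing wells are ``NaN`` in memory and ``NA`` on disk.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("Bait_ECD", "Prey_ECD", "Abs_650_nm")

#: Token used for missing cells in every TSV this package writes.
NA_TOKEN = "NA"


class ScreenFormatError(ValueError):
    """A structural problem with an input file (missing column, bad value)."""


class InteractionRecord(NamedTuple):
    """One well of the screen: bait identifier, prey identifier, A650 value."""

    bait_id: str
    prey_id: str
    absorbance: float


def _sniff_delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    return "\t"


def read_long_format(
    path: str | Path, dialect: str | None = None
) -> list[InteractionRecord]:
    """Read a long-format screen file into a list of records.

    Parameters
    ----------
    path
        TSV (default) or CSV file whose header contains the three required
        columns ``Bait_ECD``, ``Prey_ECD``, ``Abs_650_nm``.  Extra columns
        are ignored with a warning.
    dialect
        ``"tsv"`` or ``"csv"``; inferred from the file extension if omitted.

    Raises
    ------
    ScreenFormatError
        If a required column is missing, or a data row carries a non-numeric
        or negative absorbance (the error message names the line number).
    """
    path = Path(path)
    sep = _sniff_delimiter(path, dialect)
    records: list[InteractionRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ScreenFormatError(f"{path}: empty file, no header row")
        header = [h.strip() for h in header]
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise ScreenFormatError(
                    f"{path}: required column {col!r} missing from header {header}"
                )
        extra = [h for h in header if h not in REQUIRED_COLUMNS]
        if extra:
            logger.warning("%s: ignoring extra columns %s", path, extra)
        idx = {col: header.index(col) for col in REQUIRED_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            bait = row[idx["Bait_ECD"]].strip().upper()
            prey = row[idx["Prey_ECD"]].strip().upper()
            raw = row[idx["Abs_650_nm"]].strip()
            if not bait or not prey:
                raise ScreenFormatError(
                    f"{path}:{lineno}: empty bait or prey identifier"
                )
            try:
                value = float(raw)
            except ValueError:
                raise ScreenFormatError(
                    f"{path}:{lineno}: non-numeric absorbance {raw!r}"
                ) from None
            if not math.isfinite(value) or value < 0:
                raise ScreenFormatError(
                    f"{path}:{lineno}: absorbance must be finite and >= 0, "
                    f"got {raw!r}"
                )
            records.append(InteractionRecord(bait, prey, value))
    logger.info("%s: read %d interaction records", path, len(records))
    return records


def write_long_format(
    records: Iterable[InteractionRecord], path: str | Path
) -> None:
    """Write records in the canonical long TSV format (round-trips reads)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for rec in records:
            writer.writerow([rec.bait_id, rec.prey_id, f"{rec.absorbance:.10g}"])


def assemble_matrix(
    records: list[InteractionRecord], duplicate_policy: str = "error"
) -> pd.DataFrame:
    """Assemble orientation-resolved records into a bait x prey matrix.

    Rows are the sorted distinct bait identifiers, columns the sorted
    distinct prey identifiers; unmeasured (bait, prey) combinations are NaN.

    Parameters
    ----------
    records
        At least one record.
    duplicate_policy
        ``"error"`` (default — the screen yields one value per ordered pair)
        raises if any (bait, prey) pair occurs more than once, naming the
        pair; ``"mean"`` averages duplicates and logs how many were
        collapsed.
    """
    if not records:
        raise ValueError("assemble_matrix requires at least one record")
    if duplicate_policy not in ("error", "mean"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    df = pd.DataFrame(records, columns=["bait_id", "prey_id", "absorbance"])
    dup_mask = df.duplicated(subset=["bait_id", "prey_id"], keep=False)
    if dup_mask.any():
        if duplicate_policy == "error":
            pair = df.loc[dup_mask, ["bait_id", "prey_id"]].iloc[0]
            raise ValueError(
                "duplicate measurement for (bait, prey) pair "
                f"({pair.bait_id}, {pair.prey_id}) with duplicate_policy='error'"
            )
        n_dup = int(dup_mask.sum())
        logger.info("collapsing %d duplicate records by mean", n_dup)
    matrix = df.pivot_table(
        index="bait_id", columns="prey_id", values="absorbance", aggfunc="mean"
    )
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    matrix.index.name = "bait_id"
    matrix.columns.name = "prey_id"
    return matrix


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV: bait ids in the first column, prey ids as header.

    Values are written with 10 significant digits so a write/read cycle is
    lossless to well below 1e-9; missing cells are serialized as ``NA``.
    """
    matrix.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.10g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a matrix TSV written by :func:`write_matrix`."""
    matrix = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False
    )
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    matrix.index.name = "bait_id"
    matrix.columns.name = "prey_id"
    return matrix.astype(float)


EDGE_LIST_COLUMNS = (
    "id_a",
    "id_b",
    "score_bait_prey",
    "score_prey_bait",
    "geometric_mean_score",
    "class",
)


def write_edge_list(
    hits: pd.DataFrame, path: str | Path, which: str = "all"
) -> None:
    """Write a hit table as an interaction edge list TSV.

    Parameters
    ----------
    hits
        Hit table from :func:`ecia.scoring.call_hits` (columns ``id_a``,
        ``id_b``, ``score_ab``, ``score_ba``, ``geo_mean_score``,
        ``hit_class``).
    which
        ``"bidirectional"``, ``"unidirectional"`` or ``"all"`` — which
        classes to emit.  ``"all"`` emits bidirectional and unidirectional
        pairs (never the ``none`` class).
    """
    if which not in ("bidirectional", "unidirectional", "all"):
        raise ValueError(f"unknown selection {which!r}")
    if which == "all":
        selected = hits[hits["hit_class"].isin(["bidirectional", "unidirectional"])]
    else:
        selected = hits[hits["hit_class"] == which]
    out = pd.DataFrame(
        {
            "id_a": selected["id_a"],
            "id_b": selected["id_b"],
            "score_bait_prey": selected["score_ab"],
            "score_prey_bait": selected["score_ba"],
            "geometric_mean_score": selected["geo_mean_score"],
            "class": selected["hit_class"],
        }
    )
    out.to_csv(
        path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.10g"
    )


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an edge-list TSV back into hit-table form.

    Returns a frame with the in-memory hit-table column names (``score_ab``,
    ``score_ba``, ``geo_mean_score``, ``hit_class``).
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    missing = set(EDGE_LIST_COLUMNS) - set(df.columns)
    if missing:
        raise ScreenFormatError(
            f"{path}: edge list missing column(s) {sorted(missing)}"
        )
    return df.rename(
        columns={
            "score_bait_prey": "score_ab",
            "score_prey_bait": "score_ba",
            "geometric_mean_score": "geo_mean_score",
            "class": "hit_class",
        }
    )
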