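"""Tabular I/O for Ct matrices, sample metadata and result tables.

The on-disk convention is plain UTF-8 CSV/TSV with assays in rows and
samples in columns (the qPCR panel layout).  Lines starting with ``#`` are
comments and are ignored on read; result tables carry their provenance
(package version, seed, config hash) as such comment lines so the files
stay machine-parsable.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_LABELS",
    "CtMatrix",
    "SampleTable",
    "ResultTable",
    "read_ct_matrix",
    "write_ct_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_result_table",
    "write_result_table",
]

#: Closed vocabulary of clinical group labels: healthy controls plus
#: bladder-tumor stage/grade combinations (Ta/T1 = non-muscle-invasive,
#: T2/T3 = muscle-invasive; G1-G3 = grade).
GROUP_LABELS = (
    "control",
    "TaG1",
    "TaG2",
    "TaG3",
    "T1G2",
    "T1G3",
    "T2G2",
    "T2G3",
    "T3G3",
)

DEFAULT_NA_TOKENS = frozenset({"", "NA", "Undetermined"})

_CT_PRECISION = 4  # decimals used when writing Ct values


class FormatError(ValueError):
    """Raised when a file violates the tabular contract."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass
class CtMatrix:
    """Assays x samples grid of quantification-cycle (Ct) values.

    ``detected`` is a parallel boolean mask; ``False`` marks wells the
    instrument reported as undetermined (no amplification).  Undetected
    cells carry ``nan`` in ``values``.
    """

    assay_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    detected: np.ndarray

    def __post_init__(self) -> None:
        self.assay_ids = list(self.assay_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        n_a, n_s = len(self.assay_ids), len(self.sample_ids)
        if self.values.shape != (n_a, n_s):
            raise FormatError(
                f"value grid shape {self.values.shape} != ({n_a}, {n_s})"
            )
        if self.detected.shape != (n_a, n_s):
            raise FormatError("detected mask shape mismatch")
        _check_unique(self.assay_ids, "assay")
        _check_unique(self.sample_ids, "sample")
        if any(not a for a in self.assay_ids):
            raise FormatError("empty assay id")
        det = self.values[self.detected]
        if det.size and not (np.isfinite(det).all() and (det > 0).all()):
            raise FormatError("detected Ct values must be finite and > 0")

    @property
    def n_assays(self) -> int:
        return len(self.assay_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def assay_index(self, assay_id: str) -> int:
        try:
            return self.assay_ids.index(assay_id)
        except ValueError:
            raise KeyError(f"assay {assay_id!r} not in matrix") from None

    def subset(
        self,
        assays: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "CtMatrix":
        """Restrict to the given assays/samples, preserving the given order."""
        a_idx = (
            [self.assay_index(a) for a in assays]
            if assays is not None
            else list(range(self.n_assays))
        )
        if samples is not None:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            try:
                s_idx = [pos[s] for s in samples]
            except KeyError as exc:
                raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None
        else:
            s_idx = list(range(self.n_samples))
        return CtMatrix(
            [self.assay_ids[i] for i in a_idx],
            [self.sample_ids[j] for j in s_idx],
            self.values[np.ix_(a_idx, s_idx)].copy(),
            self.detected[np.ix_(a_idx, s_idx)].copy(),
        )

    def row(self, assay_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, detected) for one assay across all samples."""
        i = self.assay_index(assay_id)
        return self.values[i], self.detected[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.assay_ids, columns=self.sample_ids
        )

    def copy(self) -> "CtMatrix":
        return CtMatrix(
            list(self.assay_ids),
            list(self.sample_ids),
            self.values.copy(),
            self.detected.copy(),
        )


@dataclass
class SampleTable:
    """Per-sample clinical annotations.

    Columns: ``sample_id``, ``group`` (from :data:`GROUP_LABELS`),
    ``cohort`` ({screening, validation}) and optional ``plate_id``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"sample_id", "group", "cohort"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise FormatError("no samples")
        _check_unique(list(df["sample_id"]), "sample")
        bad = sorted(set(df["group"]) - set(GROUP_LABELS))
        if bad:
            raise FormatError(f"unknown group label(s): {bad}")
        if "plate_id" not in df.columns:
            df = df.assign(plate_id=pd.NA)
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def group_of(self) -> Mapping[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["group"]))

    def plate_of(self) -> Mapping[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["plate_id"]))

    def samples_in_group(self, group: str) -> list[str]:
        df = self.frame
        return list(df.loc[df["group"] == group, "sample_id"])

    def bc_samples(self) -> list[str]:
        """All tumor samples pooled (every group except control)."""
        df = self.frame
        return list(df.loc[df["group"] != "control", "sample_id"])

    def control_samples(self) -> list[str]:
        return self.samples_in_group("control")

    def has_plates(self) -> bool:
        return self.frame["plate_id"].notna().all()


@dataclass
class ResultTable:
    """A named numeric result table plus provenance metadata.

    ``frame`` holds the rows (first column is the row key: assay or group);
    ``provenance`` is emitted as ``#``-prefixed comment lines.
    """

    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "rank" in self.frame.columns:
            r = np.asarray(self.frame["rank"], dtype=float)
            # a midpoint-tied ranking of 1..n preserves the rank sum
            if len(r) and not math.isclose(r.sum(), len(r) * (len(r) + 1) / 2):
                raise FormatError("rank column is not a valid tied ranking")


# ---------------------------------------------------------------------------
# Ct matrix I/O


def _sep(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise ValueError(f"unknown dialect {dialect!r} (expected 'csv' or 'tsv')")


def read_ct_matrix(
    path: str | Path,
    dialect: str = "csv",
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
    transpose: bool = False,
) -> CtMatrix:
    """Parse a wide Ct matrix: first column assay ids, header sample ids.

    Cells matching ``na_tokens`` become undetected wells.  Duplicate ids and
    non-numeric cells are hard errors naming the offending row/column; the
    orientation is never guessed — pass ``transpose=True`` for
    samples-in-rows exports.
    """
    na = set(na_tokens)
    raw = pd.read_csv(
        path,
        sep=_sep(dialect),
        header=None,
        comment="#",
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=True,
        engine="python",
    )
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise FormatError(f"{path}: need a header row and at least one data row")
    header = [str(x).strip() for x in raw.iloc[0, 1:]]
    row_ids = [str(x).strip() for x in raw.iloc[1:, 0]]
    _check_unique(header, "column")
    _check_unique(row_ids, "row")
    body = raw.iloc[1:, 1:].to_numpy(dtype=object)
    values = np.full(body.shape, np.nan)
    detected = np.zeros(body.shape, dtype=bool)
    for i in range(body.shape[0]):
        for j in range(body.shape[1]):
            cell = str(body[i, j]).strip()
            if cell in na:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{row_ids[i]!r}, column {header[j]!r}"
                ) from None
            detected[i, j] = True
    if transpose:
        return CtMatrix(header, row_ids, values.T, detected.T)
    return CtMatrix(row_ids, header, values, detected)


def write_ct_matrix(
    ct: CtMatrix, path: str | Path, dialect: str = "csv"
) -> None:
    """Write a Ct matrix; undetected wells serialize as ``Undetermined``."""
    sep = _sep(dialect)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("assay_id" + sep + sep.join(ct.sample_ids) + "\n")
        for i, assay in enumerate(ct.assay_ids):
            cells = [
                f"{ct.values[i, j]:.{_CT_PRECISION}f}"
                if ct.detected[i, j]
                else "Undetermined"
                for j in range(ct.n_samples)
            ]
            fh.write(assay + sep + sep.join(cells) + "\n")


# ---------------------------------------------------------------------------
# Sample table I/O


def read_sample_table(path: str | Path, dialect: str = "csv") -> SampleTable:
    try:
        df = pd.read_csv(
            path,
            sep=_sep(dialect),
            comment="#",
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no samples") from None
    if len(df) == 0:
        raise FormatError(f"{path}: no samples")
    if "plate_id" in df.columns:
        df["plate_id"] = df["plate_id"].replace("", pd.NA)
    return SampleTable(df)


def write_sample_table(
    table: SampleTable, path: str | Path, dialect: str = "csv"
) -> None:
    df = table.frame.copy()
    df["plate_id"] = df["plate_id"].fillna("")
    df.to_csv(path, sep=_sep(dialect), index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Result table I/O


def write_result_table(
    table: ResultTable, path: str | Path, dialect: str = "csv"
) -> None:
    """Serialize deterministically: provenance header, rows sorted by rank
    then row key, numbers at 6 significant digits."""
    df = table.frame.copy()
    key_col = df.columns[0]
    if "rank" in df.columns:
        df = df.sort_values(["rank", key_col], kind="mergesort")
    else:
        df = df.sort_values(key_col, kind="mergesort")
    buf = io.StringIO()
    for k in sorted(table.provenance):
        buf.write(f"# {k}: {table.provenance[k]}\n")
    sep = _sep(dialect)
    buf.write(sep.join(df.columns) + "\n")
    for _, row in df.iterrows():
        cells = []
        for col in df.columns:
            v = row[col]
            if isinstance(v, (int, np.integer)):
                cells.append(str(int(v)))
            elif isinstance(v, (float, np.floating)):
                cells.append("nan" if not np.isfinite(v) else f"{v:.6g}")
            else:
                cells.append(str(v))
        buf.write(sep.join(cells) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def read_result_table(path: str | Path, dialect: str = "csv") -> ResultTable:
    provenance: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                provenance[k.strip()] = v.strip()
    df = pd.read_csv(path, sep=_sep(dialect), comment="#")
    return ResultTable(df, provenance)
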