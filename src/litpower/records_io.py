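"""Data model for extracted statistical records and CSV readers/writers.

A :class:`StatRecord` is one reported t-test: degrees of freedom, the t
statistic, and, when reported, a p-value (with its comparator, since the
literature writes ``p = .02`` as well as ``p < .05``) and a Cohen's d.
Records travel through the pipeline as plain CSV with a fixed header:

    paper_id, journal_id, df, t, p_cmp, p, d, line_source

Absent optional fields are empty cells, never sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical CSV column order
COLUMNS = ["paper_id", "journal_id", "df", "t", "p_cmp", "p", "d", "line_source"]

#: the three journal subfield labels used throughout
SUBFIELDS = ("neuroscience", "psychology", "medical")

#: accepted p-value comparator tags
P_COMPARATORS = ("=", "<", ">")


class RecordFormatError(ValueError):
    """A records table is missing a mandatory column or is malformed."""


class RowParseError(ValueError):
    """A single row of a records table could not be parsed.

    Carries the zero-based data-row index as :attr:`row`.
    """

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class StatRecord:
    """One extracted t-test report.

    ``df`` and ``t_value`` are mandatory; the reported p (with comparator
    tag), reported Cohen's d and the raw matched line are optional.
    Construction does not validate ``df >= 1`` or ``p > 0`` so that dirty
    input can be represented and then dropped, with a reason, by
    :func:`litpower.extraction.clean_records`.
    """

    df: int
    t_value: float
    paper_id: str | None = None
    journal_id: str | None = None
    p_cmp: str | None = None
    p_reported: float | None = None
    d_reported: float | None = None
    line_source: str | None = None

    def stat_key(self) -> tuple:
        """The statistical fields only — used for duplicate detection."""
        return (self.df, self.t_value, self.p_cmp, self.p_reported, self.d_reported)


@dataclass(frozen=True)
class JournalMeta:
    """Journal metadata: subfield label and 2014 five-year impact factor."""

    journal_id: str
    name: str
    subfield: str
    impact_factor_5yr: float

    def __post_init__(self):
        if self.subfield not in SUBFIELDS:
            raise ValueError(
                f"subfield must be one of {SUBFIELDS}, got {self.subfield!r}"
            )
        if not self.impact_factor_5yr > 0:
            raise ValueError("impact_factor_5yr must be > 0")


def records_to_frame(records: Iterable[StatRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame in canonical column order."""
    rows = []
    for r in records:
        rows.append(
            {
                "paper_id": r.paper_id,
                "journal_id": r.journal_id,
                "df": r.df,
                "t": r.t_value,
                "p_cmp": r.p_cmp,
                "p": r.p_reported,
                "d": r.d_reported,
                "line_source": r.line_source,
            }
        )
    frame = pd.DataFrame(rows, columns=COLUMNS)
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[StatRecord]:
    """Convert a canonical-column DataFrame back to records (order preserved)."""
    for col in ("df", "t"):
        if col not in frame.columns:
            raise RecordFormatError(f"missing mandatory column {col!r}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        d = row._asdict()
        try:
            df_val = int(d["df"])
            t_val = float(d["t"])
        except (TypeError, ValueError) as exc:
            raise RowParseError(i, f"unparseable numeric cell: {exc}") from None
        records.append(
            StatRecord(
                df=df_val,
                t_value=t_val,
                paper_id=_opt_str(d.get("paper_id")),
                journal_id=_opt_str(d.get("journal_id")),
                p_cmp=_opt_str(d.get("p_cmp")),
                p_reported=_opt_float(i, d.get("p")),
                d_reported=_opt_float(i, d.get("d")),
                line_source=_opt_str(d.get("line_source")),
            )
        )
    return records


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value)
    return s if s != "" else None


def _opt_float(row: int, value) -> float | None:
    if value is None or value == "":
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise RowParseError(row, f"unparseable numeric cell: {exc}") from None


def read_records(path: str | Path, fmt: str = "csv") -> list[StatRecord]:
    """Read a records table.

    Requires a header naming at least ``df`` and ``t``. Optional columns
    that are absent or empty come back as ``None`` on the record. Row
    order is preserved.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported format {fmt!r}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("df", "t"):
        if col not in frame.columns:
            raise RecordFormatError(f"missing mandatory column {col!r} in {path}")
    return frame_to_records(frame)


def write_records(records: Sequence[StatRecord], path: str | Path, fmt: str = "csv") -> None:
    """Write records as canonical CSV; absent fields become empty cells."""
    if fmt != "csv":
        raise ValueError(f"unsupported format {fmt!r}")
    frame = records_to_frame(records)
    frame.to_csv(path, index=False)


def read_journals(path: str | Path) -> list[JournalMeta]:
    """Read journal metadata CSV: journal_id, name, subfield, impact_factor_5yr."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = {"journal_id", "name", "subfield", "impact_factor_5yr"}
    missing = needed - set(frame.columns)
    if missing:
        raise RecordFormatError(f"missing mandatory column(s) {sorted(missing)} in {path}")
    return [
        JournalMeta(
            journal_id=row.journal_id,
            name=row.name,
            subfield=row.subfield,
            impact_factor_5yr=float(row.impact_factor_5yr),
        )
        for row in frame.itertuples(index=False)
    ]


def write_journals(journals: Sequence[JournalMeta], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(j) for j in journals]).to_csv(path, index=False)


def load_mat_records(path: str | Path) -> tuple[list[StatRecord], dict]:
    """Adapter for a deposited MATLAB ``.mat`` archive of t-test records.

    The internal variable layout of such archives is not standardised, so
    the adapter discovers it: it looks for 2-D numeric arrays, prefers
    variables whose names hint at df/t content, and guesses the column
    roles (df: positive integers; t: signed decimals; p: values in (0, 1])
    when a single matrix holds everything. The mapping actually used is
    logged and returned so callers can audit it.
    """
    from scipy.io import loadmat

    raw = loadmat(path)
    arrays = {
        k: np.asarray(v)
        for k, v in raw.items()
        if not k.startswith("__") and np.asarray(v).dtype.kind in "fiu"
    }
    if not arrays:
        raise RecordFormatError(f"no numeric variables found in {path}")

    mapping: dict = {"source": str(path)}
    named = {k.lower(): k for k in arrays}

    def _col(name_hints):
        for hint in name_hints:
            if hint in named:
                return arrays[named[hint]].ravel().astype(float)
        return None

    df_col = _col(["df", "dfs", "degrees_of_freedom"])
    t_col = _col(["t", "ts", "tval", "tvals", "t_values"])
    p_col = _col(["p", "ps", "pval", "pvals", "p_values"])

    if df_col is None or t_col is None:
        # fall back: single matrix with records in rows
        matrices = [a for a in arrays.values() if a.ndim == 2 and min(a.shape) >= 2]
        if not matrices:
            raise RecordFormatError(
                f"could not identify df/t variables in {path}; "
                f"variables present: {sorted(arrays)}"
            )
        mat = max(matrices, key=lambda a: a.size)
        if mat.shape[0] < mat.shape[1]:
            mat = mat.T
        df_idx = t_idx = p_idx = None
        for j in range(mat.shape[1]):
            col = mat[:, j]
            finite = col[np.isfinite(col)]
            if df_idx is None and finite.size and np.all(finite > 0) and np.allclose(finite, np.round(finite)):
                df_idx = j
            elif p_idx is None and finite.size and np.all((finite > 0) & (finite <= 1)):
                p_idx = j
            elif t_idx is None:
                t_idx = j
        if df_idx is None or t_idx is None:
            raise RecordFormatError(f"could not assign df/t columns of matrix in {path}")
        df_col, t_col = mat[:, df_idx], mat[:, t_idx]
        p_col = mat[:, p_idx] if p_idx is not None else None
        mapping["matrix_columns"] = {"df": df_idx, "t": t_idx, "p": p_idx}
    else:
        mapping["variables"] = {
            "df": named.get("df") or named.get("dfs"),
            "t": named.get("t") or named.get("ts") or named.get("tval") or named.get("tvals"),
            "p": named.get("p") or named.get("ps") or named.get("pval") or named.get("pvals"),
        }

    logger.info("MAT adapter mapping for %s: %s", path, mapping)
    records = []
    for i in range(len(df_col)):
        p_val = None
        if p_col is not None and np.isfinite(p_col[i]):
            p_val = float(p_col[i])
        records.append(
            StatRecord(
                df=int(round(float(df_col[i]))),
                t_value=float(t_col[i]),
                p_cmp="=" if p_val is not None else None,
                p_reported=p_val,
            )
        )
    return records, mapping
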