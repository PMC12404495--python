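"""CSV ingestion, variable selection and descriptive statistics.

The input contract mirrors the common qPCR-export dialect: a plain-text
RFC-4180 CSV with a mandatory header row of unique column names, one row
per sample, numeric Ct columns for the target and the normalizer, and
either a binary group column (two-group comparison) or a numeric
explanatory column (regression).  Extra columns (sample IDs, notes) are
carried along but not analyzed.

Parsing is done with the stdlib :mod:`csv` reader so that structural
problems — ragged rows, duplicate headers, oversize files — surface as
precise :class:`~ctot.errors.DataValidationError`\\ s rather than being
silently repaired.
"""

from __future__ import annotations

import csv
import io
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import DataValidationError

__all__ = [
    "QPCRTable",
    "AnalysisFrame",
    "DescriptiveSummary",
    "read_table",
    "select_variables",
    "parse_group",
    "describe",
    "DEFAULT_CUTOFF",
    "DEFAULT_MAX_BYTES",
]

DEFAULT_CUTOFF = 40.0
DEFAULT_MAX_BYTES = 10 * 1024 * 1024  # 10 MB file cap, configurable


@dataclass
class QPCRTable:
    """A rectangular, header-named table of text cells."""

    column_names: list[str]
    rows: list[list[str]]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list[str]:
        try:
            idx = self.column_names.index(name)
        except ValueError:
            raise DataValidationError(
                f"column {name!r} not found; available: {self.column_names}"
            ) from None
        return [row[idx] for row in self.rows]

    def to_csv(self, path_or_stream) -> None:
        """Write the table back out; re-reading reproduces identical cells."""
        own = isinstance(path_or_stream, (str, os.PathLike))
        stream = open(path_or_stream, "w", newline="", encoding="utf-8") if own else path_or_stream
        try:
            # quote everything so even empty single-cell rows survive a
            # write/read round trip byte-exactly
            writer = csv.writer(stream, lineterminator="\n", quoting=csv.QUOTE_ALL)
            writer.writerow(self.column_names)
            writer.writerows(self.rows)
        finally:
            if own:
                stream.close()


@dataclass
class AnalysisFrame:
    """Validated per-sample analysis variables plus the Ct cutoff.

    Exactly one of ``group`` (0/1 indicator array) and ``covariate``
    (float array) is set; this decides two-group versus regression mode.
    """

    ct: np.ndarray
    normalizer_ct: np.ndarray
    cutoff: float
    group: Optional[np.ndarray] = None
    covariate: Optional[np.ndarray] = None
    group_levels: Optional[tuple[str, str]] = None
    sample_id: Optional[list[str]] = None
    n_dropped: int = 0
    variable_names: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.group is None) == (self.covariate is None):
            raise DataValidationError(
                "exactly one of group / covariate must be provided"
            )
        self.ct = np.asarray(self.ct, dtype=float)
        self.normalizer_ct = np.asarray(self.normalizer_ct, dtype=float)
        if self.ct.shape != self.normalizer_ct.shape:
            raise DataValidationError("ct and normalizer_ct must have equal length")
        if not np.all(np.isfinite(self.ct)) or not np.all(np.isfinite(self.normalizer_ct)):
            raise DataValidationError("ct and normalizer_ct must be finite")
        if not (math.isfinite(self.cutoff) and self.cutoff > 0):
            raise DataValidationError("cutoff must be finite and > 0")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=int)
        if self.covariate is not None:
            self.covariate = np.asarray(self.covariate, dtype=float)
            if not np.all(np.isfinite(self.covariate)):
                raise DataValidationError("covariate must be finite")

    @property
    def mode(self) -> str:
        return "two-group" if self.group is not None else "regression"

    @property
    def n(self) -> int:
        return int(self.ct.shape[0])

    def predictor_values(self) -> np.ndarray:
        return self.group if self.group is not None else self.covariate


@dataclass
class DescriptiveSummary:
    """Per-column summary; numeric columns get moments and range,
    non-numeric columns get level counts."""

    name: str
    n: int
    n_missing: int
    mean: Optional[float] = None
    sd: Optional[float] = None
    variance: Optional[float] = None
    minimum: Optional[float] = None
    median: Optional[float] = None
    maximum: Optional[float] = None
    level_counts: Optional[dict] = None

    @property
    def is_numeric(self) -> bool:
        return self.level_counts is None

    def to_dict(self) -> dict:
        d = {"name": self.name, "n": self.n, "n_missing": self.n_missing}
        if self.is_numeric:
            d.update(
                mean=self.mean, sd=self.sd, variance=self.variance,
                minimum=self.minimum, median=self.median, maximum=self.maximum,
            )
        else:
            d["level_counts"] = self.level_counts
        return d


def read_table(
    source: Union[str, os.PathLike, io.TextIOBase],
    max_bytes: int = DEFAULT_MAX_BYTES,
) -> QPCRTable:
    """Parse a CSV file or text stream into a :class:`QPCRTable`.

    Quote-aware: fields containing commas or line breaks enclosed in
    quotes parse as single cells.  Raises on an empty file, missing or
    duplicate header names, a ragged row, or a file exceeding
    ``max_bytes`` (default 10 MB).
    """
    if isinstance(source, (str, os.PathLike)):
        size = os.path.getsize(source)
        if size > max_bytes:
            raise DataValidationError(
                f"file is {size} bytes, exceeding the {max_bytes}-byte cap"
            )
        with open(source, "r", newline="", encoding="utf-8-sig") as fh:
            return _parse_stream(fh, max_bytes)
    return _parse_stream(source, max_bytes)


def _parse_stream(stream, max_bytes: int) -> QPCRTable:
    text = stream.read()
    if len(text.encode("utf-8")) > max_bytes:
        raise DataValidationError(f"input exceeds the {max_bytes}-byte cap")
    reader = csv.reader(io.StringIO(text))
    try:
        raw_header = next(reader)
    except StopIteration:
        raise DataValidationError("empty file: no header row") from None
    header = [h.strip() for h in raw_header]
    if any(h == "" for h in header):
        raise DataValidationError("header contains an empty column name")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DataValidationError(f"duplicate column names in header: {dupes}")
    rows: list[list[str]] = []
    for lineno, row in enumerate(reader, start=2):
        if row == []:  # fully blank line: ignore
            continue
        if len(row) != len(header):
            raise DataValidationError(
                f"ragged row at line {lineno}: {len(row)} cells under a "
                f"{len(header)}-column header"
            )
        rows.append(list(row))
    if not rows:
        raise DataValidationError("file has a header but no data rows")
    return QPCRTable(column_names=header, rows=rows)


def _coerce_numeric(cell: str):
    """Return float(cell), None for a blank cell, or raise ValueError.

    Accepts scientific notation and surrounding whitespace; locale
    decimal commas are deliberately not supported (ambiguous in CSV).
    """
    s = cell.strip()
    if s == "":
        return None
    return float(s)


def parse_group(labels: Sequence[str]):
    """Code a binary group column as (level1, level2) + 0/1 indicators.

    Levels are ordered lexicographically ("0" < "1"; "group1" < "group2")
    so the coding is deterministic; the mapping is reported in results
    metadata and two-sided tests are invariant to it.  Blank labels are
    treated as missing (None in the indicator list).
    """
    if len(labels) == 0:
        raise DataValidationError("group column is empty")
    cleaned = [str(x).strip() for x in labels]
    levels = sorted({s for s in cleaned if s != ""})
    if len(levels) < 2:
        raise DataValidationError(
            f"group variable must have two levels; observed {levels or 'none'}"
        )
    if len(levels) > 2:
        raise DataValidationError(
            f"group variable must be binary; observed {len(levels)} levels: {levels}"
        )
    mapping = {levels[0]: 0, levels[1]: 1}
    indicators = [mapping[s] if s != "" else None for s in cleaned]
    return (levels[0], levels[1]), indicators


def select_variables(
    table: QPCRTable,
    ct_col: str,
    normalizer_col: str,
    group_col: Optional[str] = None,
    covariate_col: Optional[str] = None,
    cutoff: float = DEFAULT_CUTOFF,
    id_col: Optional[str] = None,
    normalizer_policy: str = "error",
) -> AnalysisFrame:
    """Pick the analysis variables out of a parsed table.

    Numeric coercion is applied to the Ct, normalizer and covariate
    columns; rows with any required cell missing (blank) are dropped
    with a warning and counted in ``n_dropped``.  A non-blank cell that
    does not parse as a number is an error — undetermined Ct values must
    be pre-coded as a number at or above the cutoff, not as text.
    """
    if (group_col is None) == (covariate_col is None):
        raise DataValidationError(
            "exactly one of group_col / covariate_col must be given"
        )
    if not (cutoff > 0 and math.isfinite(cutoff)):
        raise DataValidationError("cutoff must be finite and > 0")

    numeric_cols = {"Cq/Ct": ct_col, "normalizer": normalizer_col}
    if covariate_col is not None:
        numeric_cols["explanatory"] = covariate_col
    parsed: dict[str, list] = {}
    for role, colname in numeric_cols.items():
        cells = table.column(colname)
        vals = []
        for i, cell in enumerate(cells):
            try:
                vals.append(_coerce_numeric(cell))
            except ValueError:
                raise DataValidationError(
                    f"non-numeric value {cell!r} in {role} column {colname!r} "
                    f"(row {i + 2} of the file)"
                ) from None
        parsed[role] = vals

    if group_col is not None:
        levels, indicators = parse_group(table.column(group_col))
    else:
        levels, indicators = None, None

    ids = table.column(id_col) if id_col is not None else None

    keep, dropped = [], 0
    for i in range(table.n_rows):
        required = [parsed[r][i] for r in parsed]
        if group_col is not None:
            required.append(indicators[i])
        if any(v is None for v in required):
            dropped += 1
        else:
            keep.append(i)
    if dropped:
        warnings.warn(
            f"dropped {dropped} row(s) with missing required values", stacklevel=2
        )
    if not keep:
        raise DataValidationError("all rows were dropped: no complete records")

    ct = np.array([parsed["Cq/Ct"][i] for i in keep], dtype=float)
    norm = np.array([parsed["normalizer"][i] for i in keep], dtype=float)
    bad_norm = norm >= cutoff
    if np.any(bad_norm):
        which = [ids[keep[j]] if ids else f"row {keep[j] + 2}" for j in np.flatnonzero(bad_norm)]
        if normalizer_policy == "error":
            raise DataValidationError(
                f"normalizer Ct meets or exceeds the cutoff {cutoff} for {which}; "
                "normalization is undefined (pass normalizer_policy='drop' to drop)"
            )
        warnings.warn(
            f"dropping {len(which)} sample(s) with normalizer Ct >= cutoff: {which}",
            stacklevel=2,
        )
        dropped += int(bad_norm.sum())
        keep = [k for k, bad in zip(keep, bad_norm) if not bad]
        if not keep:
            raise DataValidationError("all rows were dropped: no complete records")
        ct = ct[~bad_norm]
        norm = norm[~bad_norm]

    frame_kw = dict(
        ct=ct,
        normalizer_ct=norm,
        cutoff=float(cutoff),
        sample_id=[ids[i] for i in keep] if ids else None,
        n_dropped=dropped,
        variable_names={
            "ct": ct_col,
            "normalizer": normalizer_col,
            "group": group_col,
            "covariate": covariate_col,
        },
    )
    if group_col is not None:
        grp = np.array([indicators[i] for i in keep], dtype=int)
        if len(np.unique(grp)) < 2:
            raise DataValidationError(
                "after dropping incomplete rows the group variable has one level"
            )
        frame_kw.update(group=grp, group_levels=levels)
    else:
        frame_kw.update(
            covariate=np.array([parsed["explanatory"][i] for i in keep], dtype=float)
        )
    return AnalysisFrame(**frame_kw)


def describe(table: QPCRTable) -> list[DescriptiveSummary]:
    """Descriptive statistics for every column of the table.

    Columns whose non-blank cells all coerce to numbers are summarized
    by n, missing count, mean, sample sd / variance (n−1), minimum,
    median and maximum; other columns by level counts.
    """
    out = []
    for name in table.column_names:
        cells = table.column(name)
        stripped = [c.strip() for c in cells]
        n_missing = sum(1 for c in stripped if c == "")
        present = [c for c in stripped if c != ""]
        try:
            vals = np.array([float(c) for c in present], dtype=float)
            numeric = True
        except ValueError:
            numeric = False
        if numeric and len(present) > 0:
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
            out.append(
                DescriptiveSummary(
                    name=name,
                    n=len(vals),
                    n_missing=n_missing,
                    mean=float(np.mean(vals)),
                    sd=sd,
                    variance=sd**2 if sd is not None else None,
                    minimum=float(np.min(vals)),
                    median=float(np.median(vals)),
                    maximum=float(np.max(vals)),
                )
            )
        else:
            counts: dict[str, int] = {}
            for c in present:
                counts[c] = counts.get(c, 0) + 1
            out.append(
                DescriptiveSummary(
                    name=name, n=len(present), n_missing=n_missing, level_counts=counts
                )
            )
    return out
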