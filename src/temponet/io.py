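"""Loading, validation and filtering of time-course expression tables.

Input tables are TSV/CSV matrices of log2 (RMA-style) expression values:
one row per transcript, one column per sample.  Sample columns are annotated
with their time point (hours) and replicate index, by default through the
column-name pattern ``<time>h_rep<k>`` (e.g. ``2h_rep3``); an explicit
column-to-annotation mapping can be supplied instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import get_logger

__all__ = [
    "ExpressionDataset",
    "TimeCourseMatrix",
    "ExpressionLoadError",
    "load_expression",
    "collapse_replicates",
    "filter_fold_change",
    "DEFAULT_SAMPLE_PATTERN",
]

logger = get_logger("io")

#: default column-name convention: "<time>h_rep<k>", optionally prefixed
#: with a condition label as "<condition>_<time>h_rep<k>"
DEFAULT_SAMPLE_PATTERN = (
    r"^(?:(?P<condition>[A-Za-z][\w-]*)_)?(?P<time>\d+(?:\.\d+)?)h_rep(?P<rep>\w+)$"
)


class ExpressionLoadError(ValueError):
    """Raised when an expression table fails validation."""


@dataclass
class ExpressionDataset:
    """A validated transcripts-by-samples log2 expression matrix.

    Attributes
    ----------
    values : (G, S) ndarray
        log2 expression, one row per transcript.
    transcript_ids : list of str
        Unique, non-empty row identifiers.
    sample_times : (S,) ndarray
        Time point (hours) of each sample column.
    sample_replicates : list of str
        Replicate label of each sample column.
    condition : str
        Free-text treatment-arm label (e.g. "adaptive", "challenge").
    sample_conditions : list of str or None
        Per-sample condition labels when the file encodes them.
    """

    values: np.ndarray
    transcript_ids: list[str]
    sample_times: np.ndarray
    sample_replicates: list[str]
    condition: str = ""
    sample_conditions: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        g, s = self.values.shape
        if len(self.transcript_ids) != g:
            raise ExpressionLoadError("transcript_ids length does not match row count")
        if len(self.sample_times) != s or len(self.sample_replicates) != s:
            raise ExpressionLoadError("sample annotations do not match column count")
        seen: dict[str, int] = {}
        for i, tid in enumerate(self.transcript_ids):
            if not tid:
                raise ExpressionLoadError(f"empty transcript ID at row {i}")
            if tid in seen:
                raise ExpressionLoadError(
                    f"duplicate transcript ID {tid!r} (rows {seen[tid]} and {i})"
                )
            seen[tid] = i
        if not np.all(np.isfinite(self.sample_times)):
            raise ExpressionLoadError("every sample needs a finite time point")
        if len(np.unique(self.sample_times)) < 2:
            raise ExpressionLoadError("need at least two distinct time points")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionLoadError(
                f"non-finite value at transcript {self.transcript_ids[r]!r}, "
                f"column {c} (time {self.sample_times[c]}h, "
                f"replicate {self.sample_replicates[c]})"
            )

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def time_points(self) -> np.ndarray:
        return np.unique(self.sample_times)


@dataclass
class TimeCourseMatrix:
    """Replicate-collapsed log2 expression: one profile per transcript.

    Columns are ordered by ascending time.
    """

    values: np.ndarray
    transcript_ids: list[str]
    time_points: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_points = np.asarray(self.time_points, dtype=float)
        if self.values.shape != (len(self.transcript_ids), len(self.time_points)):
            raise ValueError("shape does not match transcript/time annotations")
        if np.any(np.diff(self.time_points) <= 0):
            raise ValueError("time points must be strictly ascending")

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{t:g}h" for t in self.time_points]
        return pd.DataFrame(self.values, index=self.transcript_ids, columns=cols)


def _sniff_sep(path: Path) -> str:
    if path.suffix.lower() in (".csv",):
        return ","
    if path.suffix.lower() in (".tsv", ".tab", ".txt"):
        return "\t"
    head = path.read_text().splitlines()[0] if path.exists() else ""
    return "\t" if "\t" in head else ","


def load_expression(
    path: str | Path,
    schema: dict[str, dict] | str | None = None,
    *,
    sep: str | None = None,
    condition: str = "",
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Load and validate a TSV/CSV expression matrix.

    Parameters
    ----------
    path : path
        File with a header row; the first column holds transcript IDs.
    schema : dict, str, or None
        Either a regex with named groups ``time``/``rep`` (and optionally
        ``condition``) applied to every sample column name, or a mapping
        ``{column: {"time": float, "rep": str}}``.  Defaults to the
        ``<time>h_rep<k>`` naming convention.
    sep : str, optional
        Field separator; inferred from the extension when omitted.
    impute_missing : bool
        Replace missing cells by the row mean instead of rejecting the file.

    Raises
    ------
    ExpressionLoadError
        On a missing header, non-numeric cells, duplicate or empty IDs,
        unannotated sample columns, or (by default) missing values.
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionLoadError(f"expression file not found: {path}")
    sep = sep or _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except Exception as exc:  # malformed file
        raise ExpressionLoadError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ExpressionLoadError(f"{path}: no sample columns found (missing header?)")

    times: list[float] = []
    reps: list[str] = []
    conds: list[str] = []
    if schema is None or isinstance(schema, str):
        pattern = re.compile(schema or DEFAULT_SAMPLE_PATTERN)
        for col in df.columns:
            m = pattern.match(str(col))
            if m is None or m.group("time") is None:
                raise ExpressionLoadError(
                    f"sample column {col!r} has no time annotation "
                    f"(expected pattern {pattern.pattern!r})"
                )
            times.append(float(m.group("time")))
            reps.append(str(m.group("rep")))
            groups = m.groupdict()
            conds.append(str(groups.get("condition") or ""))
    else:
        for col in df.columns:
            if col not in schema:
                raise ExpressionLoadError(f"sample column {col!r} missing from schema")
            entry = schema[col]
            if "time" not in entry:
                raise ExpressionLoadError(f"schema for column {col!r} lacks a time")
            times.append(float(entry["time"]))
            reps.append(str(entry.get("rep", "1")))
            conds.append(str(entry.get("condition", "")))

    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    non_numeric = ~np.isfinite(values) & df.notna().to_numpy()
    if non_numeric.any():
        r, c = np.argwhere(non_numeric)[0]
        raise ExpressionLoadError(
            f"non-numeric cell at transcript {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    missing = ~np.isfinite(values)
    if missing.any():
        if impute_missing:
            row_means = np.nanmean(np.where(missing, np.nan, values), axis=1)
            rr, cc = np.nonzero(missing)
            values[rr, cc] = row_means[rr]
            logger.warning("imputed %d missing cells with row means", missing.sum())
        else:
            r, c = np.argwhere(missing)[0]
            raise ExpressionLoadError(
                f"missing value at transcript {df.index[r]!r}, column "
                f"{df.columns[c]!r} (row {r}, column {c}); rerun with imputation "
                "enabled to fill by row mean"
            )

    ids = [str(i) for i in df.index]
    distinct_conds = sorted(set(c for c in conds if c))
    ds_condition = condition or (distinct_conds[0] if len(distinct_conds) == 1 else "")
    ds = ExpressionDataset(
        values=values,
        transcript_ids=ids,
        sample_times=np.asarray(times),
        sample_replicates=reps,
        condition=ds_condition,
        sample_conditions=conds if any(conds) else None,
    )
    logger.info(
        "loaded %d transcripts x %d samples from %s (T=%d time points)",
        ds.n_transcripts, ds.n_samples, path, len(ds.time_points),
    )
    return ds


def collapse_replicates(ds: ExpressionDataset) -> TimeCourseMatrix:
    """Average replicate log2 values at each time point.

    Raises
    ------
    ValueError
        If the dataset mixes samples from more than one condition; process
        each condition in its own run.
    """
    if ds.sample_conditions is not None:
        distinct = sorted(set(ds.sample_conditions))
        if len(distinct) > 1:
            raise ValueError(
                f"dataset mixes conditions {distinct}; split the table and "
                "process each condition separately"
            )
    times = np.unique(ds.sample_times)
    out = np.empty((ds.n_transcripts, len(times)))
    for j, t in enumerate(times):
        out[:, j] = ds.values[:, ds.sample_times == t].mean(axis=1)
    return TimeCourseMatrix(
        values=out,
        transcript_ids=list(ds.transcript_ids),
        time_points=times,
        condition=ds.condition,
    )


def filter_fold_change(
    tc: TimeCourseMatrix, threshold: float = 0.5
) -> TimeCourseMatrix:
    """Drop transcripts whose temporal range is below ``threshold`` log2 units.

    A transcript is kept when ``max_t - min_t`` of its collapsed log2 profile
    is at least ``threshold``; row order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    ranges = tc.values.max(axis=1) - tc.values.min(axis=1)
    keep = ranges >= threshold
    if not keep.any():
        raise ValueError(
            f"fold-change filter at {threshold} removed every transcript; "
            "lower the threshold"
        )
    logger.info(
        "fold-change filter (>= %g log2 units): kept %d of %d transcripts",
        threshold, int(keep.sum()), tc.n_transcripts,
    )
    return TimeCourseMatrix(
        values=tc.values[keep],
        transcript_ids=[t for t, k in zip(tc.transcript_ids, keep) if k],
        time_points=tc.time_points,
        condition=tc.condition,
    )
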