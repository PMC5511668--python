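"""Per-nucleus FISH count data model, CSV I/O and the evaluability filter.

The unit of observation is a single tumor-cell nucleus with a count of HER2
and CEP17 (chromosome-17 centromere) fluorescence signals, an optional
position in the tissue section (µm), and an optional segmentation-QC label.
Nuclei are grouped per case and per data source:

* ``CD`` — observer-corrected automated counts (the quality-assurance
  reference, treated as ground truth by the synthetic generator),
* ``AD`` — raw automated image-analysis counts over all detected nuclei,
* ``MP`` — the conventional manual procedure (40–60 selected nuclei,
  typically without recorded coordinates).

Before any case-level statistic, nuclei with an insufficient number of
signals are removed by :func:`filter_evaluable`; the default rule keeps
nuclei with at least two signals of each probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    ParseError,
    SchemaError,
    UndefinedRatioError,
)

SOURCES = ("AD", "CD", "MP")
SEG_STATUSES = ("correct", "under_over", "missed")

#: Canonical CSV column order for per-cell tables.
CSV_COLUMNS = (
    "case_id",
    "nucleus_id",
    "source",
    "x_um",
    "y_um",
    "her2",
    "cep17",
    "seg_status",
)

MANDATORY_COLUMNS = ("case_id", "source", "her2", "cep17")


@dataclass(frozen=True)
class NucleusRecord:
    """One nucleus: signal counts, optional position (µm) and QC label."""

    case_id: str
    her2: int
    cep17: int
    nucleus_id: str = ""
    x: float | None = None
    y: float | None = None
    seg_status: str | None = None
    source: str = "CD"

    def __post_init__(self):
        if self.her2 < 0 or self.cep17 < 0:
            raise ValueError(
                f"negative signal count for nucleus {self.nucleus_id!r}: "
                f"her2={self.her2}, cep17={self.cep17}"
            )
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if self.seg_status is not None and self.seg_status not in SEG_STATUSES:
            raise ValueError(f"unknown seg_status {self.seg_status!r}")
        for name, v in (("x", self.x), ("y", self.y)):
            if v is not None and not math.isfinite(v):
                raise ValueError(f"non-finite coordinate {name}={v}")

    @property
    def has_position(self) -> bool:
        return self.x is not None and self.y is not None


@dataclass
class CaseCellSet:
    """All nuclei of one case from one data source.

    ``filtered`` records whether the evaluability filter has been applied;
    statistics that require filtered data check this flag.
    """

    case_id: str
    source: str
    nuclei: list[NucleusRecord] = field(default_factory=list)
    filtered: bool = False

    def __post_init__(self):
        for n in self.nuclei:
            if n.case_id != self.case_id or n.source != self.source:
                raise ValueError(
                    f"nucleus ({n.case_id!r}, {n.source!r}) does not belong to "
                    f"case set ({self.case_id!r}, {self.source!r})"
                )

    def __len__(self) -> int:
        return len(self.nuclei)

    def her2_counts(self) -> np.ndarray:
        return np.array([n.her2 for n in self.nuclei], dtype=float)

    def cep17_counts(self) -> np.ndarray:
        return np.array([n.cep17 for n in self.nuclei], dtype=float)

    def ratios(self) -> np.ndarray:
        """Per-cell HER2/CEP17 ratios; requires every nucleus to have CEP17 ≥ 1."""
        cep = self.cep17_counts()
        if np.any(cep == 0):
            raise UndefinedRatioError(
                f"case {self.case_id!r} ({self.source}): per-cell ratio undefined "
                "for nuclei with zero CEP17 signals; filter first"
            )
        return self.her2_counts() / cep

    def positions(self) -> np.ndarray:
        """(n, 2) array of nucleus positions in µm; raises if any are missing."""
        from .errors import CoordinateError

        if not all(n.has_position for n in self.nuclei):
            raise CoordinateError(
                f"case {self.case_id!r} ({self.source}): some nuclei lack coordinates"
            )
        return np.array([[n.x, n.y] for n in self.nuclei], dtype=float)


@dataclass(frozen=True)
class FilterRule:
    """Evaluability rule: keep nuclei with her2 ≥ min_her2 and cep17 ≥ min_cep17.

    The default (2, 2) is the strict reading of excluding nuclei "without
    signals or with only one HER2 or CEP17 signal"; the looser guideline
    reading (at least one of each) is ``FilterRule(1, 1)``.
    """

    min_her2: int = 2
    min_cep17: int = 2

    def __post_init__(self):
        if self.min_her2 < 0 or self.min_cep17 < 0:
            raise ValueError("filter minima must be non-negative")

    def keeps(self, n: NucleusRecord) -> bool:
        return n.her2 >= self.min_her2 and n.cep17 >= self.min_cep17


def per_cell_ratio(n: NucleusRecord) -> float:
    """HER2/CEP17 ratio of a single nucleus; error when cep17 is zero."""
    if n.cep17 == 0:
        raise UndefinedRatioError(
            f"nucleus {n.nucleus_id!r} (case {n.case_id!r}): cep17 = 0"
        )
    return n.her2 / n.cep17


def filter_evaluable(
    cells: CaseCellSet, rule: FilterRule = FilterRule()
) -> tuple[CaseCellSet, int]:
    """Apply the evaluability filter; returns (filtered set, excluded count)."""
    kept = [n for n in cells.nuclei if rule.keeps(n)]
    out = CaseCellSet(
        case_id=cells.case_id, source=cells.source, nuclei=kept, filtered=True
    )
    return out, len(cells.nuclei) - len(kept)


def _parse_int(value, column: str, row: int) -> int:
    if isinstance(value, (int, np.integer)):
        return int(value)
    text = str(value).strip()
    try:
        return int(text)
    except ValueError:
        raise ParseError(
            f"row {row}: column {column!r} must be an integer count, got {value!r}",
            row=row,
        ) from None


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "" or text.lower() == "nan":
        return None
    return float(text)


def read_cell_table(
    path, schema: Mapping[str, str] | None = None
) -> list[CaseCellSet]:
    """Read a per-cell CSV into one :class:`CaseCellSet` per (case, source).

    ``schema`` optionally maps canonical column names (``case_id``, ``her2``,
    ``cep17``, ``source``, ``nucleus_id``, ``x_um``, ``y_um``, ``seg_status``)
    to the actual column headers in the file. Row order is preserved within
    each case set. Counts must be integers; fractional values are rejected
    with the offending row number rather than rounded.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c: c for c in CSV_COLUMNS}
    if schema:
        colmap.update(schema)
    for canonical in MANDATORY_COLUMNS:
        if colmap[canonical] not in df.columns:
            raise SchemaError(
                f"mandatory column {colmap[canonical]!r} (for {canonical!r}) "
                f"missing from {path}"
            )

    def col(name, default=None):
        actual = colmap[name]
        if actual in df.columns:
            return df[actual]
        return pd.Series([default] * len(df))

    groups: dict[tuple[str, str], list[NucleusRecord]] = {}
    it = zip(
        col("case_id"),
        col("nucleus_id", ""),
        col("source"),
        col("x_um", ""),
        col("y_um", ""),
        col("her2"),
        col("cep17"),
        col("seg_status", ""),
    )
    for i, (case_id, nid, source, x, y, her2, cep17, seg) in enumerate(it):
        row = i + 2  # 1-based with header
        seg = str(seg).strip() or None
        rec = NucleusRecord(
            case_id=str(case_id),
            nucleus_id=str(nid),
            source=str(source).strip(),
            x=_parse_optional_float(x),
            y=_parse_optional_float(y),
            her2=_parse_int(her2, "her2", row),
            cep17=_parse_int(cep17, "cep17", row),
            seg_status=seg,
        )
        groups.setdefault((rec.case_id, rec.source), []).append(rec)

    return [
        CaseCellSet(case_id=cid, source=src, nuclei=recs)
        for (cid, src), recs in groups.items()
    ]


def cells_to_frame(cases: Iterable[CaseCellSet]) -> pd.DataFrame:
    """Flatten case sets into a DataFrame with the canonical column order."""
    rows = []
    for cs in cases:
        for n in cs.nuclei:
            rows.append(
                {
                    "case_id": n.case_id,
                    "nucleus_id": n.nucleus_id,
                    "source": n.source,
                    "x_um": "" if n.x is None else repr(float(n.x)),
                    "y_um": "" if n.y is None else repr(float(n.y)),
                    "her2": n.her2,
                    "cep17": n.cep17,
                    "seg_status": n.seg_status or "",
                }
            )
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_cell_table(cases: Sequence[CaseCellSet], path) -> None:
    """Write case sets as CSV; round-trips losslessly through read_cell_table."""
    cells_to_frame(cases).to_csv(path, index=False)


def require_filtered(cells: CaseCellSet, n_min: int = 1) -> None:
    """Guard used by downstream statistics that assume filtered input."""
    if not cells.filtered:
        raise ValueError(
            f"case {cells.case_id!r} ({cells.source}): evaluability filter "
            "has not been applied"
        )
    if len(cells) < n_min:
        raise InsufficientDataError(
            f"case {cells.case_id!r} ({cells.source}): {len(cells)} nuclei, "
            f"need at least {n_min}"
        )
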