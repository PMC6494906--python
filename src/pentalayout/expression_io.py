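"""Readers/writers for the three expression-table dialects, plus
substructure aggregation and linear/log2 scale handling.

Dialects
--------
``allen_microarray``
    Log2 intensities. Expression CSV: row-id first column, one column per
    sample, header optional; the annotation CSV row order defines the
    sample order.
``adtbi_fpkm``
    Linear FPKM values, same physical layout.
``nuclei_counts``
    Linear counts per nucleus; annotations may carry cell type and class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ontology import OntologyError, OntologyMap

__all__ = [
    "SampleRecord",
    "ExpressionMatrix",
    "FormatError",
    "DIALECTS",
    "read_expression_table",
    "write_expression_table",
    "aggregate_substructures",
    "to_linear",
    "to_log2",
]


class FormatError(ValueError):
    """An input file violates the declared dialect."""


#: dialect -> (scale, unit)
DIALECTS: Dict[str, Tuple[str, str]] = {
    "allen_microarray": ("log2", "intensity"),
    "adtbi_fpkm": ("linear", "FPKM"),
    "nuclei_counts": ("linear", "counts"),
}


@dataclass(frozen=True)
class SampleRecord:
    """Annotation for one sample (a tissue sample, a substructure column
    after aggregation, or one nucleus)."""

    sample_id: str
    subject_id: str = ""
    substructure: str = ""
    hemisphere: str = "none"  # {left, right, none}
    age: Optional[float] = None
    sex: str = "unknown"
    cell_type: str = ""
    cell_class: str = ""
    extra: Dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", "none"):
            raise ValueError(f"invalid hemisphere {self.hemisphere!r}")
        if self.age is not None and self.age < 0:
            raise ValueError(f"negative age {self.age} for {self.sample_id!r}")


class ExpressionMatrix:
    """A row-id x sample matrix of expression values.

    Parameters
    ----------
    row_ids
        Unique gene or probe identifiers.
    samples
        One :class:`SampleRecord` per column.
    values
        Array of shape ``(len(row_ids), len(samples))``; must be finite,
        and nonnegative when ``scale == "linear"``.
    scale
        ``"linear"`` or ``"log2"``.
    unit
        ``"intensity"``, ``"FPKM"`` or ``"counts"``.
    """

    def __init__(
        self,
        row_ids: Sequence[str],
        samples: Sequence[SampleRecord],
        values: np.ndarray,
        scale: str = "linear",
        unit: str = "intensity",
    ):
        values = np.asarray(values, dtype=float)
        row_ids = [str(r) for r in row_ids]
        if len(set(row_ids)) != len(row_ids):
            raise ValueError("row_ids must be unique")
        if values.shape != (len(row_ids), len(samples)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(row_ids)} rows x {len(samples)} samples"
            )
        if scale not in ("linear", "log2"):
            raise ValueError(f"invalid scale {scale!r}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(f"non-finite value at row {bad[0]}, column {bad[1]}")
        if scale == "linear" and np.any(values < 0):
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value on linear scale at row {row_ids[bad[0]]!r}, "
                f"sample {samples[bad[1]].sample_id!r}"
            )
        self.row_ids: List[str] = row_ids
        self.samples: List[SampleRecord] = list(samples)
        self.values = values
        self.scale = scale
        self.unit = unit
        self._row_index = {r: i for i, r in enumerate(row_ids)}

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]

    def row(self, row_id: str) -> np.ndarray:
        try:
            return self.values[self._row_index[row_id]]
        except KeyError:
            raise KeyError(f"unknown row id {row_id!r}") from None

    def select_rows(self, row_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._row_index[r] for r in row_ids]
        return ExpressionMatrix(
            list(row_ids), self.samples, self.values[idx], self.scale, self.unit
        )

    def select_samples(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            self.row_ids,
            [self.samples[i] for i in idx],
            self.values[:, idx],
            self.scale,
            self.unit,
        )

    def restrict_subject(self, subject_id: str) -> "ExpressionMatrix":
        mask = np.array([s.subject_id == subject_id for s in self.samples])
        return self.select_samples(mask)

    def subjects(self) -> List[str]:
        seen: Dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.subject_id)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# annotation column aliases, per dialect-agnostic tolerant parsing
_ANNOT_ALIASES = {
    "sample_id": ("sample_id", "well_id", "sample_name", "nucleus_id"),
    "subject_id": ("subject_id", "donor_id", "donor_name", "specimen_id"),
    "substructure": ("substructure", "structure_acronym", "structure", "region"),
    "hemisphere": ("hemisphere", "hemi", "side"),
    "age": ("age", "age_years", "age_category"),
    "sex": ("sex", "gender"),
    "cell_type": ("cell_type", "cluster", "cell_type_alias_label"),
    "cell_class": ("cell_class", "class", "class_label"),
}


def _pick(columns: Sequence[str], key: str) -> Optional[str]:
    lower = {c.lower(): c for c in columns}
    for alias in _ANNOT_ALIASES[key]:
        if alias in lower:
            return lower[alias]
    return None


def _parse_annotations(annotation_path) -> List[SampleRecord]:
    annot = pd.read_csv(annotation_path, dtype=str, keep_default_na=False)
    cols = list(annot.columns)
    sid_col = _pick(cols, "sample_id")
    if sid_col is None:
        raise FormatError(
            f"annotation file {annotation_path} lacks a sample-id column "
            f"(accepted names: {_ANNOT_ALIASES['sample_id']})"
        )
    records = []
    for i, row in annot.iterrows():
        def get(key: str, default: str = "") -> str:
            col = _pick(cols, key)
            return str(row[col]).strip() if col is not None else default

        age_text = get("age")
        age: Optional[float] = None
        if age_text not in ("", "nan"):
            try:
                age = float(age_text)
            except ValueError:
                # ordinal age categories like "78-82" or "90+": rank is
                # recovered downstream; keep the midpoint-free code in extra
                age = None
        hemi = get("hemisphere", "none").lower() or "none"
        if hemi in ("l", "lh"):
            hemi = "left"
        elif hemi in ("r", "rh"):
            hemi = "right"
        records.append(
            SampleRecord(
                sample_id=str(row[sid_col]).strip(),
                subject_id=get("subject_id"),
                substructure=get("substructure"),
                hemisphere=hemi if hemi in ("left", "right") else "none",
                age=age,
                sex=get("sex", "unknown") or "unknown",
                cell_type=get("cell_type"),
                cell_class=get("cell_class"),
                extra={"age_category": age_text} if age is None and age_text else {},
            )
        )
    return records


def _read_values(path) -> Tuple[List[str], Optional[List[str]], np.ndarray]:
    """Header-tolerant parse: returns (row_ids, header sample ids or None, values)."""
    raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a row-id column plus data columns")

    def numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    first_data = raw.iloc[0, 1:]
    has_header = not all(numeric(c) for c in first_data)
    header: Optional[List[str]] = None
    if has_header:
        header = [str(c) for c in first_data]
        raw = raw.iloc[1:].reset_index(drop=True)
    row_ids = [str(r) for r in raw.iloc[:, 0]]
    values = np.empty((raw.shape[0], raw.shape[1] - 1))
    for i in range(raw.shape[0]):
        for j in range(1, raw.shape[1]):
            cell = raw.iat[i, j]
            try:
                values[i, j - 1] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row {i}, column {j}"
                ) from None
    return row_ids, header, values


def read_expression_table(path, annotation_path, dialect: str) -> ExpressionMatrix:
    """Read an expression CSV plus its sample-annotation CSV.

    The annotation row order defines the sample order; when the expression
    file carries a header, its ids must agree with the annotation ids.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    scale, unit = DIALECTS[dialect]
    samples = _parse_annotations(annotation_path)
    row_ids, header, values = _read_values(path)
    if values.shape[1] != len(samples):
        raise FormatError(
            f"sample-count mismatch: expression file {path} has "
            f"{values.shape[1]} data columns but annotation file "
            f"{annotation_path} has {len(samples)} rows"
        )
    if header is not None:
        annot_ids = [s.sample_id for s in samples]
        if header != annot_ids:
            raise FormatError(
                f"expression header ids do not match annotation sample ids: "
                f"{header[:3]}... vs {annot_ids[:3]}..."
            )
    try:
        return ExpressionMatrix(row_ids, samples, values, scale=scale, unit=unit)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_table(m: ExpressionMatrix, path, annotation_path) -> None:
    """Write ``m`` in the shared on-disk layout (round-trips with
    :func:`read_expression_table`)."""
    frame = m.to_frame()
    frame.index.name = "row_id"
    frame.to_csv(path)
    annot = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in m.samples],
            "subject_id": [s.subject_id for s in m.samples],
            "substructure": [s.substructure for s in m.samples],
            "hemisphere": [s.hemisphere for s in m.samples],
            "age": [
                s.age if s.age is not None else s.extra.get("age_category", "")
                for s in m.samples
            ],
            "sex": [s.sex for s in m.samples],
            "cell_type": [s.cell_type for s in m.samples],
            "cell_class": [s.cell_class for s in m.samples],
        }
    )
    annot.to_csv(annotation_path, index=False)


def aggregate_substructures(
    m: ExpressionMatrix, ontology: OntologyMap, subject: str
) -> ExpressionMatrix:
    """Average one subject's samples to substructure level, pooling
    hemispheres, on the matrix's stored scale.

    Output columns appear in rostro-caudal ontology order and are labeled
    by substructure code.
    """
    sub = m.restrict_subject(subject)
    if sub.shape[1] == 0:
        raise ValueError(f"no samples for subject {subject!r}")
    for s in sub.samples:
        if s.substructure not in ontology:
            raise OntologyError(
                f"sample {s.sample_id!r} has unknown substructure code "
                f"{s.substructure!r}"
            )
    groups: Dict[str, List[int]] = {}
    for j, s in enumerate(sub.samples):
        groups.setdefault(s.substructure, []).append(j)
    order = [c for c in ontology.substructures if c in groups]
    cols = np.column_stack([sub.values[:, groups[c]].mean(axis=1) for c in order])
    records = [
        SampleRecord(
            sample_id=code,
            subject_id=subject,
            substructure=code,
            hemisphere="none",
        )
        for code in order
    ]
    return ExpressionMatrix(sub.row_ids, records, cols, sub.scale, sub.unit)


def to_linear(m: ExpressionMatrix) -> ExpressionMatrix:
    """Unlog a log2 matrix (``v -> 2**v``); identity on linear matrices."""
    if m.scale == "linear":
        return ExpressionMatrix(m.row_ids, m.samples, m.values.copy(), "linear", m.unit)
    return ExpressionMatrix(
        m.row_ids, m.samples, np.exp2(m.values), "linear", m.unit
    )


def to_log2(m: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """Log2-transform a linear matrix; identity on log2 matrices."""
    if m.scale == "log2":
        return ExpressionMatrix(m.row_ids, m.samples, m.values.copy(), "log2", m.unit)
    vals = np.log2(m.values + pseudocount) if pseudocount else np.log2(m.values)
    if not np.all(np.isfinite(vals)):
        raise ValueError("log2 of zero values; pass a positive pseudocount")
    return ExpressionMatrix(m.row_ids, m.samples, vals, "log2", m.unit)
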