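"""Readers and writers for the package's tab-delimited artifacts.

Dialect: UTF-8, tab-separated, mandatory header row, scientific notation
accepted. Expression matrices are probes-as-rows with sample ids in the
header; the loader validates uniqueness and rejects missing or non-numeric
cells with their coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    FormatError,
    FunctionAnnotation,
    SampleMetadata,
    _first_duplicate,
)

METADATA_COLUMNS = ("sample_id", "risk_class", "subclass")
ANNOTATION_COLUMNS = ("probe_id", "gene_symbol", "category")

#: significant digits written for expression values; round-trip accurate to
#: ~1e-9 relative, far below assay noise.
FLOAT_FORMAT = "%.10g"


def read_expression_matrix(path, dataset_id: str, cell_type: str) -> ExpressionMatrix:
    """Load a probes x samples TSV, preserving row/column order from the file."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    probe_ids = [str(p) for p in raw.index]
    sample_ids = [str(c) for c in raw.columns]
    dup = _first_duplicate(probe_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicated probe row {dup!r}")
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicated sample column {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        cell = raw.iat[i, j]
        what = "missing value" if cell.strip() == "" else f"non-numeric value {cell!r}"
        raise FormatError(
            f"{path}: {what} at probe {probe_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(
        dataset_id=dataset_id,
        cell_type=cell_type,
        probe_ids=tuple(probe_ids),
        sample_ids=tuple(sample_ids),
        values=numeric.to_numpy(dtype=float),
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    frame = pd.DataFrame(
        matrix.values, index=list(matrix.probe_ids), columns=list(matrix.sample_ids)
    )
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")


def read_metadata(path) -> List[SampleMetadata]:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    records = []
    for row in frame.itertuples(index=False):
        try:
            records.append(
                SampleMetadata(
                    sample_id=row.sample_id,
                    risk_class=row.risk_class,
                    subclass=row.subclass,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    dup = _first_duplicate([r.sample_id for r in records])
    if dup is not None:
        raise FormatError(f"{path}: duplicated sample id {dup!r}")
    return records


def write_metadata(metadata: Iterable[SampleMetadata], path) -> None:
    frame = pd.DataFrame(
        [(m.sample_id, m.risk_class, m.subclass) for m in metadata],
        columns=list(METADATA_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotations(path) -> List[FunctionAnnotation]:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    records = [
        FunctionAnnotation(row.probe_id, row.gene_symbol, row.category)
        for row in frame.itertuples(index=False)
    ]
    return records


def write_annotations(annotations: Iterable[FunctionAnnotation], path) -> None:
    frame = pd.DataFrame(
        [(a.probe_id, a.gene_symbol, a.category) for a in annotations],
        columns=list(ANNOTATION_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_scores(scores, path) -> None:
    """Persist posterior risk scores as a two-column TSV."""
    frame = pd.DataFrame(
        [(s.sample_id, s.posterior_high) for s in scores],
        columns=["sample_id", "posterior_high"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_scores(path):
    from .predictor import RiskScore

    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return [
        RiskScore(str(row.sample_id), float(row.posterior_high))
        for row in frame.itertuples(index=False)
    ]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
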