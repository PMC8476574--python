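"""Readers and writers for the package's plain-text table dialects.

* Expression matrix: TSV, first column ``gene_id``, remaining columns
  sample ids; companion annotation TSV with ``sample_id`` plus optional
  ``stained_phenotype`` / ``response`` / ``cohort`` columns.
* Cell table: CSV with header ``sample_id,stamp_id,region,compartment,
  marker,x_um,y_um``.
* Classifier model: TSV mirroring the published rank-table layout
  (gene_id, signature phenotype, per-phenotype means and ranks).

Repertoire I/O lives in :mod:`spatialpheno.repertoire`.
"""

from __future__ import annotations

import pandas as pd

from .containers import ExpressionMatrix
from .spatial import CELL_TABLE_COLUMNS


def read_expression(values_path, annotations_path=None) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(values, ann)


def write_expression(expr: ExpressionMatrix, values_path, annotations_path=None):
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(values_path, sep="\t")
    if annotations_path is not None:
        ann = expr.annotations.copy()
        ann.index.name = "sample_id"
        ann.to_csv(annotations_path, sep="\t")


def read_cells(path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    return cells


def write_cells(cells: pd.DataFrame, path) -> None:
    cells[CELL_TABLE_COLUMNS].to_csv(path, index=False)


def read_model(path):
    from .classifier import ClassifierModel

    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ClassifierModel.from_frame(frame)


def write_model(model, path) -> None:
    model.to_frame().to_csv(path, sep="\t")
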