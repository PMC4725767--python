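"""Readers and writers for every external representation the pipeline touches.

Expression tables are tab-separated, proteins in rows and samples in columns;
values are ratios between each tumour and a common spiked-in internal
standard.  Two dialects are supported:

``generic``
    First column holds the protein identifier, every remaining column is a
    sample.
``maxquant_protein_groups``
    A protein-groups export; ratio columns are recognized by a configurable
    column-name prefix (default ``"Ratio H/L normalized "``) and the sample
    name is what follows the prefix.  Because H is the heavy internal
    standard, this dialect defaults to standard-over-sample orientation.

All matrices are stored internally as log2 in *sample/standard* orientation
regardless of input orientation.  Zeros and non-numeric cells become missing
(a zero ratio is a non-detection artifact, not a measurement).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CategoryMap, ExpressionMatrix, FormatError, SampleAnnotation

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_gmt",
    "write_gmt",
    "read_hierarchy",
    "write_result_table",
]

MAXQUANT_RATIO_PREFIX = "Ratio H/L normalized "

_ORIENTATION_DEFAULTS = {
    "generic": "sample_over_standard",
    "maxquant_protein_groups": "standard_over_sample",
}


def read_expression_matrix(
    path,
    dialect: str = "generic",
    ratio_orientation: str | None = None,
    log_already: bool = False,
    ratio_prefix: str = MAXQUANT_RATIO_PREFIX,
    id_column: str | None = None,
) -> ExpressionMatrix:
    """Read a tab-separated expression table into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    dialect
        ``"generic"`` or ``"maxquant_protein_groups"``.
    ratio_orientation
        ``"sample_over_standard"`` or ``"standard_over_sample"``.  When None
        the dialect default applies (generic: sample/standard; maxquant:
        standard/sample, because the H channel is the internal standard).
        Standard-over-sample inputs are sign-inverted after the log transform.
    log_already
        If True, values on disk are already log2-transformed and only the
        orientation inversion (negation) may apply.
    id_column
        Protein-identifier column for the maxquant dialect (default: first
        column).
    """
    if dialect not in _ORIENTATION_DEFAULTS:
        raise FormatError(f"unknown dialect: {dialect!r}")
    orientation = ratio_orientation or _ORIENTATION_DEFAULTS[dialect]
    if orientation not in ("sample_over_standard", "standard_over_sample"):
        raise FormatError(f"unknown ratio orientation: {orientation!r}")

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two tab-separated columns")

    if dialect == "maxquant_protein_groups":
        idc = id_column or raw.columns[0]
        ratio_cols = [c for c in raw.columns if c.startswith(ratio_prefix)]
        if not ratio_cols:
            raise FormatError(
                f"{path}: no ratio columns with prefix {ratio_prefix!r}"
            )
        table = raw[[idc] + ratio_cols].copy()
        table.columns = [idc] + [c[len(ratio_prefix):] for c in ratio_cols]
    else:
        table = raw

    table = table.set_index(table.columns[0])

    def _cell(x: str) -> float:
        # Python float() parses exactly (round-trip safe); pandas' fast
        # parser may lose the last digit
        try:
            v = float(x)
        except ValueError:
            return np.nan
        return v if np.isfinite(v) else np.nan

    values = table.apply(lambda col: col.map(_cell))

    if not log_already:
        values = values.where(values > 0)  # zeros / negatives are non-detections
        values = np.log2(values)
    if orientation == "standard_over_sample":
        values = -values

    return ExpressionMatrix(values)


def write_expression_matrix(matrix: ExpressionMatrix, path, comment: str | None = None) -> None:
    """Write log2 values as generic TSV; missing entries become empty cells.

    Values are written with full ``repr`` precision so that a read with
    ``log_already=True`` round-trips bit-identically.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(["protein_id"] + [str(s) for s in matrix.sample_ids]) + "\n")
        for pid, row in matrix.data.iterrows():
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write("\t".join([str(pid)] + cells) + "\n")


def read_sample_annotation(path) -> SampleAnnotation:
    """Read a two-column (sample_id, class) TSV; header row optional.

    Class label order is the order of first appearance in the file.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated fields")
            rows.append(parts)
    if rows and rows[0][0].lower() in ("sample", "sample_id"):
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: no annotation rows")
    ids = [r[0] for r in rows]
    labels = pd.Series([r[1] for r in rows], index=pd.Index(ids, name="sample_id"))
    return SampleAnnotation(labels)


def write_sample_annotation(annotation: SampleAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for sid, lab in annotation.labels.items():
            fh.write(f"{sid}\t{lab}\n")


def read_gmt(path) -> CategoryMap:
    """Read gene sets in Broad GMT dialect: name, description, members.

    The description column is discarded; duplicate members within one line
    are deduplicated.
    """
    members: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in members:
                raise FormatError(f"{path}:{ln}: duplicate category name {name!r}")
            members[name] = frozenset(f for f in fields[2:] if f)
            if not members[name]:
                raise FormatError(f"{path}:{ln}: category {name!r} has no members")
    return CategoryMap(members)


def write_gmt(categories: CategoryMap, path) -> None:
    with open(path, "w") as fh:
        for name, mem in categories.members.items():
            fh.write("\t".join([name, "na"] + sorted(str(m) for m in mem)) + "\n")


def read_hierarchy(path) -> dict:
    """Read a two-column (category, parent) TSV into a parent-link mapping."""
    parents: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated fields")
            child, parent = parts
            if child in parents:
                raise FormatError(f"{path}:{ln}: duplicate child {child!r}")
            parents[child] = parent
    return parents


def write_result_table(frame: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a result table as TSV with a header comment recording parameters."""
    path = Path(path)
    with open(path, "w") as fh:
        if params:
            kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
            fh.write(f"# {kv}\n")
        frame.to_csv(fh, sep="\t", index=False)
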