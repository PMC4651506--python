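"""Tab-delimited readers and writers for every pipeline artifact.

All tables are plain TSV with a leading ``# columns:`` schema comment;
expression matrices have gene ids in the first column and sample ids in
the header row, sample sheets are two columns (sample, stage), CT tables
are long-format (gene, sample, ct). Everything a writer emits is
re-parseable by the matching reader.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .data import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_ct",
    "write_ct",
    "write_table",
    "read_table",
]


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ([df.index.name or "id"] if index else []) + [str(c) for c in df.columns]
    with open(path, "w") as fh:
        fh.write("# columns: " + "\t".join(cols) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def _scan_matrix_lines(path: Path) -> list[list[str]]:
    rows = []
    width = None
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not raw or raw[0].startswith("#"):
                continue
            if width is None:
                width = len(raw)
            elif len(raw) != width:
                raise ValueError(
                    f"{path}: line {lineno} has {len(raw)} fields, expected {width}"
                )
            rows.append(raw)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return rows


def write_expression(expr: ExpressionMatrix, path, sample_sheet_path=None) -> None:
    write_table(expr.values.rename_axis("gene_id"), path, index=True)
    if sample_sheet_path is not None:
        write_sample_sheet(expr.stage_of_sample, sample_sheet_path)


def read_expression(path, stage_of_sample: dict[str, str]) -> ExpressionMatrix:
    """Read a genes × samples TSV and join it against the sample sheet.

    Raises descriptive errors (with line numbers where possible) on
    ragged rows, duplicate gene ids, non-numeric cells and samples the
    sheet does not know.
    """
    path = Path(path)
    rows = _scan_matrix_lines(path)
    header, body = rows[0], rows[1:]
    samples = header[1:]
    unknown = [s for s in samples if s not in stage_of_sample]
    if unknown:
        raise ValueError(f"{path}: samples not in sample sheet: {unknown[:5]}")
    gene_ids = [r[0] for r in body]
    seen: set[str] = set()
    for lineno_offset, g in enumerate(gene_ids):
        if g in seen:
            raise ValueError(f"{path}: duplicate gene id {g!r}")
        seen.add(g)
    values = []
    for offset, r in enumerate(body, start=2):
        try:
            values.append([float(x) for x in r[1:]])
        except ValueError:
            bad = next(x for x in r[1:] if not _is_float(x))
            raise ValueError(
                f"{path}: non-numeric cell {bad!r} at line {offset} (gene {r[0]!r})"
            ) from None
    df = pd.DataFrame(values, index=gene_ids, columns=samples)
    return ExpressionMatrix(df, {s: stage_of_sample[s] for s in samples})


def _is_float(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def write_sample_sheet(stage_of_sample: dict[str, str], path) -> None:
    df = pd.DataFrame(
        {"sample": list(stage_of_sample), "stage": list(stage_of_sample.values())}
    )
    write_table(df, path)


def read_sample_sheet(path) -> dict[str, str]:
    df = read_table(path)
    if not {"sample", "stage"} <= set(df.columns):
        raise ValueError(f"{path}: sample sheet needs 'sample' and 'stage' columns")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return dict(zip(df["sample"].astype(str), df["stage"].astype(str)))


def write_ct(ct_table: pd.DataFrame, path) -> None:
    """Write a genes × samples CT matrix as long-format (gene, sample, ct)."""
    long = ct_table.rename_axis("gene").reset_index().melt(
        id_vars="gene", var_name="sample", value_name="ct"
    )
    write_table(long, path)


def read_ct(path) -> pd.DataFrame:
    """Read a long-format CT table back into a genes × samples matrix."""
    df = read_table(path)
    if not {"gene", "sample", "ct"} <= set(df.columns):
        raise ValueError(f"{path}: CT table needs gene, sample and ct columns")
    wide = df.pivot(index="gene", columns="sample", values="ct")
    wide.index.name = None
    wide.columns.name = None
    return wide
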