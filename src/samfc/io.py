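"""Readers and writers for expression matrices, truth labels and results.

Matrices are delimited text (tab by default, comma for ``.csv``) with a
header row of sample names and the gene identifier in the first column.
Result tables are tab-delimited with ``#``-prefixed metadata header lines.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .experiment import PairedExperiment

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_truth",
    "write_truth",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path, pairing_spec: Optional[Sequence[Sequence[str]]] = None
) -> PairedExperiment:
    """Load a genes x samples matrix into a validated :class:`PairedExperiment`.

    ``pairing_spec`` is a list of ``(condition1_sample, condition2_sample)``
    column-name pairs; by default the first half of the columns pairs with
    the second half in order.  Duplicate gene identifiers and non-numeric
    cells are rejected with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        lines = [int(np.nonzero(df.index == d)[0][-1]) + 2 for d in dup[:3]]
        raise ValueError(
            f"duplicate gene id(s) {list(dup[:3])} (e.g. line(s) {lines})"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().values & ~df.isna().values)
    if bad.size or numeric.isna().values.any():
        r, c = (bad[0] if bad.size else np.argwhere(numeric.isna().values)[0])
        raise ValueError(
            f"non-numeric cell at line {r + 2}, column {df.columns[c]!r} "
            f"(gene {df.index[r]!r})"
        )
    if pairing_spec is not None:
        cols = list(df.columns)
        try:
            pairing = tuple(
                (cols.index(a), cols.index(b)) for a, b in pairing_spec
            )
        except ValueError as e:
            raise ValueError(f"pairing references a missing sample column: {e}")
    else:
        if df.shape[1] % 2:
            raise ValueError(
                "odd number of sample columns with the default pairing; "
                "declare an explicit pairing of column names"
            )
        pairing = None
    return PairedExperiment(tuple(df.index), numeric.values, pairing)


def write_matrix(experiment: PairedExperiment, path, sample_names=None) -> None:
    path = Path(path)
    if sample_names is None:
        sample_names = [f"s{j}" for j in range(experiment.values.shape[1])]
    df = pd.DataFrame(
        experiment.values, index=list(experiment.gene_ids), columns=sample_names
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep=_sep_for(path))


def write_table(df: pd.DataFrame, path, metadata: Optional[dict] = None) -> None:
    """Tab-delimited table with ``#key=value`` metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`; returns (df, metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "=" in line:
                    k, _, v = line[1:].strip().partition("=")
                    meta[k] = v
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t")
    return df, meta


def write_truth(gene_ids, is_de, path, outlier_mask=None) -> None:
    df = pd.DataFrame({"gene_id": list(gene_ids), "is_de": np.asarray(is_de, int)})
    write_table(df, path)
    if outlier_mask is not None:
        mpath = Path(path).with_name(Path(path).stem + "_outlier_mask.tsv")
        mdf = pd.DataFrame(
            np.asarray(outlier_mask, int),
            columns=[f"s{j}" for j in range(np.asarray(outlier_mask).shape[1])],
        )
        mdf.insert(0, "gene_id", list(gene_ids))
        write_table(mdf, mpath)


def read_truth(path) -> pd.DataFrame:
    df, _ = read_table(path)
    df["is_de"] = df["is_de"].astype(bool)
    return df
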