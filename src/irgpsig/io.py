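"""Reading and writing the pipeline's external formats.

Expression matrices, clinical tables and MAF-lite mutation tables are
delimited text (TSV by default, CSV by file extension); gene lists are plain
text with one symbol per line.  All tabular outputs are TSV with a header
and floats rendered at 10 significant digits, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_matrix",
    "read_clinical",
    "read_gene_list",
    "read_maf",
    "write_tsv",
]

logger = logging.getLogger("irgpsig")

MAF_COLUMNS = {
    "Tumor_Sample_Barcode": "sample",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_class",
    "Start_Position": "position",
}


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(
    path,
    gene_id_column: str | None = None,
    duplicate_policy: str = "max",
    transpose: bool = False,
) -> pd.DataFrame:
    """Load a genes x samples expression matrix from delimited text.

    Genes are expected in rows with a header of sample IDs (the TCGA
    convention); ``transpose=True`` accepts samples-in-rows files.  Missing
    or non-numeric cells raise, naming the offending gene and sample.
    Duplicate gene symbols are resolved per ``duplicate_policy``:
    ``"error"``, ``"max"`` (element-wise maximum, the usual probe-collapse
    rule) or ``"mean"``.
    """
    if duplicate_policy not in {"error", "max", "mean"}:
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if gene_id_column is None:
        gene_id_column = df.columns[0]
    if gene_id_column not in df.columns:
        raise ValueError(f"gene ID column {gene_id_column!r} not found in {path}")
    df = df.set_index(gene_id_column)
    df.index.name = "gene"
    if transpose:
        df = df.T
        df.index.name = "gene"
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate sample IDs: {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"missing or non-numeric expression value for gene "
            f"{numeric.index[gi]!r}, sample {numeric.columns[si]!r}"
        )
    if numeric.index.duplicated().any():
        dup = sorted(set(numeric.index[numeric.index.duplicated()]))
        if duplicate_policy == "error":
            raise ValueError(f"duplicate gene IDs: {dup}")
        agg = "max" if duplicate_policy == "max" else "mean"
        # groupby(sort=False) keeps first-occurrence row order
        numeric = numeric.groupby(level=0, sort=False).agg(agg)
        logger.info("collapsed %d duplicate gene IDs with %s", len(dup), agg)
    return numeric.astype(float)


def read_clinical(
    path,
    time_column: str = "time",
    event_column: str = "event",
    id_column: str | None = None,
    event_mapping: dict | None = None,
) -> pd.DataFrame:
    """Load a clinical table into a survival frame (index sample ID, columns
    ``time``, ``event`` and any extra covariates).

    Rows with missing or non-positive time, or missing/unmappable event, are
    dropped with a logged count.  ``event_mapping`` converts alternative
    codings (e.g. ``{"Dead": 1, "Alive": 0}``); events must end up in {0, 1}.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if id_column is None:
        id_column = df.columns[0]
    for col, what in [(id_column, "sample ID"), (time_column, "time"),
                      (event_column, "event")]:
        if col not in df.columns:
            raise ValueError(f"{what} column {col!r} not found in {path}")
    df = df.set_index(id_column)
    df.index.name = "sample"
    if df.index.duplicated().any():
        raise ValueError("duplicate sample IDs in clinical table")
    time = pd.to_numeric(df[time_column], errors="coerce")
    event = df[event_column]
    if event_mapping is not None:
        event = event.map(event_mapping)
    event = pd.to_numeric(event, errors="coerce")
    valid = time.notna() & (time > 0) & event.isin([0, 1])
    dropped = int((~valid).sum())
    if dropped:
        logger.info("dropped %d clinical rows with invalid time/event", dropped)
    if valid.sum() == 0:
        raise ValueError("no usable samples in clinical table")
    out = df.loc[valid].drop(columns=[time_column, event_column])
    out.insert(0, "time", time[valid].astype(float))
    out.insert(1, "event", event[valid].astype(int))
    return out


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks and duplicates are
    dropped, first-seen order preserved."""
    seen: dict[str, None] = {}
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym:
            seen.setdefault(sym)
    if not seen:
        raise ValueError(f"gene list {path} is empty")
    return list(seen)


def read_maf(path) -> pd.DataFrame:
    """Load a MAF-lite TSV into the canonical mutation-table layout
    (columns ``sample``, ``gene``, ``variant_class``, ``position``)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file missing required column(s): {missing}")
    out = df[list(MAF_COLUMNS)].rename(columns=MAF_COLUMNS)
    if (out["sample"].astype(str).str.len() == 0).any() or out["sample"].isna().any():
        raise ValueError("empty sample ID in mutation table")
    return out


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a TSV with floats at 10 significant digits (reproducible
    byte-identical output)."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
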