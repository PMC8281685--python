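"""Within-sample gene-pair binarization and frequency filtering.

The immune-related gene-pair (IRGP) transform replaces absolute expression
with within-sample order: for an ordered pair (A, B) the indicator is 1 when
A's expression strictly exceeds B's in that sample, else 0 (ties score 0).
Because only the within-sample ranking matters, the transform is invariant
to any strictly increasing per-sample rescaling of expression — the property
that lets a signature trained on one platform transfer to another without
normalization.

A pair profile is a pairs x samples ``pandas.DataFrame`` of 0/1 values whose
index holds pair IDs ``"GENEA|GENEB"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "pair_id",
    "split_pair_id",
    "build_pair_matrix",
    "filter_pairs",
    "pair_frequencies",
]

PAIR_SEP = "|"


def pair_id(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}{PAIR_SEP}{gene_b}"


def split_pair_id(pid: str) -> tuple[str, str]:
    gene_a, gene_b = pid.split(PAIR_SEP)
    return gene_a, gene_b


def build_pair_matrix(expr: pd.DataFrame, immune_genes: list[str]) -> pd.DataFrame:
    """Binary pair profile of an expression matrix restricted to immune genes.

    One row per unordered gene combination, oriented canonically: ``gene_a``
    precedes ``gene_b`` in ``immune_genes`` order, giving G*(G-1)/2 rows for
    G matched genes.  Entry (p, s) is 1 iff expression(gene_a, s) >
    expression(gene_b, s) strictly; equality gives 0.

    Parameters
    ----------
    expr
        Genes x samples expression matrix (any within-sample
        monotone-comparable units).
    immune_genes
        Gene symbols defining the pairing universe and the canonical
        orientation order.

    Raises
    ------
    ValueError
        If fewer than 2 listed genes are present in ``expr`` (the matched
        genes are named in the message).
    """
    seen = set()
    matched = [
        g for g in immune_genes
        if g in expr.index and not (g in seen or seen.add(g))
    ]
    if len(matched) < 2:
        raise ValueError(
            f"need >=2 immune genes present in the expression matrix; "
            f"matched only {matched}"
        )
    values = expr.loc[matched].to_numpy(dtype=float)
    ia, ib = np.triu_indices(len(matched), k=1)
    binary = (values[ia] > values[ib]).astype(np.int8)
    index = pd.Index(
        [pair_id(matched[i], matched[j]) for i, j in zip(ia, ib)], name="pair"
    )
    return pd.DataFrame(binary, index=index, columns=expr.columns)


def pair_frequencies(profile: pd.DataFrame) -> pd.Series:
    """Per-pair fraction of samples with indicator 1."""
    return profile.mean(axis=1)


def filter_pairs(
    profile: pd.DataFrame, min_minor_freq: float = 0.20
) -> tuple[pd.DataFrame, int]:
    """Drop near-constant pairs; keep those with minor-state frequency
    at least ``min_minor_freq``.

    A pair is retained iff its 1-frequency lies in the closed interval
    [min_minor_freq, 1 - min_minor_freq]; row order is preserved.  Returns
    the filtered profile and the number of removed pairs.

    Raises
    ------
    ValueError
        On an empty input, an out-of-range threshold, or if no pair
        survives ("no informative pairs").
    """
    if profile.shape[0] == 0:
        raise ValueError("empty pair profile")
    if not 0.0 < min_minor_freq < 0.5:
        raise ValueError(f"min_minor_freq must be in (0, 0.5), got {min_minor_freq}")
    freq = pair_frequencies(profile)
    keep = (freq >= min_minor_freq) & (freq <= 1.0 - min_minor_freq)
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no informative pairs after frequency filtering")
    return profile.loc[keep], removed
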