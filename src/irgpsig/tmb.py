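"""Tumor mutation burden (TMB) from somatic-variant records.

TMB is the per-sample count of qualifying somatic variants divided by the
length of the interrogated exonic territory in megabases.  Mutation tables
follow a MAF-lite layout: one row per somatic variant with columns
``sample``, ``gene``, ``variant_class``, ``position``.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CODING_CLASSES",
    "NONSYNONYMOUS_CLASSES",
    "DEFAULT_EXOME_MB",
    "compute_tmb",
]

# MAF Variant_Classification vocabulary for coding somatic variants
CODING_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Silent",
        "Splice_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
    }
)
NONSYNONYMOUS_CLASSES = frozenset(CODING_CLASSES - {"Silent"})

#: conventional captured-exome size in megabases
DEFAULT_EXOME_MB = 38.0


def compute_tmb(
    muts: pd.DataFrame,
    samples=None,
    exome_length_mb: float = DEFAULT_EXOME_MB,
    include_classes=None,
) -> pd.DataFrame:
    """Per-sample mutation count and TMB (mutations per megabase).

    Parameters
    ----------
    muts
        MAF-lite table with at least ``sample`` and ``variant_class`` columns.
    samples
        Optional cohort roster; listed samples absent from ``muts`` receive
        count 0 (a sequenced sample without calls is a zero-burden sample).
    exome_length_mb
        Length of the interrogated exonic territory, megabases.
    include_classes
        Variant classes to count; defaults to all coding classes including
        synonymous.  Unknown class names raise, listing the vocabulary.
    """
    if exome_length_mb <= 0:
        raise ValueError(f"exome_length_mb must be positive, got {exome_length_mb}")
    classes = CODING_CLASSES if include_classes is None else frozenset(include_classes)
    unknown = classes - CODING_CLASSES
    if unknown:
        raise ValueError(
            f"unknown variant class(es) {sorted(unknown)}; "
            f"known vocabulary: {sorted(CODING_CLASSES)}"
        )
    kept = muts[muts["variant_class"].isin(classes)]
    counts = kept.groupby("sample").size()
    roster = (
        pd.Index(samples, name="sample") if samples is not None else counts.index
    )
    counts = counts.reindex(roster, fill_value=0).astype(int)
    return pd.DataFrame(
        {"mutation_count": counts, "tmb": counts / exome_length_mb}
    )
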