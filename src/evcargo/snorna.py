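"""Dual-library snoRNA box-class profiling.

snoRNAs (60-300 nt) are captured both as full-length molecules in a
whole-transcriptome (WTA) library and as short fragments in a size-selected
small-RNA library.  This module summarizes the most abundant snoRNA species
per library type by box class (C/D, H/ACA, scaRNA) and measures the overlap
between the two library views.  Fragments are attributed to their parent
snoRNA species; no sub-fragment identity is kept.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .quantify import top_n
from .reference_io import SNO_CLASSES, SnoAnnotation

__all__ = [
    "top20_union",
    "sno_class_summary",
    "library_overlap",
    "attribute_fragments",
]


def top20_union(group_percents: pd.DataFrame, n: int = 20) -> set[str]:
    """Union of the per-group top-n snoRNA ids (tie rules as in quantify.top_n)."""
    tn = top_n(group_percents, n)
    return set(tn["feature"])


def sno_class_summary(
    sno_ids: Iterable[str], annotation: Sequence[SnoAnnotation] | Mapping[str, str]
) -> pd.Series:
    """Counts per box class for a set of snoRNA ids.

    ``annotation`` may be SnoAnnotation records or an id -> class mapping.
    Counts over {CD, HACA, SCARNA} sum to the size of the input set; an
    unannotated id raises.
    """
    if isinstance(annotation, Mapping):
        class_of = dict(annotation)
    else:
        class_of = {a.id: a.box_class for a in annotation}
    counts = {c: 0 for c in SNO_CLASSES}
    missing = []
    for sid in sno_ids:
        if sid not in class_of:
            missing.append(sid)
        else:
            counts[class_of[sid]] += 1
    if missing:
        raise ValueError(f"snoRNA ids without annotation: {sorted(missing)}")
    return pd.Series(counts, dtype=int)


def library_overlap(set_wta: set[str], set_small: set[str]) -> tuple[int, float]:
    """(intersection size, Jaccard index) between the two library views.

    The Jaccard of two empty sets is defined as 0.
    """
    inter = len(set_wta & set_small)
    union = len(set_wta | set_small)
    return inter, (inter / union if union else 0.0)


def attribute_fragments(
    reads: Iterable[tuple[str, str]], sno_sequences: Mapping[str, str]
) -> pd.Series:
    """Count reads that are exact substrings of a snoRNA, per parent snoRNA id.

    Small-RNA-library snoRNA evidence arrives as fragments; each fragment is
    attributed to the first parent (ascending id) containing it exactly.
    Reads matching no snoRNA are ignored.  Returns counts indexed by snoRNA
    id (only ids with >= 1 fragment).
    """
    parents = sorted(sno_sequences.items())
    counts: dict[str, int] = {}
    for _, seq in reads:
        for sid, full in parents:
            if seq in full:
                counts[sid] = counts.get(sid, 0) + 1
                break
    return pd.Series(counts, dtype=int).sort_index()
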