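"""isomiR identity, classification, naming and per-miRNA variant histograms.

An isomiR is identified by its canonical miRNA plus the way it departs from
the canonical sequence: a 5' end offset, a 3' end offset (which includes any
non-templated tail), internal substitutions, and the tail itself.  Distinct
keys define distinct isomiRs.  Each key falls into exactly one of six variant
classes depending on which ends differ and whether substitutions are present.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "IsomiRKey",
    "VariantClass",
    "classify",
    "name_isomir",
    "parse_isomir_name",
    "isomir_count_table",
    "variant_class_histogram",
]


class VariantClass(str, enum.Enum):
    """The six mutually exclusive variant categories of an isomiR key."""

    CANONICAL = "CANONICAL"
    FIVE_PRIME_ONLY = "FIVE_PRIME_ONLY"
    THREE_PRIME_ONLY = "THREE_PRIME_ONLY"
    BOTH_ENDS = "BOTH_ENDS"
    SUBSTITUTION_ONLY = "SUBSTITUTION_ONLY"
    SUBSTITUTION_AND_END = "SUBSTITUTION_AND_END"

    def __str__(self) -> str:  # str(VariantClass.CANONICAL) == "CANONICAL"
        return self.value


@dataclass(frozen=True)
class IsomiRKey:
    """Canonical-collapsed identity of a read relative to its miRNA.

    ``substitutions`` positions are canonical-relative and 0-based; the tuple
    is kept sorted by position.  A non-templated tail is an end modification:
    it contributes to ``offset3`` and never to ``substitutions``.
    """

    mirna_id: str
    offset5: int = 0
    offset3: int = 0
    substitutions: tuple[tuple[int, str, str], ...] = field(default_factory=tuple)
    tail: str = ""

    def __post_init__(self) -> None:
        subs = tuple(sorted(self.substitutions, key=lambda s: s[0]))
        object.__setattr__(self, "substitutions", subs)

    @property
    def is_canonical(self) -> bool:
        return (
            self.offset5 == 0
            and self.offset3 == 0
            and not self.substitutions
            and not self.tail
        )


def classify(key: IsomiRKey) -> VariantClass:
    """Assign an isomiR key to its variant class.

    The classes partition key space: exactly one applies to every key.
    """
    end5 = key.offset5 != 0
    end3 = key.offset3 != 0 or key.tail != ""
    subs = bool(key.substitutions)
    if subs:
        if end5 or end3:
            return VariantClass.SUBSTITUTION_AND_END
        return VariantClass.SUBSTITUTION_ONLY
    if end5 and end3:
        return VariantClass.BOTH_ENDS
    if end5:
        return VariantClass.FIVE_PRIME_ONLY
    if end3:
        return VariantClass.THREE_PRIME_ONLY
    return VariantClass.CANONICAL


def name_isomir(key: IsomiRKey) -> str:
    """Render an isomiR key as a deterministic, invertible name.

    The canonical key maps to the bare miRNA id.  Any variant maps to
    ``id|5e{off}|3e{off}|s:{pos}{ref}>{alt};...|t:{tail}`` with ``-`` for
    empty substitution lists / tails.  Distinct keys yield distinct names.
    """
    if key.is_canonical:
        return key.mirna_id
    o5 = f"{key.offset5:+d}" if key.offset5 != 0 else "0"
    o3 = f"{key.offset3:+d}" if key.offset3 != 0 else "0"
    subs = ";".join(f"{p}{ref}>{alt}" for p, ref, alt in key.substitutions) or "-"
    tail = key.tail or "-"
    return f"{key.mirna_id}|5e{o5}|3e{o3}|s:{subs}|t:{tail}"


_SUB_RE = re.compile(r"^(-?\d+)([ACGT])>([ACGT])$")


def parse_isomir_name(name: str) -> IsomiRKey:
    """Invert :func:`name_isomir`; raises ValueError on malformed names."""
    if "|" not in name:
        return IsomiRKey(mirna_id=name)
    parts = name.split("|")
    if len(parts) != 5:
        raise ValueError(f"malformed isomiR name {name!r}: expected 5 '|' fields")
    mirna_id, f5, f3, fs, ft = parts
    if not f5.startswith("5e") or not f3.startswith("3e"):
        raise ValueError(f"malformed isomiR name {name!r}: bad offset fields")
    if not fs.startswith("s:") or not ft.startswith("t:"):
        raise ValueError(f"malformed isomiR name {name!r}: bad subs/tail fields")
    try:
        offset5 = int(f5[2:])
        offset3 = int(f3[2:])
    except ValueError:
        raise ValueError(f"malformed isomiR name {name!r}: non-integer offset") from None
    subs: list[tuple[int, str, str]] = []
    if fs[2:] != "-":
        for token in fs[2:].split(";"):
            m = _SUB_RE.match(token)
            if not m:
                raise ValueError(f"malformed substitution token {token!r} in {name!r}")
            subs.append((int(m.group(1)), m.group(2), m.group(3)))
    tail = "" if ft[2:] == "-" else ft[2:]
    if tail and not set(tail) <= set("ACGT"):
        raise ValueError(f"malformed tail {tail!r} in {name!r}")
    key = IsomiRKey(
        mirna_id=mirna_id,
        offset5=offset5,
        offset3=offset3,
        substitutions=tuple(subs),
        tail=tail,
    )
    if key.is_canonical:
        raise ValueError(
            f"malformed isomiR name {name!r}: canonical keys use the bare miRNA id"
        )
    return key


def isomir_count_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-read assignment table into isomiR counts per sample.

    ``assignments`` needs columns: sample_id, mirna_id, offset5, offset3,
    subs, tail (the serialized TSV convention: '-' for empty).  Returns a long
    DataFrame with columns name, mirna_id, class, sample_id, count.
    """
    from .assign import key_from_row  # deferred: avoid import cycle

    rows = assignments.copy()
    keys = [key_from_row(r) for r in rows.itertuples(index=False)]
    rows["name"] = [name_isomir(k) for k in keys]
    rows["class"] = [classify(k).value for k in keys]
    grouped = (
        rows.groupby(["name", "mirna_id", "class", "sample_id"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return grouped


def variant_class_histogram(
    isomir_counts: pd.DataFrame, include_canonical: bool = False
) -> pd.DataFrame:
    """Per-(miRNA, sample) percentages of each variant class.

    By default percentages are computed among isomiR (non-canonical) reads
    only, so that for every miRNA with at least one isomiR read the class
    percentages sum to 100; miRNAs with no isomiR reads are absent.  With
    ``include_canonical=True`` the canonical reads enter the denominator (and
    the CANONICAL class appears as a row).

    Input is the long table from :func:`isomir_count_table`; output columns
    are mirna_id, sample_id, class, percent.
    """
    df = isomir_counts
    if not include_canonical:
        df = df[df["class"] != VariantClass.CANONICAL.value]
    if df.empty:
        return pd.DataFrame(columns=["mirna_id", "sample_id", "class", "percent"])
    per_class = (
        df.groupby(["mirna_id", "sample_id", "class"], sort=True)["count"]
        .sum()
        .reset_index()
    )
    totals = per_class.groupby(["mirna_id", "sample_id"])["count"].transform("sum")
    per_class["percent"] = 100.0 * per_class["count"] / totals
    return per_class.drop(columns="count")
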