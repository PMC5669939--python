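"""Readers and writers for miRNA references, snoRNA annotation, count tables and sample sheets.

All sequences are stored internally as DNA over {A, C, G, T}; miRBase-style
RNA sequences (containing U) are converted on read so that reads and
references share one alphabet.  FASTA headers are split on whitespace: the
first token is the record id, the remainder is kept as a free-text
description.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MatureRecord",
    "HairpinRecord",
    "SnoAnnotation",
    "read_mature_fasta",
    "read_hairpin_fasta",
    "write_fasta",
    "link_mature_to_hairpin",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_sample_sheet",
    "read_sno_annotation",
    "write_sno_annotation",
]

_VALID_BASES = set("ACGT")


@dataclass
class MatureRecord:
    """A canonical mature miRNA sequence, optionally located on its hairpin.

    ``start``/``end`` are 0-based half-open coordinates on the hairpin and are
    unset (None) until :func:`link_mature_to_hairpin` is called.
    """

    id: str
    sequence: str
    hairpin_id: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HairpinRecord:
    """A pre-miRNA hairpin sequence providing templated context for end variation."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


#: canonical snoRNA box-class labels
SNO_CLASSES = ("CD", "HACA", "SCARNA")

# accepted spellings, after uppercasing and stripping '/', '-', '_', ' ' and 'BOX'
_SNO_CLASS_ALIASES = {
    "CD": "CD",
    "HACA": "HACA",
    "SCARNA": "SCARNA",
    "SCA": "SCARNA",
}


@dataclass
class SnoAnnotation:
    """snoRNA id, box class (CD / HACA / SCARNA), length and optional host gene."""

    id: str
    box_class: str
    length: int
    host_gene: Optional[str] = None
    sequence: Optional[str] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.box_class not in SNO_CLASSES:
            raise ValueError(
                f"unknown snoRNA box class {self.box_class!r} for {self.id!r}; "
                f"expected one of {SNO_CLASSES}"
            )
        if self.length <= 0:
            raise ValueError(f"snoRNA {self.id!r} has non-positive length {self.length}")


def normalize_sno_class(label: str) -> str:
    """Normalize a free-form box-class label to one of CD / HACA / SCARNA."""
    key = label.upper()
    for ch in "/-_ ":
        key = key.replace(ch, "")
    key = key.removesuffix("BOX")
    try:
        return _SNO_CLASS_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown snoRNA box class label {label!r}") from None


def _read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse FASTA into (id, sequence, description) with validation shared by
    both reference readers: uppercase, U->T, unique ids, ACGT(U) alphabet."""
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-ACGTU characters: {sorted(bad)}"
            )
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append((rec.id, seq, desc))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def read_mature_fasta(path: str | Path) -> list[MatureRecord]:
    """Read mature miRNA sequences; hairpin coordinates are left unset."""
    return [MatureRecord(id=i, sequence=s, description=d) for i, s, d in _read_fasta(path)]


def read_hairpin_fasta(path: str | Path) -> list[HairpinRecord]:
    """Read hairpin (pre-miRNA) sequences."""
    return [HairpinRecord(id=i, sequence=s, description=d) for i, s, d in _read_fasta(path)]


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    """Write records with ``.id`` and ``.sequence`` attributes as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def link_mature_to_hairpin(
    matures: Iterable[MatureRecord],
    hairpins: Iterable[HairpinRecord],
    mapping: dict[str, str],
) -> tuple[list[MatureRecord], list[str]]:
    """Locate each mature on its hairpin by exact substring search.

    Coordinates are set to the first (lowest-start) exact occurrence.  Matures
    occurring more than once on their hairpin are resolved to the first
    occurrence and reported in the returned warning list.

    Returns (linked matures, warnings).  Raises ValueError if a mature has no
    hairpin in ``mapping`` or is not a substring of its hairpin.
    """
    hp_by_id = {h.id: h for h in hairpins}
    linked: list[MatureRecord] = []
    warnings: list[str] = []
    for m in matures:
        try:
            hp_id = mapping[m.id]
        except KeyError:
            raise ValueError(f"no hairpin mapping for mature {m.id!r}") from None
        try:
            hp = hp_by_id[hp_id]
        except KeyError:
            raise ValueError(f"hairpin {hp_id!r} (for mature {m.id!r}) not found") from None
        start = hp.sequence.find(m.sequence)
        if start < 0:
            raise ValueError(f"mature {m.id!r} not found in hairpin {hp_id!r}")
        if hp.sequence.find(m.sequence, start + 1) >= 0:
            warnings.append(
                f"mature {m.id!r} occurs more than once in hairpin {hp_id!r}; "
                f"using first occurrence at {start}"
            )
        linked.append(
            MatureRecord(
                id=m.id,
                sequence=m.sequence,
                hairpin_id=hp_id,
                start=start,
                end=start + len(m.sequence),
                description=m.description,
            )
        )
    return linked, warnings


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample count table (TSV, header = sample ids,
    first column = feature ids).  Counts must be non-negative integers;
    fractional values are rejected rather than rounded."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty:
        raise ValueError(f"count table {path} has no sample columns")
    if df.index.has_duplicates:
        raise ValueError(f"duplicate feature ids in {path}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise ValueError(f"non-numeric counts in {path}")
    if (numeric < 0).any().any():
        raise ValueError(f"negative counts in {path}")
    if not (numeric == numeric.round()).all().all():
        raise ValueError(f"fractional counts in {path}; counts must be integers")
    out = numeric.astype(int)
    out.index = out.index.astype(str)
    out.index.name = "feature_id"
    out.columns = out.columns.astype(str)
    return out


def write_counts_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a count table so that :func:`read_counts_tsv` round-trips it exactly."""
    out = table.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet with columns sample_id, group_id, replicate.

    (group_id, replicate) pairs must be unique and replicate >= 1.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group_id": str})
    required = ["sample_id", "group_id", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} is missing columns {missing}")
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise ValueError("replicate numbers must be >= 1")
    if df.duplicated(subset=["group_id", "replicate"]).any():
        raise ValueError("duplicate (group_id, replicate) pairs in sample sheet")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return df[required]


def validate_sample_sheet(sheet: pd.DataFrame, counts: pd.DataFrame) -> None:
    """Check that every count-table sample appears in the sheet."""
    missing = set(counts.columns) - set(sheet["sample_id"])
    if missing:
        raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")


def read_sno_annotation(path: str | Path) -> list[SnoAnnotation]:
    """Read a snoRNA annotation TSV with columns id, box_class, length[, host_gene]."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = ["id", "box_class", "length"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"snoRNA annotation {path} is missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        host = getattr(row, "host_gene", None)
        if pd.isna(host):
            host = None
        records.append(
            SnoAnnotation(
                id=str(row.id),
                box_class=normalize_sno_class(str(row.box_class)),
                length=int(row.length),
                host_gene=host,
            )
        )
    return records


def write_sno_annotation(records: Iterable[SnoAnnotation], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "box_class": r.box_class,
            "length": r.length,
            "host_gene": r.host_gene if r.host_gene is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
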