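"""Assignment of small-RNA reads to canonical mature miRNAs.

Each read is placed, ungapped, against every candidate (mature, 5'-offset)
position on the mature's hairpin.  A placement fixes the 3' offset through the
read length; terminal bases in the 3' extension region that mismatch the
hairpin (or fall beyond its end) may be recorded as a non-templated tail.
Among all placements within the parameter bounds the assignment minimizing
(number of substitutions, tail length, |offset5| + |offset3|) wins,
lexicographically; remaining ties break by ascending miRNA id, then ascending
5' offset, so results do not depend on reference file order.

Sign conventions: offset5 = read_start - mature_start on the hairpin
(negative = 5' extension, positive = 5' trimming); offset3 = read_end -
mature_end (positive = 3' extension, negative = 3' trimming).  offset3
includes the tail; tail length <= min(max_tail, max(offset3, 0)).

5' extensions must be templated (copied from the hairpin): a placement that
would start before the hairpin is invalid.  3' extensions may be templated or
carried by the tail.  Mismatches in the non-tail span anywhere in the read are
substitutions, recorded at canonical-relative positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .reference_io import HairpinRecord, MatureRecord

__all__ = [
    "AssignmentParams",
    "ReadAssignment",
    "MirnaIndex",
    "build_index",
    "assign_read",
    "assign_library",
    "write_assignment_tsv",
    "key_from_assignment",
    "key_from_row",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class AssignmentParams:
    """Bounds of the placement search.

    max_5p_shift / max_3p_shift bound |offset5| and |offset3| (the latter
    including any tail); max_tail bounds the non-templated tail; max_subs
    bounds internal substitutions; reads shorter than min_read_len are
    reported UNASSIGNED.
    """

    max_5p_shift: int = 3
    max_3p_shift: int = 5
    max_tail: int = 3
    max_subs: int = 2
    min_read_len: int = 16

    def __post_init__(self) -> None:
        for name in ("max_5p_shift", "max_3p_shift", "max_tail", "max_subs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_read_len < 16:
            raise ValueError("min_read_len must be >= 16")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    mirna_id: str
    offset5: int
    offset3: int
    substitutions: tuple[tuple[int, str, str], ...]
    tail: str

    @property
    def score(self) -> tuple[int, int, int]:
        return (len(self.substitutions), len(self.tail), abs(self.offset5) + abs(self.offset3))


@dataclass(frozen=True)
class _Candidate:
    """One (mature, offset5) anchor precomputed at index build time."""

    mirna_id: str
    hairpin: str
    mature_start: int
    mature_end: int
    read_start: int  # mature_start + offset5; always >= 0 (templated 5')
    offset5: int


class MirnaIndex:
    """Enumerates candidate placements for reads; equivalent to brute force.

    The index simply precomputes, for every mature and every admissible 5'
    offset, the hairpin anchor a read would occupy, sorted by (mirna_id,
    offset5) so iteration order realizes the tie-breaking rules.
    """

    def __init__(
        self,
        matures: Iterable[MatureRecord],
        hairpins: Iterable[HairpinRecord],
        max_5p_shift: int = AssignmentParams.max_5p_shift,
    ):
        matures = list(matures)
        if not matures:
            raise ValueError("cannot build an assignment index over an empty reference")
        hp_by_id = {h.id: h.sequence for h in hairpins}
        self.max_5p_shift = max_5p_shift
        self.candidates: list[_Candidate] = []
        for m in sorted(matures, key=lambda m: m.id):
            if m.start is None or m.hairpin_id is None:
                raise ValueError(f"mature {m.id!r} is not linked to a hairpin")
            hp = hp_by_id[m.hairpin_id]
            for off5 in range(-max_5p_shift, max_5p_shift + 1):
                rs = m.start + off5
                if rs < 0:
                    continue  # 5' extension beyond the hairpin cannot be templated
                self.candidates.append(
                    _Candidate(
                        mirna_id=m.id,
                        hairpin=hp,
                        mature_start=m.start,
                        mature_end=m.end,
                        read_start=rs,
                        offset5=off5,
                    )
                )


def build_index(
    matures: Iterable[MatureRecord],
    hairpins: Iterable[HairpinRecord],
    max_5p_shift: int = AssignmentParams.max_5p_shift,
) -> MirnaIndex:
    return MirnaIndex(matures, hairpins, max_5p_shift=max_5p_shift)


def _score_candidate(
    read: str, cand: _Candidate, params: AssignmentParams
) -> Optional[tuple[tuple[int, int, int], ReadAssignment]]:
    """Score one placement; None if it violates the parameter bounds.

    The tail length is chosen to minimize (n_subs, tail_len): the longest
    admissible tail absorbs the most terminal mismatches, then the tail is
    shrunk while its innermost base matches the hairpin (a matching base is
    templated extension, not tail).
    """
    L = len(read)
    hp = cand.hairpin
    rs = cand.read_start
    offset3 = (rs + L) - cand.mature_end
    if abs(offset3) > params.max_3p_shift or abs(cand.offset5) > params.max_5p_shift:
        return None
    overhang = max(0, rs + L - len(hp))  # beyond hairpin end: must be tail
    t_allow = min(params.max_tail, max(offset3, 0))
    if overhang > t_allow:
        return None
    template = hp[rs : rs + L]
    mism = [i for i in range(len(template)) if read[i] != template[i]]
    # suffix_mm[t] = mismatches in the last t templated positions
    best: Optional[tuple[int, int]] = None  # (n_subs, tail_len)
    n_mism = len(mism)
    for t in range(overhang, t_allow + 1):
        cut = L - t
        subs_count = sum(1 for i in mism if i < cut)
        if subs_count > params.max_subs:
            continue
        if best is None or (subs_count, t) < best:
            best = (subs_count, t)
    if best is None:
        return None
    n_subs, tail_len = best
    cut = L - tail_len
    subs = tuple(
        (rs + i - cand.mature_start, template[i], read[i]) for i in mism if i < cut
    )
    tail = read[cut:]
    asn = ReadAssignment(
        read_id="",
        mirna_id=cand.mirna_id,
        offset5=cand.offset5,
        offset3=offset3,
        substitutions=subs,
        tail=tail,
    )
    return (n_subs, tail_len, abs(cand.offset5) + abs(offset3)), asn


def assign_read(
    read: str, index: MirnaIndex, params: AssignmentParams = AssignmentParams(), read_id: str = ""
) -> Optional[ReadAssignment]:
    """Best single assignment of a read, or None (UNASSIGNED).

    Reads shorter than min_read_len return None; invalid characters raise.
    """
    read = read.upper()
    bad = set(read) - _VALID
    if bad:
        raise ValueError(f"read contains invalid characters: {sorted(bad)}")
    if len(read) < params.min_read_len:
        return None
    best: Optional[tuple[tuple[int, int, int], ReadAssignment]] = None
    # candidates are pre-sorted by (mirna_id, offset5); strict '<' keeps the first
    for cand in index.candidates:
        if abs(cand.offset5) > params.max_5p_shift:
            continue
        scored = _score_candidate(read, cand, params)
        if scored is None:
            continue
        if best is None or scored[0] < best[0]:
            best = scored
    if best is None:
        return None
    asn = best[1]
    if read_id:
        asn = ReadAssignment(
            read_id=read_id,
            mirna_id=asn.mirna_id,
            offset5=asn.offset5,
            offset3=asn.offset3,
            substitutions=asn.substitutions,
            tail=asn.tail,
        )
    return asn


def _iter_reads(source) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ/FASTA path or an iterable of pairs."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fastq" if first == "@" else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield rec.id, str(rec.seq).upper()
    else:
        for read_id, seq in source:
            yield read_id, seq.upper()


def assign_library(
    reads, index: MirnaIndex, params: AssignmentParams = AssignmentParams()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign every read in a library; returns (assignment table, counters).

    ``reads`` is a FASTQ/FASTA path or an iterable of (read_id, sequence).
    The result is identical to calling :func:`assign_read` per read; a
    vectorized mismatch-count prefilter prunes placements that provably cannot
    satisfy the bounds (total mismatches > max_subs + admissible tail).

    The table has one row per read; unassigned reads carry mirna_id '-'.
    Counters satisfy assigned + unassigned == total reads.
    """
    pairs = list(_iter_reads(reads))
    n_total = len(pairs)
    rows: list[dict] = []
    counters = {"assigned": 0, "unassigned": 0}
    if n_total == 0:
        empty = pd.DataFrame(
            columns=["read_id", "mirna_id", "offset5", "offset3", "subs", "tail"]
        )
        return empty, counters

    base_code = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT", start=1):
        base_code[ord(b)] = i

    # group reads by length for the vectorized prefilter
    by_len: dict[int, list[int]] = {}
    for i, (_, seq) in enumerate(pairs):
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"read {pairs[i][0]!r} contains invalid characters: {sorted(bad)}"
            )
        by_len.setdefault(len(seq), []).append(i)

    candidate_lists: dict[int, list[_Candidate]] = {i: [] for i in range(n_total)}
    slack = params.max_subs + params.max_tail
    for L, idxs in by_len.items():
        if L < params.min_read_len:
            continue
        mat = np.frombuffer(
            "".join(pairs[i][1] for i in idxs).encode(), dtype=np.uint8
        ).reshape(len(idxs), L)
        mat = base_code[mat]
        for cand in index.candidates:
            if abs(cand.offset5) > params.max_5p_shift:
                continue
            rs = cand.read_start
            offset3 = (rs + L) - cand.mature_end
            if abs(offset3) > params.max_3p_shift:
                continue
            t_allow = min(params.max_tail, max(offset3, 0))
            overhang = max(0, rs + L - len(cand.hairpin))
            if overhang > t_allow:
                continue
            tmpl = np.zeros(L, dtype=np.uint8)  # 0 = beyond hairpin: never matches
            seg = cand.hairpin[rs : rs + L]
            tmpl[: len(seg)] = base_code[np.frombuffer(seg.encode(), dtype=np.uint8)]
            n_mm = (mat != tmpl).sum(axis=1)
            hits = np.nonzero(n_mm <= params.max_subs + t_allow)[0]
            for h in hits:
                candidate_lists[idxs[h]].append(cand)

    for i, (read_id, seq) in enumerate(pairs):
        if len(seq) < params.min_read_len:
            asn = None
        else:
            best = None
            for cand in candidate_lists[i]:
                scored = _score_candidate(seq, cand, params)
                if scored is None:
                    continue
                if best is None or scored[0] < best[0]:
                    best = scored
            asn = best[1] if best is not None else None
        if asn is None:
            counters["unassigned"] += 1
            rows.append(
                {"read_id": read_id, "mirna_id": "-", "offset5": 0, "offset3": 0,
                 "subs": "-", "tail": "-"}
            )
        else:
            counters["assigned"] += 1
            rows.append(
                {
                    "read_id": read_id,
                    "mirna_id": asn.mirna_id,
                    "offset5": asn.offset5,
                    "offset3": asn.offset3,
                    "subs": serialize_subs(asn.substitutions),
                    "tail": asn.tail or "-",
                }
            )
    return pd.DataFrame(rows), counters


def serialize_subs(subs: tuple[tuple[int, str, str], ...]) -> str:
    return ";".join(f"{p}:{ref}>{alt}" for p, ref, alt in subs) or "-"


def parse_subs(text: str) -> tuple[tuple[int, str, str], ...]:
    if text in ("-", ""):
        return ()
    out = []
    for token in text.split(";"):
        pos, change = token.split(":")
        ref, alt = change.split(">")
        out.append((int(pos), ref, alt))
    return tuple(out)


def write_assignment_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def key_from_assignment(asn: ReadAssignment):
    from .isomir import IsomiRKey

    return IsomiRKey(
        mirna_id=asn.mirna_id,
        offset5=asn.offset5,
        offset3=asn.offset3,
        substitutions=asn.substitutions,
        tail=asn.tail,
    )


def key_from_row(row):
    """IsomiRKey from a serialized assignment-table row (namedtuple or Series)."""
    from .isomir import IsomiRKey

    tail = row.tail
    return IsomiRKey(
        mirna_id=row.mirna_id,
        offset5=int(row.offset5),
        offset3=int(row.offset3),
        substitutions=parse_subs(row.subs),
        tail="" if tail == "-" else tail,
    )
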