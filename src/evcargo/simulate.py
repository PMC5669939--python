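"""Synthetic small-RNA references, abundance profiles, reads and biophysics inputs.

The generator emulates the study conditions of an EV small-RNA cargo
experiment on a handful of cell lines: four groups with two biological
replicates each; a shared core of highly abundant miRNAs present in every
group plus a few group-specific miRNAs abundant in only one; multinomial
sampling noise between replicates; an isomiR process dominated by 3'-end
variation with occasional templated 5' shifts, non-templated A/U tails and
rare internal substitutions; and a snoRNA population carried both as
full-length molecules (60-300 nt, profiled WTA-style) and as short fragments
entering the small-RNA library.

Every read is emitted together with its ground truth (source, offsets,
substitutions, tail and variant class) so each downstream stage can be
verified by parameter recovery.  All randomness flows from the single seed in
:class:`SimConfig` through one generator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .isomir import IsomiRKey, classify
from .reference_io import HairpinRecord, MatureRecord, SnoAnnotation

__all__ = [
    "SimConfig",
    "SimulatedReference",
    "simulate_reference",
    "simulate_abundances",
    "simulate_sno_abundances",
    "simulate_reads",
    "simulate_spectrum",
    "simulate_size_histogram",
    "write_fastq",
    "write_truth_tsv",
    "sample_sheet_frame",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def _default_dist_3p() -> dict[int, float]:
    # 3'-skewed end variation: most reads canonical at the 3' end, trimming
    # slightly more common than extension
    return {-2: 0.03, -1: 0.09, 0: 0.78, 1: 0.07, 2: 0.03}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a four-cell-line EV experiment with duplicate
    libraries, a 14-member shared abundant core, three group-specific miRNAs
    per line, a 3'-dominated isomiR process and a ~10% snoRNA-fragment
    admixture.
    """

    seed: int = 0
    n_groups: int = 4
    n_replicates: int = 2
    n_mirnas: int = 60
    n_shared_core: int = 14
    n_group_specific: int = 3
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    reads_per_sample: int = 20000
    p_5p_shift: float = 0.05
    dist_3p_offset: dict[int, float] = field(default_factory=_default_dist_3p)
    sub_rate: float = 0.002
    tail_rate: float = 0.05
    tail_max: int = 3
    n_snornas: int = 40
    sno_length_range: tuple[int, int] = (60, 300)
    sno_fragment_length_range: tuple[int, int] = (20, 35)
    sno_fragment_fraction: float = 0.1
    #: optional per-box-class abundance weights for the WTA-style (full-length)
    #: and small-RNA-style (fragment) snoRNA pools, e.g. {"CD": 3, "HACA": 1}
    sno_wta_class_weights: Optional[dict[str, float]] = None
    sno_small_class_weights: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        for p in (self.p_5p_shift, self.sub_rate, self.tail_rate, self.sno_fragment_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.dist_3p_offset.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dist_3p_offset must sum to 1 (got {total})")
        if self.n_shared_core + self.n_groups * self.n_group_specific > self.n_mirnas:
            raise ValueError("core + group-specific miRNAs exceed n_mirnas")
        lo, hi = self.sno_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid sno_length_range")
        if self.tail_max < 0:
            raise ValueError("tail_max must be >= 0")

    @property
    def group_ids(self) -> list[str]:
        return [f"group{g + 1}" for g in range(self.n_groups)]

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{g}_rep{r + 1}"
            for g in self.group_ids
            for r in range(self.n_replicates)
        ]


@dataclass
class SimulatedReference:
    hairpins: list[HairpinRecord]
    matures: list[MatureRecord]
    sno_annotation: list[SnoAnnotation]

    @property
    def sno_sequences(self) -> dict[str, str]:
        return {s.id: s.sequence for s in self.sno_annotation}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def simulate_reference(config: SimConfig) -> SimulatedReference:
    """Generate hairpins each embedding one mature, plus annotated snoRNAs.

    Mature lengths are uniform in [20, 23]; hairpin flanks are uniform random
    5-30 nt on each side, so end variation of a few nt is always templatable.
    snoRNA box classes are drawn CD/HACA/SCARNA with probabilities
    0.5/0.4/0.1 and lengths uniform in ``sno_length_range``.
    """
    rng = np.random.default_rng(config.seed)
    hairpins: list[HairpinRecord] = []
    matures: list[MatureRecord] = []
    for i in range(config.n_mirnas):
        mat_len = int(rng.integers(20, 24))
        left = int(rng.integers(5, 31))
        right = int(rng.integers(5, 31))
        mature_seq = _random_seq(rng, mat_len)
        hairpin_seq = _random_seq(rng, left) + mature_seq + _random_seq(rng, right)
        hp_id = f"sim-mir-{i + 1:03d}"
        m_id = f"sim-miR-{i + 1:03d}"
        hairpins.append(HairpinRecord(id=hp_id, sequence=hairpin_seq))
        matures.append(
            MatureRecord(
                id=m_id,
                sequence=mature_seq,
                hairpin_id=hp_id,
                start=left,
                end=left + mat_len,
            )
        )
    classes = rng.choice(["CD", "HACA", "SCARNA"], size=config.n_snornas, p=[0.5, 0.4, 0.1])
    lo, hi = config.sno_length_range
    snos = []
    for i in range(config.n_snornas):
        length = int(rng.integers(lo, hi + 1))
        snos.append(
            SnoAnnotation(
                id=f"sim-sno-{i + 1:03d}",
                box_class=str(classes[i]),
                length=length,
                sequence=_random_seq(rng, length),
            )
        )
    return SimulatedReference(hairpins=hairpins, matures=matures, sno_annotation=snos)


def simulate_abundances(config: SimConfig, matures: list[MatureRecord]) -> pd.DataFrame:
    """Expected miRNA proportions per group (miRNA x group, columns sum to 1).

    The first ``n_shared_core`` miRNAs form a shared abundant core: their
    (jittered) abundance exceeds every background miRNA in every group, so
    they always rank in the top (core + specific) of each group.  The next
    ``n_groups * n_group_specific`` miRNAs are group-specific: abundant in
    exactly one group and absent (proportion 0) elsewhere.  The remainder is
    a log-normal background shared by all groups.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = [m.id for m in matures]
    n = len(ids)
    nc, ns, ng = config.n_shared_core, config.n_group_specific, config.n_groups
    bg_lo = nc + ns * ng
    vals = np.zeros((n, ng))
    background = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=(n - bg_lo, ng))
    vals[bg_lo:, :] = background
    ceiling = background.max() if background.size else 1.0
    # core strictly above every background value, everywhere
    vals[:nc, :] = ceiling * rng.uniform(1.5, 4.0, size=(nc, ng))
    for g in range(ng):
        rows = slice(nc + g * ns, nc + (g + 1) * ns)
        vals[rows, g] = ceiling * rng.uniform(1.5, 4.0, size=ns)
    vals /= vals.sum(axis=0, keepdims=True)
    return pd.DataFrame(vals, index=ids, columns=config.group_ids)


def simulate_sno_abundances(config: SimConfig, reference: SimulatedReference) -> pd.DataFrame:
    """Expected snoRNA proportions per group for the full-length (WTA) pool.

    Log-normal per-group abundances, optionally biased by box class through
    ``sno_wta_class_weights`` (e.g. to plant an H/ACA-rich full-length pool).
    """
    rng = np.random.default_rng(config.seed + 2)
    ids = [s.id for s in reference.sno_annotation]
    vals = rng.lognormal(config.lognormal_mu, config.lognormal_sigma,
                         size=(len(ids), config.n_groups))
    if config.sno_wta_class_weights:
        w = np.array(
            [config.sno_wta_class_weights.get(s.box_class, 1.0)
             for s in reference.sno_annotation]
        )
        vals *= w[:, None]
    vals /= vals.sum(axis=0, keepdims=True)
    return pd.DataFrame(vals, index=ids, columns=config.group_ids)


def _choose_weighted(rng: np.random.Generator, values: list, probs: np.ndarray, size: int):
    return rng.choice(len(values), size=size, p=probs)


def _simulate_mirna_read(
    rng: np.random.Generator,
    mature: MatureRecord,
    hairpin: str,
    config: SimConfig,
    offs3: list[int],
    p3: np.ndarray,
) -> tuple[str, IsomiRKey]:
    """One read from a mature miRNA under the isomiR process; returns
    (sequence, ground-truth key in the same canonical form the assigner uses)."""
    start, end = mature.start, mature.end
    # 5' offset: templated +-1 with probability p_5p_shift, clipped to hairpin
    off5 = 0
    if rng.random() < config.p_5p_shift:
        off5 = -1 if rng.random() < 0.5 else 1
        if start + off5 < 0:
            off5 = 0
    # templated 3' offset, clipped to available 3' flank
    off3 = offs3[int(rng.choice(len(offs3), p=p3))]
    off3 = min(off3, len(hairpin) - end)
    tail = ""
    if off3 > 0 and rng.random() < config.tail_rate and config.tail_max > 0:
        t = min(int(rng.integers(1, config.tail_max + 1)), off3)
        tail_chars = []
        for k in range(t):
            pos = end + off3 - t + k
            tmpl = hairpin[pos] if pos < len(hairpin) else None
            options = [b for b in "AT" if b != tmpl] or ["A", "T"]
            tail_chars.append(options[int(rng.integers(0, len(options)))])
        tail = "".join(tail_chars)
    rs = start + off5
    re_ = end + off3
    templated = hairpin[rs : re_ - len(tail)]
    # substitutions only at positions inside the canonical mature span; a
    # substituted base in the end-variation region would be indistinguishable
    # from tailing, so the generative record would no longer be canonical
    seq = list(templated)
    subs: list[tuple[int, str, str]] = []
    for i, hp_pos in enumerate(range(rs, re_ - len(tail))):
        if start <= hp_pos < end and rng.random() < config.sub_rate:
            ref = seq[i]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            seq[i] = alt
            subs.append((hp_pos - start, ref, alt))
    key = IsomiRKey(
        mirna_id=mature.id,
        offset5=off5,
        offset3=off3,
        substitutions=tuple(subs),
        tail=tail,
    )
    return "".join(seq) + tail, key


def simulate_reads(
    config: SimConfig,
    reference: SimulatedReference,
    abundances: pd.DataFrame,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Simulate per-sample small-RNA reads with per-read ground truth.

    Returns (reads, truth): ``reads`` maps sample_id to a list of
    (read_id, sequence); ``truth`` is a DataFrame with one row per read
    (read_id, sample_id, source_id, offset5, offset3, subs, tail, true_class).
    miRNA reads are drawn multinomially from the sample's group abundances;
    a ``sno_fragment_fraction`` share of reads are uniform substrings of
    snoRNAs (fragment lengths uniform in ``sno_fragment_length_range``),
    optionally class-biased via ``sno_small_class_weights``.
    """
    rng = np.random.default_rng(config.seed + 3)
    mat_by_id = {m.id: m for m in reference.matures}
    hp_by_id = {h.id: h.sequence for h in reference.hairpins}
    offs3 = sorted(config.dist_3p_offset)
    p3 = np.array([config.dist_3p_offset[o] for o in offs3])
    p3 = p3 / p3.sum()

    sno_ids = [s.id for s in reference.sno_annotation]
    sno_seqs = reference.sno_sequences
    if config.sno_small_class_weights and sno_ids:
        sw = np.array(
            [config.sno_small_class_weights.get(s.box_class, 1.0)
             for s in reference.sno_annotation],
            dtype=float,
        )
        sw = sw / sw.sum()
    elif sno_ids:
        sw = np.full(len(sno_ids), 1.0 / len(sno_ids))
    else:
        sw = None

    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows: list[dict] = []
    frag_lo, frag_hi = config.sno_fragment_length_range
    for group in config.group_ids:
        probs = abundances[group].to_numpy()
        mirna_ids = list(abundances.index)
        for rep in range(config.n_replicates):
            sample = f"{group}_rep{rep + 1}"
            out: list[tuple[str, str]] = []
            n_sno = int(round(config.sno_fragment_fraction * config.reads_per_sample)) if sw is not None else 0
            n_mirna = config.reads_per_sample - n_sno
            sources = rng.choice(len(mirna_ids), size=n_mirna, p=probs)
            for j, src in enumerate(sources):
                m = mat_by_id[mirna_ids[src]]
                seq, key = _simulate_mirna_read(
                    rng, m, hp_by_id[m.hairpin_id], config, offs3, p3
                )
                read_id = f"{sample}:r{j + 1:06d}"
                out.append((read_id, seq))
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "sample_id": sample,
                        "source_id": m.id,
                        "offset5": key.offset5,
                        "offset3": key.offset3,
                        "subs": ";".join(
                            f"{p}:{r}>{a}" for p, r, a in key.substitutions
                        ) or "-",
                        "tail": key.tail or "-",
                        "true_class": classify(key).value,
                    }
                )
            if n_sno:
                picks = rng.choice(len(sno_ids), size=n_sno, p=sw)
                for j, src in enumerate(picks):
                    sid = sno_ids[src]
                    full = sno_seqs[sid]
                    flen = int(rng.integers(frag_lo, min(frag_hi, len(full)) + 1))
                    pos = int(rng.integers(0, len(full) - flen + 1))
                    seq = full[pos : pos + flen]
                    read_id = f"{sample}:s{j + 1:06d}"
                    out.append((read_id, seq))
                    truth_rows.append(
                        {
                            "read_id": read_id,
                            "sample_id": sample,
                            "source_id": sid,
                            "offset5": 0,
                            "offset3": 0,
                            "subs": "-",
                            "tail": "-",
                            "true_class": "SNORNA_FRAGMENT",
                        }
                    )
            reads[sample] = out
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Write reads as 4-line FASTQ records with constant quality 'I' (Phred+33)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, lineterminator="\n")


def sample_sheet_frame(config: SimConfig) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{g}_rep{r + 1}", "group_id": g, "replicate": r + 1}
        for g in config.group_ids
        for r in range(config.n_replicates)
    ]
    return pd.DataFrame(rows)


def simulate_spectrum(
    seed: int = 0,
    peak_over_shoulder: float = 3.0,
    wavelengths: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Synthetic gold-nanoparticle UV-Vis spectrum (400-900 nm, 1 nm steps).

    A Lorentzian plasmon peak at 519 nm over a broad aggregation shoulder
    near 650 nm; ``peak_over_shoulder`` sets the approximate A519/A650 ratio.
    Returns a DataFrame with columns wavelength_nm, absorbance.
    """
    rng = np.random.default_rng(seed)
    if wavelengths is None:
        wavelengths = np.arange(400.0, 901.0, 1.0)
    peak = 1.0 / (1.0 + ((wavelengths - 519.0) / 35.0) ** 2)
    shoulder = 1.0 / (1.0 + ((wavelengths - 650.0) / 120.0) ** 2)
    # solve mixture weights so that A(519)/A(650) == peak_over_shoulder
    p519 = 1.0
    s519 = 1.0 / (1.0 + ((519.0 - 650.0) / 120.0) ** 2)
    p650 = 1.0 / (1.0 + ((650.0 - 519.0) / 35.0) ** 2)
    s650 = 1.0
    # absorbance = peak + w * shoulder; ratio r = (p519 + w s519)/(p650 + w s650)
    r = peak_over_shoulder
    w = (p519 - r * p650) / (r * s650 - s519)
    if w < 0:
        raise ValueError("peak_over_shoulder outside the attainable range")
    absorbance = peak + w * shoulder
    if noise_sd > 0:
        absorbance = np.clip(absorbance + rng.normal(0, noise_sd, absorbance.size), 0, None)
    return pd.DataFrame({"wavelength_nm": wavelengths, "absorbance": absorbance})


def simulate_size_histogram(
    seed: int = 0,
    n_particles: int = 230,
    mean_log_nm: float = 4.17,
    sd_log_nm: float = 0.35,
    bin_width_nm: float = 10.0,
) -> pd.DataFrame:
    """Synthetic AFM particle-size histogram.

    Log-normal diameters (default median ~65 nm, the small-EV regime peaking
    at 60-70 nm) binned at ``bin_width_nm``; bins below 30 nm are retained in
    the output so the exclusion rule of the mean-diameter computation is
    exercised.  Returns a DataFrame with columns diameter_nm (bin centers)
    and count.
    """
    rng = np.random.default_rng(seed)
    diam = rng.lognormal(mean_log_nm, sd_log_nm, size=n_particles)
    diam = diam[diam <= 250.0]
    edges = np.arange(0.0, 260.0, bin_width_nm)
    counts, _ = np.histogram(diam, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = counts > 0
    return pd.DataFrame({"diameter_nm": centers[keep], "count": counts[keep]})
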