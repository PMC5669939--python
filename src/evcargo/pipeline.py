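"""End-to-end pipeline: simulate -> assign -> classify -> quantify -> cluster
-> snoRNA profiling -> biophysics, with a digest manifest for reproducibility.

Every stage writes plain-text outputs into the run directory and registers
them in a manifest (file name -> SHA-256).  A run is fully determined by its
configuration and seed: re-running with the same config yields byte-identical
outputs and therefore an identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import assign as assign_mod
from . import biophysics, cluster, isomir, quantify, simulate, snorna
from .reference_io import (
    read_hairpin_fasta,
    read_mature_fasta,
    read_sample_sheet,
    read_sno_annotation,
    link_mature_to_hairpin,
    write_counts_tsv,
    write_fasta,
    write_sno_annotation,
)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger("evcargo")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With ``simulate_inputs`` (the default) the synthetic-data module
    generates references, reads and biophysics inputs from ``sim``; otherwise
    the listed input paths must exist before any stage runs.
    """

    out_dir: str = "evcargo_run"
    seed: int = 0
    simulate_inputs: bool = True
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    assignment: assign_mod.AssignmentParams = field(default_factory=assign_mod.AssignmentParams)
    threshold_percent: float = quantify.DEFAULT_THRESHOLD_PERCENT
    top_n: int = 10
    sno_top_n: int = 20
    pseudocount: float = cluster.DEFAULT_PSEUDOCOUNT
    wta_reads_per_sample: int = 100000
    # external inputs (used when simulate_inputs is False)
    mature_fasta: Optional[str] = None
    hairpin_fasta: Optional[str] = None
    mature_hairpin_map: Optional[str] = None  # TSV: mature_id, hairpin_id
    reads_dir: Optional[str] = None  # one FASTQ per sample: <sample_id>.fastq
    sample_sheet: Optional[str] = None
    sno_annotation: Optional[str] = None
    spectrum: Optional[str] = None
    size_histogram: Optional[str] = None


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {})
    if "dist_3p_offset" in sim_raw:
        sim_raw["dist_3p_offset"] = {int(k): float(v) for k, v in sim_raw["dist_3p_offset"].items()}
    for tup_key in ("sno_length_range", "sno_fragment_length_range"):
        if tup_key in sim_raw:
            sim_raw[tup_key] = tuple(sim_raw[tup_key])
    asn_raw = raw.pop("assignment", {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if sim_raw:
        cfg.sim = simulate.SimConfig(**{**dataclasses.asdict(cfg.sim), **sim_raw})
    if asn_raw:
        cfg.assignment = assign_mod.AssignmentParams(**asn_raw)
    cfg.sim.seed = cfg.seed
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns the manifest dict.

    Any stage failure aborts with the stage name and cause.  The manifest
    (also written to <out_dir>/manifest.json) lists each output file with its
    SHA-256 digest plus the run's headline counters.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    stats: dict = {"seed": config.seed}

    if not config.simulate_inputs:
        required = {
            "mature_fasta": config.mature_fasta,
            "hairpin_fasta": config.hairpin_fasta,
            "mature_hairpin_map": config.mature_hairpin_map,
            "reads_dir": config.reads_dir,
            "sample_sheet": config.sample_sheet,
        }
        missing = [k for k, v in required.items() if v is None or not Path(v).exists()]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("simulate" if config.simulate_inputs else "load-inputs")
        if config.simulate_inputs:
            config.sim.seed = config.seed
            ref = simulate.simulate_reference(config.sim)
            abundances = simulate.simulate_abundances(config.sim, ref.matures)
            reads, truth = simulate.simulate_reads(config.sim, ref, abundances)
            sheet = simulate.sample_sheet_frame(config.sim)
            write_fasta(ref.matures, out / "mature.fa")
            write_fasta(ref.hairpins, out / "hairpin.fa")
            write_sno_annotation(ref.sno_annotation, out / "sno_annotation.tsv")
            simulate.write_truth_tsv(truth, out / "sim_truth.tsv")
            sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False, lineterminator="\n")
            for sample, rs in reads.items():
                simulate.write_fastq(rs, out / f"{sample}.fastq")
                files.append(out / f"{sample}.fastq")
            files += [
                out / "mature.fa", out / "hairpin.fa", out / "sno_annotation.tsv",
                out / "sim_truth.tsv", out / "sample_sheet.tsv",
            ]
            matures, hairpins = ref.matures, ref.hairpins
            sno_ann = ref.sno_annotation
            sno_seqs = ref.sno_sequences
        else:
            matures = read_mature_fasta(config.mature_fasta)
            hairpins = read_hairpin_fasta(config.hairpin_fasta)
            mapping_df = pd.read_csv(config.mature_hairpin_map, sep="\t")
            mapping = dict(zip(mapping_df.iloc[:, 0], mapping_df.iloc[:, 1]))
            matures, warnings = link_mature_to_hairpin(matures, hairpins, mapping)
            for w in warnings:
                logger.warning(w)
            sheet = read_sample_sheet(config.sample_sheet)
            reads = {
                s: list(assign_mod._iter_reads(Path(config.reads_dir) / f"{s}.fastq"))
                for s in sheet["sample_id"]
            }
            sno_ann = read_sno_annotation(config.sno_annotation) if config.sno_annotation else []
            sno_seqs = {a.id: a.sequence for a in sno_ann if a.sequence}

        stage("assign")
        index = assign_mod.build_index(matures, hairpins, config.assignment.max_5p_shift)
        all_assignments = []
        n_assigned = n_unassigned = 0
        unassigned_reads: dict[str, list[tuple[str, str]]] = {}
        for sample in sheet["sample_id"]:
            table, counters = assign_mod.assign_library(reads[sample], index, config.assignment)
            table.insert(0, "sample_id", sample)
            assign_mod.write_assignment_tsv(table, out / f"{sample}.assignments.tsv")
            files.append(out / f"{sample}.assignments.tsv")
            n_assigned += counters["assigned"]
            n_unassigned += counters["unassigned"]
            seq_of = dict(reads[sample])
            unassigned_reads[sample] = [
                (r, seq_of[r]) for r in table.loc[table["mirna_id"] == "-", "read_id"]
            ]
            all_assignments.append(table[table["mirna_id"] != "-"])
            logger.info(
                "sample %s: %d assigned, %d unassigned",
                sample, counters["assigned"], counters["unassigned"],
            )
        assignments = pd.concat(all_assignments, ignore_index=True)
        stats["reads_total"] = n_assigned + n_unassigned
        stats["reads_assigned"] = n_assigned
        stats["reads_unassigned"] = n_unassigned

        stage("classify")
        iso_counts = isomir.isomir_count_table(assignments)
        iso_counts.to_csv(out / "isomir_counts.tsv", sep="\t", index=False, lineterminator="\n")
        hist = isomir.variant_class_histogram(iso_counts)
        hist.to_csv(out / "variant_class_histogram.tsv", sep="\t", index=False,
                    lineterminator="\n", float_format="%.6g")
        files += [out / "isomir_counts.tsv", out / "variant_class_histogram.tsv"]

        stage("quantify")
        mirna_counts = (
            assignments.groupby(["mirna_id", "sample_id"]).size().unstack(fill_value=0)
        )
        mirna_counts = mirna_counts.reindex(columns=list(sheet["sample_id"]), fill_value=0)
        write_counts_tsv(mirna_counts, out / "mirna_counts.tsv")
        percents = quantify.percent_of_total(mirna_counts)
        gmeans = quantify.group_mean(percents, sheet)
        retained = quantify.threshold_filter(gmeans, config.threshold_percent)
        pd.Series(retained, name="feature_id").to_csv(
            out / "retained_features.tsv", sep="\t", index=False, lineterminator="\n"
        )
        tn = quantify.top_n(gmeans, config.top_n)
        tn.to_csv(out / "top_n.tsv", sep="\t", index=False, lineterminator="\n",
                  float_format="%.6g")
        share = quantify.cumulative_top_share(gmeans, config.top_n)
        share.rename("cumulative_percent").to_frame().to_csv(
            out / "cumulative_top_share.tsv", sep="\t", lineterminator="\n",
            float_format="%.6g", index_label="group",
        )
        frac = quantify.isomir_fraction(iso_counts)
        frac.rename("isomir_fraction").to_frame().to_csv(
            out / "isomir_fraction.tsv", sep="\t", lineterminator="\n",
            float_format="%.6g", index_label="sample_id",
        )
        files += [
            out / "mirna_counts.tsv", out / "retained_features.tsv", out / "top_n.tsv",
            out / "cumulative_top_share.tsv", out / "isomir_fraction.tsv",
        ]
        stats["features_in"] = int(mirna_counts.shape[0])
        stats["features_retained"] = len(retained)
        stats["isomir_fraction_mean"] = float(frac.mean())

        stage("cluster")
        logm = cluster.log2_transform(percents, config.pseudocount)
        tree = cluster.hierarchical_cluster(logm, cluster.ClusterConfig(pseudocount=config.pseudocount))
        (out / "samples.nwk").write_text(tree.to_newick() + "\n")
        coherence = cluster.replicate_coherence(tree, sheet)
        pd.DataFrame(
            sorted(coherence.items()), columns=["group", "coherent"]
        ).to_csv(out / "replicate_coherence.tsv", sep="\t", index=False, lineterminator="\n")
        files += [out / "samples.nwk", out / "replicate_coherence.tsv"]
        stats["coherent_groups"] = int(sum(coherence.values()))
        stats["n_groups"] = len(coherence)

        stage("snorna")
        if sno_ann:
            class_of = {a.id: a.box_class for a in sno_ann}
            if config.simulate_inputs:
                sno_ab = simulate.simulate_sno_abundances(config.sim, ref)
                rng = np.random.default_rng(config.seed + 4)
                wta_counts = pd.DataFrame(
                    {
                        s: rng.multinomial(
                            config.wta_reads_per_sample,
                            sno_ab[sheet.set_index("sample_id").loc[s, "group_id"]].to_numpy(),
                        )
                        for s in sheet["sample_id"]
                    },
                    index=sno_ab.index,
                )
            else:
                wta_counts = None
            small_counts = pd.DataFrame(
                {
                    s: snorna.attribute_fragments(unassigned_reads[s], sno_seqs)
                    for s in sheet["sample_id"]
                }
            ).fillna(0).astype(int)
            report_rows = []
            sets: dict[str, set] = {}
            for lib, counts in (("WTA", wta_counts), ("SMALL", small_counts)):
                if counts is None or counts.empty:
                    continue
                counts = counts[counts.sum(axis=1) > 0]
                write_counts_tsv(counts, out / f"sno_counts_{lib}.tsv")
                files.append(out / f"sno_counts_{lib}.tsv")
                pct = quantify.percent_of_total(counts)
                gm = quantify.group_mean(pct, sheet)
                top = snorna.top20_union(gm, config.sno_top_n)
                sets[lib] = top
                summary = snorna.sno_class_summary(top, class_of)
                for cls, cnt in summary.items():
                    report_rows.append({"library": lib, "box_class": cls, "count": int(cnt)})
            if len(sets) == 2:
                inter, jac = snorna.library_overlap(sets["WTA"], sets["SMALL"])
                report_rows.append({"library": "overlap", "box_class": "intersection", "count": inter})
                stats["sno_overlap_jaccard"] = jac
            pd.DataFrame(report_rows).to_csv(
                out / "sno_class_report.tsv", sep="\t", index=False, lineterminator="\n"
            )
            files.append(out / "sno_class_report.tsv")

        stage("biophys")
        if config.simulate_inputs:
            spec_df = simulate.simulate_spectrum(seed=config.seed)
            hist_df = simulate.simulate_size_histogram(seed=config.seed)
            spec_df.to_csv(out / "spectrum.tsv", sep="\t", index=False,
                           lineterminator="\n", float_format="%.8g")
            hist_df.to_csv(out / "size_histogram.tsv", sep="\t", index=False,
                           lineterminator="\n", float_format="%.8g")
            files += [out / "spectrum.tsv", out / "size_histogram.tsv"]
        else:
            spec_df = biophysics.read_spectrum_tsv(config.spectrum) if config.spectrum else None
            hist_df = (
                biophysics.read_size_histogram_tsv(config.size_histogram)
                if config.size_histogram else None
            )
        bio_rows = []
        if spec_df is not None:
            ai = biophysics.aggregation_index(spec_df["wavelength_nm"], spec_df["absorbance"])
            bio_rows.append({"quantity": "aggregation_index", "value": f"{ai:.6g}"})
            stats["aggregation_index"] = ai
        if hist_df is not None:
            wmd = biophysics.weighted_mean_diameter(hist_df["diameter_nm"], hist_df["count"])
            bio_rows.append({"quantity": "weighted_mean_diameter_nm", "value": f"{wmd:.6g}"})
            stats["weighted_mean_diameter_nm"] = wmd
        if bio_rows:
            pd.DataFrame(bio_rows).to_csv(
                out / "biophysics.tsv", sep="\t", index=False, lineterminator="\n"
            )
            files.append(out / "biophysics.tsv")
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    manifest = {
        "stats": stats,
        "files": {f.name: _sha256(f) for f in sorted(set(files))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
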