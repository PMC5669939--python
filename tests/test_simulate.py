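import io

import numpy as np
import pandas as pd
import pytest

from evcargo.assign import parse_subs
from evcargo.isomir import IsomiRKey, classify
from evcargo.simulate import (
    SimConfig,
    sample_sheet_frame,
    simulate_abundances,
    simulate_reads,
    simulate_reference,
    simulate_size_histogram,
    simulate_spectrum,
    write_fastq,
)


def _fastq_bytes(reads):
    buf = io.StringIO()
    for rid, seq in reads:
        buf.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return buf.getvalue()


class TestReference:
    def test_determinism_same_seed(self, small_sim_config):
        a = simulate_reference(small_sim_config)
        b = simulate_reference(small_sim_config)
        assert [(h.id, h.sequence) for h in a.hairpins] == [
            (h.id, h.sequence) for h in b.hairpins
        ]
        assert [(m.id, m.sequence) for m in a.matures] == [
            (m.id, m.sequence) for m in b.matures
        ]

    def test_counts_and_embedding(self, small_sim_config):
        ref = simulate_reference(small_sim_config)
        assert len(ref.matures) == small_sim_config.n_mirnas
        assert len(ref.hairpins) == small_sim_config.n_mirnas
        hp = {h.id: h.sequence for h in ref.hairpins}
        for m in ref.matures:
            assert hp[m.hairpin_id][m.start : m.end] == m.sequence
            assert 20 <= len(m.sequence) <= 23

    def test_sno_lengths_in_range(self, small_sim_config):
        ref = simulate_reference(small_sim_config)
        lo, hi = small_sim_config.sno_length_range
        for s in ref.sno_annotation:
            assert lo <= s.length <= hi
            assert len(s.sequence) == s.length


class TestAbundances:
    def test_columns_sum_to_one(self, small_sim_config):
        ref = simulate_reference(small_sim_config)
        ab = simulate_abundances(small_sim_config, ref.matures)
        assert np.allclose(ab.sum(axis=0), 1.0, atol=1e-12)

    def test_group_specific_absent_elsewhere(self, small_sim_config):
        cfg = small_sim_config
        ref = simulate_reference(cfg)
        ab = simulate_abundances(cfg, ref.matures)
        for g in range(cfg.n_groups):
            rows = slice(
                cfg.n_shared_core + g * cfg.n_group_specific,
                cfg.n_shared_core + (g + 1) * cfg.n_group_specific,
            )
            specific = ab.iloc[rows]
            own = cfg.group_ids[g]
            for other in cfg.group_ids:
                if other != own:
                    assert (specific[other] < 1e-4).all()
            assert (specific[own] > 0).all()

    def test_shared_core_in_top_ranks_everywhere(self, small_sim_config):
        cfg = small_sim_config
        ref = simulate_reference(cfg)
        ab = simulate_abundances(cfg, ref.matures)
        core = set(ab.index[: cfg.n_shared_core])
        k = cfg.n_shared_core + cfg.n_group_specific
        for g in cfg.group_ids:
            top = set(ab[g].nlargest(k).index)
            assert core <= top


class TestReads:
    def test_degenerate_parameters_all_canonical(self, small_sim_config):
        cfg = SimConfig(
            seed=3, n_mirnas=30, n_shared_core=10, n_group_specific=2,
            reads_per_sample=500, sub_rate=0.0, p_5p_shift=0.0,
            dist_3p_offset={0: 1.0}, tail_rate=0.0, sno_fragment_fraction=0.0,
        )
        ref = simulate_reference(cfg)
        ab = simulate_abundances(cfg, ref.matures)
        _, truth = simulate_reads(cfg, ref, ab)
        assert (truth["true_class"] == "CANONICAL").all()

    def test_same_seed_identical_fastq_bytes(self, small_sim_config):
        ref = simulate_reference(small_sim_config)
        ab = simulate_abundances(small_sim_config, ref.matures)
        r1, _ = simulate_reads(small_sim_config, ref, ab)
        r2, _ = simulate_reads(small_sim_config, ref, ab)
        s = small_sim_config.sample_ids[0]
        assert _fastq_bytes(r1[s]) == _fastq_bytes(r2[s])

    def test_three_prime_variant_rate_within_binomial_ci(self):
        cfg = SimConfig(
            seed=5, n_mirnas=20, n_shared_core=8, n_group_specific=1,
            n_groups=2, n_replicates=1, reads_per_sample=10000,
            p_5p_shift=0.0, sub_rate=0.0, tail_rate=0.0,
            dist_3p_offset={-1: 0.5, 0: 0.5}, sno_fragment_fraction=0.0,
        )
        ref = simulate_reference(cfg)
        ab = simulate_abundances(cfg, ref.matures)
        _, truth = simulate_reads(cfg, ref, ab)
        sub = truth[truth["sample_id"] == "group1_rep1"]
        frac = (sub["offset3"] != 0).mean()
        n = len(sub)
        sd = np.sqrt(0.5 * 0.5 / n)
        assert abs(frac - 0.5) < 3 * sd

    def test_truth_classes_consistent_with_classifier(self, small_sim_config):
        ref = simulate_reference(small_sim_config)
        ab = simulate_abundances(small_sim_config, ref.matures)
        _, truth = simulate_reads(small_sim_config, ref, ab)
        mirna = truth[truth["true_class"] != "SNORNA_FRAGMENT"]
        for row in mirna.itertuples(index=False):
            key = IsomiRKey(
                mirna_id=row.source_id,
                offset5=int(row.offset5),
                offset3=int(row.offset3),
                substitutions=parse_subs(row.subs),
                tail="" if row.tail == "-" else row.tail,
            )
            assert classify(key).value == row.true_class

    def test_reads_never_shorter_than_16(self, small_sim_config):
        ref = simulate_reference(small_sim_config)
        ab = simulate_abundances(small_sim_config, ref.matures)
        reads, _ = simulate_reads(small_sim_config, ref, ab)
        assert min(len(s) for rs in reads.values() for _, s in rs) >= 16

    def test_empirical_fractions_match_abundances(self):
        cfg = SimConfig(
            seed=9, n_mirnas=10, n_shared_core=4, n_group_specific=1,
            n_groups=2, n_replicates=1, reads_per_sample=20000,
            sno_fragment_fraction=0.0,
        )
        ref = simulate_reference(cfg)
        ab = simulate_abundances(cfg, ref.matures)
        _, truth = simulate_reads(cfg, ref, ab)
        sub = truth[truth["sample_id"] == "group1_rep1"]
        obs = sub["source_id"].value_counts(normalize=True)
        for mid, p in ab["group1"].items():
            o = obs.get(mid, 0.0)
            sd = np.sqrt(max(p * (1 - p), 1e-12) / len(sub))
            assert abs(o - p) < 4 * sd + 1e-9

    def test_fastq_writer_format(self, tmp_path):
        write_fastq([("r1", "ACGT")], tmp_path / "x.fastq")
        assert (tmp_path / "x.fastq").read_text() == "@r1\nACGT\n+\nIIII\n"

    def test_sample_sheet_matches_samples(self, small_sim_config):
        sheet = sample_sheet_frame(small_sim_config)
        assert list(sheet["sample_id"]) == small_sim_config.sample_ids


class TestConfigValidation:
    def test_dist_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(dist_3p_offset={0: 0.5})

    def test_core_plus_specific_bounded(self):
        with pytest.raises(ValueError, match="exceed"):
            SimConfig(n_mirnas=10, n_shared_core=8, n_group_specific=2, n_groups=4)


class TestBiophysicsInputs:
    def test_spectrum_ratio_matches_requested(self):
        df = simulate_spectrum(seed=0, peak_over_shoulder=2.5)
        wl = df["wavelength_nm"].to_numpy()
        ab = df["absorbance"].to_numpy()
        a519 = ab[wl == 519.0][0]
        a650 = ab[wl == 650.0][0]
        assert a519 / a650 == pytest.approx(2.5, rel=1e-9)

    def test_size_histogram_reasonable(self):
        df = simulate_size_histogram(seed=0)
        assert (df["diameter_nm"] > 0).all()
        assert df["count"].sum() > 100
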