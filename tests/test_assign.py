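"""Assignment tests, anchored on an independent brute-force oracle.

The oracle enumerates every (miRNA, 5' offset, tail split) placement
directly from the definition and picks the lexicographically best
(score, mirna_id, offset5); it shares no code with the implementation.
"""

import itertools

import numpy as np
import pytest

from evcargo.assign import (
    AssignmentParams,
    assign_library,
    assign_read,
    build_index,
    key_from_row,
)
from evcargo.isomir import classify
from evcargo.reference_io import HairpinRecord, MatureRecord
from evcargo.simulate import (
    SimConfig,
    simulate_abundances,
    simulate_reads,
    simulate_reference,
)


def brute_force_assign(read, matures, hairpins, params):
    """Naive reference search over all placements; returns
    (mirna_id, offset5, offset3, subs, tail) or None."""
    hp_by_id = {h.id: h.sequence for h in hairpins}
    if len(read) < params.min_read_len:
        return None
    best = None
    for m in sorted(matures, key=lambda m: m.id):
        hp = hp_by_id[m.hairpin_id]
        for o5 in range(-params.max_5p_shift, params.max_5p_shift + 1):
            rs = m.start + o5
            if rs < 0:
                continue
            o3 = (rs + len(read)) - m.end
            if abs(o3) > params.max_3p_shift:
                continue
            for t in range(0, min(params.max_tail, max(o3, 0)) + 1):
                cut = len(read) - t
                if rs + cut > len(hp):
                    continue  # templated span runs off the hairpin
                subs = tuple(
                    (i + o5, hp[rs + i], read[i])
                    for i in range(cut)
                    if read[i] != hp[rs + i]
                )
                if len(subs) > params.max_subs:
                    continue
                score = (len(subs), t, abs(o5) + abs(o3))
                cand = (score, m.id, o5, o3, subs, read[cut:])
                if best is None or (cand[0], cand[1], cand[2]) < (best[0], best[1], best[2]):
                    best = cand
    if best is None:
        return None
    _, mid, o5, o3, subs, tail = best
    return mid, o5, o3, subs, tail


def _as_tuple(asn):
    if asn is None:
        return None
    return (asn.mirna_id, asn.offset5, asn.offset3, asn.substitutions, asn.tail)


class TestAssignReadExamples:
    def test_exact_canonical_read(self, toy_reference):
        matures, hairpins = toy_reference
        index = build_index(matures, hairpins)
        asn = assign_read(matures[0].sequence, index)
        assert _as_tuple(asn) == ("mirA", 0, 0, (), "")

    def test_three_prime_trim(self, toy_reference):
        matures, hairpins = toy_reference
        index = build_index(matures, hairpins)
        asn = assign_read(matures[0].sequence[:-2], index)
        assert _as_tuple(asn) == ("mirA", 0, -2, (), "")

    def test_non_templated_tail(self, toy_reference):
        matures, hairpins = toy_reference
        # hairpin continues "TT" after the mature; read appends "AA"
        assert hairpins[0].sequence[30:32] == "TT"
        index = build_index(matures, hairpins)
        asn = assign_read(matures[0].sequence + "AA", index)
        assert _as_tuple(asn) == ("mirA", 0, 2, (), "AA")

    def test_templated_extension_is_not_tail(self, toy_reference):
        matures, hairpins = toy_reference
        index = build_index(matures, hairpins)
        asn = assign_read(matures[0].sequence + "TT", index)
        assert _as_tuple(asn) == ("mirA", 0, 2, (), "")

    def test_identical_matures_tie_to_ascending_id(self, toy_reference):
        matures, hairpins = toy_reference
        m = matures[0]
        twin_hp = HairpinRecord(id="hp2", sequence=hairpins[0].sequence)
        twin = MatureRecord(id="mirB", sequence=m.sequence, hairpin_id="hp2",
                            start=m.start, end=m.end)
        index = build_index([twin, m], [hairpins[0], twin_hp])
        asn = assign_read(m.sequence, index)
        assert asn.mirna_id == "mirA"

    def test_substitution_recorded_at_canonical_position(self, toy_reference):
        matures, hairpins = toy_reference
        read = list(matures[0].sequence)
        ref_base = read[10]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref_base]
        read[10] = alt
        asn = assign_read("".join(read), build_index(matures, hairpins))
        assert asn.substitutions == ((10, ref_base, alt),)
        assert (asn.offset5, asn.offset3, asn.tail) == (0, 0, "")

    def test_short_read_unassigned_not_error(self, toy_reference):
        matures, hairpins = toy_reference
        index = build_index(matures, hairpins)
        assert assign_read("ACGTACGTACGT", index) is None

    def test_invalid_characters_error(self, toy_reference):
        matures, hairpins = toy_reference
        index = build_index(matures, hairpins)
        with pytest.raises(ValueError, match="invalid"):
            assign_read("ACGTNACGTACGTACGTACGT", index)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_index([], [])


def _enumerate_perturbed_reads(matures, hairpins, rng, n_random=300):
    """Reads spanning the parameter space: every end-offset combination plus
    random substitution/tail variants."""
    hp_by_id = {h.id: h.sequence for h in hairpins}
    reads = []
    for m in matures:
        hp = hp_by_id[m.hairpin_id]
        for o5, o3 in itertools.product(range(-3, 4), range(-4, 5)):
            rs, re_ = m.start + o5, m.end + o3
            if rs < 0 or re_ > len(hp) or re_ - rs < 16:
                continue
            reads.append(hp[rs:re_])
            # tailed variant
            reads.append(hp[rs : re_ - 2] + "AA" if re_ - rs > 18 else hp[rs:re_])
    bases = "ACGT"
    for _ in range(n_random):
        m = matures[rng.integers(0, len(matures))]
        hp = hp_by_id[m.hairpin_id]
        seq = list(hp[m.start : m.end])
        for _ in range(rng.integers(0, 4)):  # up to 3 substitutions (some exceed max)
            i = rng.integers(0, len(seq))
            seq[i] = bases[rng.integers(0, 4)]
        reads.append("".join(seq))
    return reads


class TestOracleEquivalence:
    def test_matches_brute_force_on_toy_reference(self, toy_reference):
        matures, hairpins = toy_reference
        params = AssignmentParams()
        index = build_index(matures, hairpins)
        rng = np.random.default_rng(0)
        for read in _enumerate_perturbed_reads(matures, hairpins, rng):
            expected = brute_force_assign(read, matures, hairpins, params)
            got = _as_tuple(assign_read(read, index, params))
            assert got == expected, read

    def test_matches_brute_force_on_simulated_reference(self):
        cfg = SimConfig(seed=21, n_mirnas=8, n_shared_core=4, n_group_specific=1,
                        n_groups=2, n_replicates=1, reads_per_sample=100)
        ref = simulate_reference(cfg)
        params = AssignmentParams()
        index = build_index(ref.matures, ref.hairpins)
        rng = np.random.default_rng(1)
        reads = _enumerate_perturbed_reads(ref.matures, ref.hairpins, rng, n_random=500)
        for read in reads:
            expected = brute_force_assign(read, ref.matures, ref.hairpins, params)
            got = _as_tuple(assign_read(read, index, params))
            assert got == expected, read


class TestReconstruction:
    def test_offsets_subs_tail_reproduce_read(self):
        cfg = SimConfig(seed=13, n_mirnas=15, n_shared_core=5, n_group_specific=1,
                        n_groups=2, n_replicates=1, reads_per_sample=2000,
                        sno_fragment_fraction=0.0)
        ref = simulate_reference(cfg)
        ab = simulate_abundances(cfg, ref.matures)
        reads, _ = simulate_reads(cfg, ref, ab)
        hp_of = {m.id: (h, m) for m in ref.matures
                 for h in ref.hairpins if h.id == m.hairpin_id}
        index = build_index(ref.matures, ref.hairpins)
        sample = cfg.sample_ids[0]
        for read_id, seq in reads[sample][:500]:
            asn = assign_read(seq, index)
            assert asn is not None
            hp, m = hp_of[asn.mirna_id]
            rs = m.start + asn.offset5
            cut = m.end + asn.offset3 - len(asn.tail)
            rebuilt = list(hp.sequence[rs:cut])
            for pos, _, alt in asn.substitutions:
                rebuilt[pos - asn.offset5] = alt
            assert "".join(rebuilt) + asn.tail == seq


class TestAssignLibrary:
    def test_empty_input(self, toy_reference):
        matures, hairpins = toy_reference
        table, counters = assign_library([], build_index(matures, hairpins))
        assert table.empty
        assert counters == {"assigned": 0, "unassigned": 0}

    def test_conservation_and_per_read_equivalence(self, toy_reference):
        matures, hairpins = toy_reference
        index = build_index(matures, hairpins)
        params = AssignmentParams()
        m = matures[0].sequence
        reads = [("r1", m), ("r2", m[:-3]), ("r3", "A" * 22), ("r4", m + "AA"),
                 ("r5", "ACGTACGTACGT")]
        table, counters = assign_library(reads, index, params)
        assert counters["assigned"] + counters["unassigned"] == len(reads)
        assert len(table) == len(reads)
        for row in table.itertuples(index=False):
            seq = dict(reads)[row.read_id]
            single = assign_read(seq, index, params)
            if row.mirna_id == "-":
                assert single is None
            else:
                key = key_from_row(row)
                assert key.mirna_id == single.mirna_id
                assert key.offset5 == single.offset5
                assert key.offset3 == single.offset3
                assert key.substitutions == single.substitutions
                assert key.tail == single.tail

    def test_fastq_path_input(self, toy_reference, tmp_path):
        matures, hairpins = toy_reference
        p = tmp_path / "reads.fastq"
        seq = matures[0].sequence
        p.write_text(f"@r1\n{seq}\n+\n{'I' * len(seq)}\n")
        table, counters = assign_library(p, build_index(matures, hairpins))
        assert counters == {"assigned": 1, "unassigned": 0}
        assert table.iloc[0]["mirna_id"] == "mirA"

    def test_simulator_reads_recover_true_source(self, small_sim_config):
        ref = simulate_reference(small_sim_config)
        ab = simulate_abundances(small_sim_config, ref.matures)
        reads, truth = simulate_reads(small_sim_config, ref, ab)
        truth = truth.set_index("read_id")
        index = build_index(ref.matures, ref.hairpins)
        sample = small_sim_config.sample_ids[0]
        table, _ = assign_library(reads[sample], index)
        assigned = table[table["mirna_id"] != "-"]
        mirna_truth = truth.loc[assigned["read_id"]]
        hits = (assigned["mirna_id"].to_numpy() == mirna_truth["source_id"].to_numpy())
        assert hits.mean() >= 0.99

    def test_determinism_under_reference_reordering(self, small_sim_config):
        ref = simulate_reference(small_sim_config)
        ab = simulate_abundances(small_sim_config, ref.matures)
        reads, _ = simulate_reads(small_sim_config, ref, ab)
        sample = small_sim_config.sample_ids[0]
        subset = reads[sample][:200]
        fwd = build_index(ref.matures, ref.hairpins)
        rev = build_index(ref.matures[::-1], ref.hairpins[::-1])
        t1, _ = assign_library(subset, fwd)
        t2, _ = assign_library(subset, rev)
        assert t1.equals(t2)
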