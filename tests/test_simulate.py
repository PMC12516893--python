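"""Synthetic reference panel, EMS spiking, and pooled read simulation."""

import numpy as np
import pytest

from tillseq import seqcodes as sc
from tillseq.pooling import build_scheme
from tillseq.simulate import (MutationRecord, generate_references,
                              read_pool_fastq, read_truth_tsv,
                              simulate_pool_reads, spike_mutations,
                              write_pool_fastq, write_truth_tsv)


class TestGenerateReferences:
    def test_zero_divergence_gives_identical_parents(self):
        for a in generate_references(n_amplicons=3, divergence=0.0, seed=1):
            assert a.seq_a == a.seq_b

    def test_panel_size_and_length_range(self, panel17):
        assert len(panel17) == 17
        assert all(452 <= a.length <= 704 for a in panel17)
        assert len({a.gene_id for a in panel17}) == 13

    def test_full_divergence_changes_every_interior_base(self):
        for a in generate_references(n_amplicons=2, divergence=1.0, seed=2):
            pl = a.primer_len
            assert a.seq_a[:pl] == a.seq_b[:pl]
            assert a.seq_a[-pl:] == a.seq_b[-pl:]
            interior = slice(pl, a.length - pl)
            assert all(x != y for x, y in zip(a.seq_a[interior], a.seq_b[interior]))

    def test_primer_regions_conserved(self):
        for a in generate_references(n_amplicons=4, divergence=0.3, seed=3):
            assert a.divergent_sites.min() >= a.primer_len
            assert a.divergent_sites.max() < a.length - a.primer_len

    def test_exon_model_invariants(self, panel17):
        for a in panel17:
            prev = 0
            for s, e in a.exons:
                assert 0 <= s < e <= a.length
                assert s >= prev
                prev = e
            assert a.cds_offset in (0, 1, 2)
            assert a.strand in "+-"

    def test_inverted_length_range_rejected(self):
        with pytest.raises(ValueError):
            generate_references(length_range=(704, 452))

    def test_reproducible_under_seed(self):
        a = generate_references(n_amplicons=2, seed=9)
        b = generate_references(n_amplicons=2, seed=9)
        assert [x.seq_a for x in a] == [x.seq_a for x in b]
        assert [x.exons for x in a] == [x.exons for x in b]


class TestSpikeMutations:
    def test_forced_zero_count_gives_empty_truth(self, scheme8, panel17):
        assert spike_mutations(scheme8, panel17, seed=0, n_mutations=0) == []

    def test_records_are_ems_canonical_by_construction(self, scheme8, panel17):
        truth = spike_mutations(scheme8, panel17, seed=5)
        assert truth
        for m in truth:
            assert (m.ref_base, m.alt_base) in {("G", "A"), ("C", "T")}
            amp = next(a for a in panel17 if a.amplicon_id == m.amplicon_id)
            assert 0 <= m.position < amp.length
            assert amp.seq_a[m.position] == m.ref_base
            assert 0 <= m.family_id < scheme8.n_families

    def test_non_ems_record_rejected(self):
        with pytest.raises(ValueError):
            MutationRecord(0, "amp00", 10, "A", "G", "het")

    def test_mean_count_matches_poisson_expectation(self, scheme8, panel17):
        # mean over many seeds within 3 standard errors of total_kb / freq
        total_kb = sum(a.length for a in panel17) * scheme8.n_families / 1000
        expected = total_kb / 320.0
        counts = [
            len(spike_mutations(scheme8, panel17, freq_kb_per_mutation=320.0, seed=s))
            for s in range(60)
        ]
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_truth_tsv_round_trip(self, tmp_path, scheme8, panel17):
        truth = spike_mutations(scheme8, panel17, seed=7)
        path = tmp_path / "truth.tsv"
        write_truth_tsv(truth, path)
        assert read_truth_tsv(path) == truth


class TestSimulatePoolReads:
    def test_error_free_reads_match_a_parental_sequence(self):
        scheme = build_scheme(8, 2)
        amps = generate_references(n_amplicons=1, length_range=(452, 452),
                                   divergence=0.01, seed=4)
        rs = simulate_pool_reads(scheme, amps, [], coverage_per_family=5,
                                 error_rate=0.0, seed=4)
        amp = amps[0]
        seq_a, seq_b = amp.seq_a, amp.seq_b
        for pool, readset in rs.items():
            for i in range(readset.n_reads):
                read = sc.decode(readset.bases[i, : readset.lengths[i]])
                assert read in seq_a or read in seq_b

    def test_per_position_pool_depth_near_coverage_times_pool_size(self, scheme8):
        amps = generate_references(n_amplicons=1, length_range=(500, 500), seed=6)
        rs = simulate_pool_reads(scheme8, amps, [], coverage_per_family=11.3,
                                 read_length=150, error_rate=0.0, seed=6)
        expected = 11.3 * 64
        for pool in ("R0", "C3", "D7"):
            depth = rs[pool].lengths.sum() / amps[0].length
            assert abs(depth - expected) / expected < 0.03

    def test_het_pool_vaf_converges_to_half_per_family(self, scheme8):
        # one het carrier in 64-family pools: expected VAF 1/128
        amps = generate_references(n_amplicons=1, length_range=(500, 500),
                                   divergence=0.0, seed=8)
        amp = amps[0]
        pos = int(np.flatnonzero(amp.codes[0] == sc.G)[50])
        m = MutationRecord(175, amp.amplicon_id, pos, "G", "A", "het")
        rs = simulate_pool_reads(scheme8, amps, [m], coverage_per_family=60,
                                 error_rate=0.0, seed=8)
        mut_ref = amp.codes[0].copy()
        mut_ref[pos] = sc.A
        alt = depth = 0
        for pool in scheme8.pools_of(175):
            readset = rs[pool]
            for i in range(readset.n_reads):
                # locate each error-free read by exact match against the
                # reference or its mutated counterpart
                read = readset.bases[i, : readset.lengths[i]]
                off = _locate(read, amp.codes[0], pos)
                if off is None:
                    off = _locate(read, mut_ref, pos)
                if off is None:
                    continue
                depth += 1
                if read[pos - off] == sc.A:
                    alt += 1
        p = 1 / 128
        se = np.sqrt(p * (1 - p) / depth)
        assert depth > 1e4
        assert abs(alt / depth - p) < 3 * se

    def test_reproducible_bit_for_bit(self, small_config):
        from tillseq.pipeline import simulate_fixture

        a = simulate_fixture(small_config, seed=3)
        b = simulate_fixture(small_config, seed=3)
        assert a.truth == b.truth
        for pool in a.readsets:
            np.testing.assert_array_equal(a.readsets[pool].bases, b.readsets[pool].bases)
            np.testing.assert_array_equal(a.readsets[pool].lengths, b.readsets[pool].lengths)

    def test_long_reads_truncated_with_warning(self):
        scheme = build_scheme(1, 1)
        amps = generate_references(n_amplicons=1, length_range=(100, 100), seed=1,
                                   primer_len=10)
        with pytest.warns(UserWarning, match="truncated"):
            rs = simulate_pool_reads(scheme, amps, [], coverage_per_family=5,
                                     read_length=150, error_rate=0.0, seed=1)
        assert max(r.lengths.max() for r in rs.values()) <= 100

    def test_fastq_round_trip(self, tmp_path):
        scheme = build_scheme(4, 2)
        amps = generate_references(n_amplicons=1, seed=2)
        rs = simulate_pool_reads(scheme, amps, [], coverage_per_family=3, seed=2)
        path = tmp_path / "R0.fastq"
        write_pool_fastq("R0", rs["R0"], amps, path, error_rate=0.002)
        back = read_pool_fastq(path)
        assert back.n_reads == rs["R0"].n_reads
        np.testing.assert_array_equal(back.lengths, rs["R0"].lengths)
        for i in range(back.n_reads):
            n = back.lengths[i]
            np.testing.assert_array_equal(back.bases[i, :n], rs["R0"].bases[i, :n])


def _locate(read, ref_codes, pos):
    """Offset of an error-free read on the reference if it covers pos."""
    ref = ref_codes.tobytes()
    probe = read.tobytes()
    off = ref.find(probe)
    if off == -1:
        return None
    if off <= pos < off + len(probe):
        return off
    # same read may occur elsewhere; scan remaining matches
    while True:
        off = ref.find(probe, off + 1)
        if off == -1:
            return None
        if off <= pos < off + len(probe):
            return off
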