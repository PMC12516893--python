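"""Pooled binomial testing, EMS/divergence filters, and candidate calling."""

import math

import numpy as np
import pytest

from tillseq import seqcodes as sc
from tillseq.detection import (CallParams, calibrate_threshold, call_mutations,
                               ems_canonical, export_vaf_matrix,
                               mask_divergent_sites)
from tillseq.detection import test_position as binom_test
from tillseq.pipeline import map_pools, simulate_fixture
from tillseq.pooling import build_scheme
from tillseq.simulate import MutationRecord, generate_references, simulate_pool_reads


def _binom_sf_oracle(k, n, p):
    """Upper-tail P(X >= k) by direct log-space summation of the pmf."""
    total = 0.0
    for x in range(k, n + 1):
        lg = (math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
              + x * math.log(p) + (n - x) * math.log1p(-p))
        total += math.exp(lg)
    return min(total, 1.0)


class TestTestPosition:
    def test_zero_alt_is_p_one_and_fails(self):
        p, passed = binom_test(0, 100, 0.002)
        assert p == 1.0 and not passed

    def test_all_alt_closed_form(self):
        p, passed = binom_test(10, 10, 0.001, alpha=0.05, n_tests=1)
        assert p == pytest.approx((0.001 / 3) ** 10, rel=1e-9)
        assert passed

    def test_zero_depth_untestable(self):
        p, passed = binom_test(0, 0, 0.002)
        assert math.isnan(p) and not passed

    def test_invalid_error_rate(self):
        with pytest.raises(ValueError):
            binom_test(1, 10, 0.0)

    @pytest.mark.parametrize(
        "alt,depth,err",
        [(6, 720, 0.002), (3, 50, 0.01), (1, 1000, 0.0005), (12, 980, 0.003),
         (2, 7, 0.1), (5, 723, 0.002)],
    )
    def test_tail_matches_brute_force_summation(self, alt, depth, err):
        p, _ = binom_test(alt, depth, err)
        assert p == pytest.approx(_binom_sf_oracle(alt, depth, err / 3), rel=1e-9)

    def test_bonferroni_pass_rule(self):
        p, passed = binom_test(6, 720, 0.002, alpha=0.05, n_tests=1)
        assert passed
        _, passed = binom_test(6, 720, 0.002, alpha=0.05, n_tests=10**6)
        assert not passed
        # min_alt floor applies regardless of significance
        _, passed = binom_test(1, 10, 0.0001, alpha=0.05, min_alt=2, n_tests=1)
        assert not passed


class TestEmsCanonical:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("G", "A", True), ("C", "T", True),
        ("A", "G", False), ("T", "C", False),
        ("G", "T", False), ("C", "A", False), ("A", "T", False),
    ])
    def test_spectrum(self, ref, alt, expected):
        assert ems_canonical(ref, alt) is expected

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            ems_canonical("N", "A")


class TestDivergenceMask:
    def test_zero_divergence_empty_mask(self):
        amps = generate_references(n_amplicons=2, divergence=0.0, seed=1)
        masks = mask_divergent_sites(amps)
        assert all(m.size == 0 for m in masks.values())

    def test_single_engineered_site(self):
        amp = generate_references(n_amplicons=1, divergence=0.0, seed=2)[0]
        pos = amp.length // 2
        b = list(amp.seq_b)
        b[pos] = "A" if amp.seq_a[pos] != "A" else "C"
        amp.seq_b = "".join(b)
        amp.__dict__.pop("codes", None)
        amp.__dict__.pop("divergent_sites", None)
        masks = mask_divergent_sites([amp])
        assert masks[amp.amplicon_id].tolist() == [pos]


def test_calibrated_threshold_matches_monte_carlo_null():
    """The exact convolution tail equals a simulated error-only null."""
    rng = np.random.default_rng(99)
    d, err, dim, min_alt = 300, 0.006, 8, 2
    nsim = 40000
    counts = rng.binomial(d, err / 3, size=(nsim, 3, dim))
    mx = counts.max(axis=2)
    stat = np.where((mx >= min_alt).all(axis=1), mx.sum(axis=1), -1)
    # rebuild the exact tail used by calibrate_threshold
    from scipy import stats as st

    x = np.arange(201)
    cdf = st.binom.cdf(x, d, err / 3)
    cdf[-1] = 1.0
    cdfp = np.concatenate([[0.0], cdf[:-1]])
    m = cdf**dim - cdfp**dim
    ax = m.copy()
    ax[:min_alt] = 0
    s = np.convolve(np.convolve(ax, ax), ax)
    tail = np.cumsum(s[::-1])[::-1]
    for t in (6, 8, 10):
        emp = (stat >= t).mean()
        se = math.sqrt(max(emp * (1 - emp), 1e-9) / nsim)
        assert abs(emp - tail[t]) < 4 * se + 1e-6
    # and the calibration picks the smallest threshold meeting the budget
    t_star = calibrate_threshold(d, err, dim, n_tests=1000, min_alt=min_alt, alpha=0.05)
    assert 1000 * tail[t_star] <= 0.05
    assert t_star == 3 * min_alt or 1000 * tail[t_star - 1] > 0.05


class TestCallMutations:
    def _fixture(self, truth_spec, seed=12, divergence=0.005, error_rate=0.002):
        scheme = build_scheme(8, 2)
        amps = generate_references(n_amplicons=2, length_range=(452, 520),
                                   divergence=divergence, seed=seed)
        truth = []
        for fam, ai, site_rank in truth_spec:
            amp = amps[ai]
            conserved_gc = np.flatnonzero(
                ((amp.codes[0] == sc.G) | (amp.codes[0] == sc.C))
                & (amp.codes[0] == amp.codes[1])
            )
            pos = int(conserved_gc[site_rank])
            ref = amp.seq_a[pos]
            truth.append(MutationRecord(fam, amp.amplicon_id, pos, ref,
                                        "A" if ref == "G" else "T", "het"))
        rs = simulate_pool_reads(scheme, amps, truth, coverage_per_family=40,
                                 error_rate=error_rate, seed=seed)
        counts, _ = map_pools(rs, amps)
        return scheme, amps, truth, counts

    def test_single_spiked_mutation_recovered_uniquely(self):
        scheme, amps, truth, counts = self._fixture([(5, 0, 60)])
        cands = call_mutations(counts, scheme, amps, CallParams())
        assert len(cands) == 1
        c = cands[0]
        m = truth[0]
        assert (c.amplicon_id, c.position, c.alt_base) == (m.amplicon_id, m.position, m.alt_base)
        assert c.status == "unique" and c.families == (m.family_id,)
        assert set(scheme.pools_of(m.family_id)) <= {
            lab for ax in "RCD" for lab in c.supporting_pools[ax]
        }

    def test_two_mutations_in_disjoint_families(self):
        scheme, amps, truth, counts = self._fixture([(0, 0, 40), (7, 1, 80)])
        cands = call_mutations(counts, scheme, amps, CallParams())
        assert len(cands) == 2
        got = {(c.amplicon_id, c.position): c.families for c in cands}
        for m in truth:
            assert got[(m.amplicon_id, m.position)] == (m.family_id,)

    def test_no_mutations_no_errors_no_candidates(self):
        scheme, amps, truth, counts = self._fixture([], error_rate=0.0)
        assert call_mutations(counts, scheme, amps, CallParams()) == []

    def test_missing_pool_is_a_configuration_error(self):
        scheme, amps, truth, counts = self._fixture([])
        del counts["R0"]
        with pytest.raises(ValueError, match="R0"):
            call_mutations(counts, scheme, amps, CallParams())

    def test_candidates_are_ems_canonical_and_unmasked(self):
        scheme, amps, truth, counts = self._fixture([(3, 0, 20), (6, 1, 30)])
        masks = mask_divergent_sites(amps)
        for c in call_mutations(counts, scheme, amps, CallParams()):
            assert ems_canonical(c.ref_base, c.alt_base)
            assert c.position not in masks[c.amplicon_id]
            for call in c.pool_calls:
                assert call.ems_flag

    def test_parental_heterozygosity_is_masked_not_called(self):
        # a divergent site segregating in all families gives a strong VAF
        # signal in every pool; the mask must silence it
        scheme, amps, truth, counts = self._fixture([], divergence=0.01,
                                                    error_rate=0.0)
        div_total = sum(a.divergent_sites.size for a in amps)
        assert div_total > 0
        vaf = export_vaf_matrix(counts, scheme, amps)
        pools = scheme.pool_labels
        masked_rows = vaf[vaf["masked"]]
        assert (masked_rows[pools].max(axis=1) > 0.2).any()
        assert call_mutations(counts, scheme, amps, CallParams()) == []


class TestVafMatrix:
    def test_clean_input_all_zero(self):
        scheme = build_scheme(8, 2)
        amps = generate_references(n_amplicons=1, divergence=0.0, seed=3)
        rs = simulate_pool_reads(scheme, amps, [], coverage_per_family=10,
                                 error_rate=0.0, seed=3)
        counts, _ = map_pools(rs, amps)
        vaf = export_vaf_matrix(counts, scheme, amps)
        assert (vaf[scheme.pool_labels].to_numpy() == 0).all()
        assert not vaf["masked"].any()

    def test_het_mutation_elevates_exactly_three_pools(self):
        scheme = build_scheme(8, 2)
        amps = generate_references(n_amplicons=1, divergence=0.0, seed=4)
        amp = amps[0]
        pos = int(np.flatnonzero(amp.codes[0] == sc.G)[30])
        m = MutationRecord(5, amp.amplicon_id, pos, "G", "A", "het")
        rs = simulate_pool_reads(scheme, amps, [m], coverage_per_family=50,
                                 error_rate=0.0, seed=4)
        counts, _ = map_pools(rs, amps)
        vaf = export_vaf_matrix(counts, scheme, amps)
        row = vaf[vaf["pos"] == pos].iloc[0]
        hot = {p for p in scheme.pool_labels if row[p] > 0.05}
        assert hot == set(scheme.pools_of(5))
        # expected VAF 1/(2 * pool size) = 1/8
        for p in hot:
            assert row[p] == pytest.approx(1 / 8, abs=0.06)
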