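"""Divergence estimation: NG86 counting against a brute-force oracle,
the Jukes–Cantor correction, GY94 pairwise ML behaviour, locus-set
summaries, bootstrap CIs and per-year rates."""

import math

import numpy as np
import pytest

from conifer_div import syndata
from conifer_div.moldiv import (
    PairwiseCodonML,
    SaturationError,
    bootstrap_ci,
    gy94_pairwise_ml,
    jc_correct,
    ng86,
    summarize_loci,
    yearly_rate,
)
from conifer_div.ortho import CodonAlignment

from _oracles import oracle_ng86_counts


class TestJukesCantor:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_closed_form(self):
        assert jc_correct(0.6) == pytest.approx(-0.75 * math.log(0.2)) == pytest.approx(1.2071, abs=1e-4)

    @pytest.mark.parametrize("p", [0.75, 0.8, -0.1])
    def test_domain_errors(self, p):
        with pytest.raises(SaturationError):
            jc_correct(p)


class TestNG86:
    def test_identical_sequences(self):
        aln = CodonAlignment("a", "b", "ATGAAACTT", "ATGAAACTT")
        est = ng86(aln)
        assert est.Sd == est.Nd == 0
        assert est.dS == est.dN == 0
        assert est.omega is None

    def test_worked_example_single_synonymous_difference(self):
        # TTT GGG AAA vs TTC GGG AAA: one synonymous third-position change
        est = ng86(CodonAlignment("a", "b", "TTTGGGAAA", "TTCGGGAAA"))
        assert est.S == pytest.approx(5 / 3)
        assert est.N == pytest.approx(9 - 5 / 3)
        assert (est.Sd, est.Nd) == (1.0, 0.0)
        assert est.pS == pytest.approx(0.6)
        assert est.dS == pytest.approx(1.2071, abs=1e-4)
        assert est.dN == 0.0

    def test_sites_sum_to_three_per_codon(self, random_codon_alignment):
        for seed in range(5):
            aln = random_codon_alignment(25, seed)
            est = ng86(aln)
            assert est.S + est.N == pytest.approx(3 * est.n_codons_compared)

    def test_gapped_and_ambiguous_columns_skipped(self):
        row_a = "AAA" * 5 + "GGG" + "---" + "CTT"
        row_b = "AAA" * 5 + "GGA" + "CTT" + "CTN"
        est = ng86(CodonAlignment("a", "b", row_a, row_b))
        assert est.n_codons_compared == 6  # gap and ambiguity columns skipped
        assert (est.Sd, est.Nd) == (1.0, 0.0)

    def test_matches_brute_force_oracle(self, random_codon_alignment):
        # smaller pilot of the full oracle-equivalence run
        for seed in range(100):
            aln = random_codon_alignment(20, seed, p_diff=0.4)
            est = ng86(aln)
            codons_a = [c for c, _ in aln.codon_columns()]
            codons_b = [c for _, c in aln.codon_columns()]
            S, N, Sd, Nd = oracle_ng86_counts(codons_a, codons_b)
            assert est.S == pytest.approx(S, abs=1e-9)
            assert est.N == pytest.approx(N, abs=1e-9)
            assert est.Sd == pytest.approx(Sd, abs=1e-9)
            assert est.Nd == pytest.approx(Nd, abs=1e-9)

    def test_saturation_raises_with_proportions(self):
        # maximally divergent codons at every position
        row_a = "TTT" * 30
        row_b = "AGG" * 30
        with pytest.raises(SaturationError) as err:
            ng86(CodonAlignment("a", "b", row_a, row_b))
        assert err.value.pN is not None

    def test_single_position_differences_count_as_one(self, random_codon_alignment):
        aln = random_codon_alignment(50, seed=3, p_diff=0.0)
        # introduce single-position synonymous-or-not changes manually
        est = ng86(aln)
        assert est.Sd + est.Nd == 0


class TestGY94ML:
    def test_identical_sequences_fit_at_zero_divergence(self):
        seq = "ATGAAACTTGGGCCCACT" * 20
        res = gy94_pairwise_ml(CodonAlignment("a", "b", seq, seq), seed=0)
        assert res.t < 1e-4
        assert res.dS == pytest.approx(0.0, abs=1e-4)
        assert res.dN == pytest.approx(0.0, abs=1e-4)

    def test_parameter_recovery_moderate_size(self):
        truth = syndata.CodonPairTruth(omega=0.2, kappa=2.0, t=0.35, n_codons=5000, seed=99)
        seq_a, seq_b = syndata.simulate_codon_pair(truth)
        res = gy94_pairwise_ml(CodonAlignment("a", "b", seq_a, seq_b), seed=1)
        assert res.converged
        assert res.omega == pytest.approx(0.2, rel=0.15)
        assert res.kappa == pytest.approx(2.0, rel=0.15)
        assert res.t == pytest.approx(0.35, rel=0.15)
        assert res.dN / res.dS == pytest.approx(res.omega, rel=1e-6)

    def test_likelihood_dominates_truth_parameters(self):
        truth = syndata.CodonPairTruth(omega=0.2, kappa=2.0, t=0.35, n_codons=2000, seed=5)
        seq_a, seq_b = syndata.simulate_codon_pair(truth)
        model = PairwiseCodonML(CodonAlignment("a", "b", seq_a, seq_b))
        res = model.fit(seed=2)
        assert res.lnL >= model.loglike(0.35, 2.0, 0.2) - 1e-6

    def test_sites_sum_to_total(self):
        truth = syndata.CodonPairTruth(omega=0.3, kappa=2.0, t=0.2, n_codons=500, seed=8)
        seq_a, seq_b = syndata.simulate_codon_pair(truth)
        res = gy94_pairwise_ml(CodonAlignment("a", "b", seq_a, seq_b), seed=0)
        assert res.S + res.N == pytest.approx(3 * res.n_codons_compared)

    def test_small_alignment_warns(self):
        seq = "ATGAAACTTGGGCCCACT" * 2
        with pytest.warns(UserWarning, match="unstable"):
            PairwiseCodonML(CodonAlignment("a", "b", seq, seq))

    def test_summary_renders(self):
        truth = syndata.CodonPairTruth(omega=0.5, kappa=2.0, t=0.3, n_codons=300, seed=4)
        seq_a, seq_b = syndata.simulate_codon_pair(truth)
        res = gy94_pairwise_ml(CodonAlignment("a", "b", seq_a, seq_b), seed=0)
        text = res.summary()
        assert "dN/dS" in text and "kappa" in text and "log-likelihood" in text


class TestSummaries:
    def test_printed_means_reproduce(self):
        # unweighted means across the per-species values
        assert np.mean([0.172, 0.177, 0.176]) == pytest.approx(0.175, abs=5e-4)
        spruce_yew = summarize_loci(
            [_fake_estimate(ds) for ds in (0.577, 0.605, 0.611)]
        )
        assert round(spruce_yew.mean_dS, 3) == 0.598

    def test_undefined_omega_excluded_and_counted(self):
        ests = [_fake_estimate(0.1, omega=0.5), _fake_estimate(0.0, omega=None),
                _fake_estimate(0.2, omega=1.5)]
        s = summarize_loci(ests)
        assert s.n_omega_defined == 2 and s.n_omega_undefined == 1
        assert s.mean_omega == pytest.approx(1.0)
        assert s.n_omega_gt_1 == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_loci([])


class TestBootstrap:
    def test_constant_vector_gives_degenerate_interval(self):
        lo, hi = bootstrap_ci([0.2] * 10, seed=0)
        assert lo == hi == pytest.approx(0.2)

    def test_interval_contains_sample_mean(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(4.0, 0.05, size=50)
        for seed in range(5):
            lo, hi = bootstrap_ci(values, seed=seed)
            assert lo <= values.mean() <= hi

    def test_determinism(self):
        values = [0.1, 0.3, 0.2, 0.5, 0.15]
        assert bootstrap_ci(values, seed=7) == bootstrap_ci(values, seed=7)

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning):
            bootstrap_ci([0.1, 0.2, 0.3], n_boot=50, seed=0)


class TestYearlyRate:
    def test_pine_bound(self):
        assert yearly_rate(0.175, 1.6e8).rate == pytest.approx(5.47e-10, rel=1e-3)

    def test_yew_bound(self):
        assert yearly_rate(0.598, 2.4e8).rate == pytest.approx(1.246e-9, rel=1e-3)

    def test_zero_divergence(self):
        assert yearly_rate(0.0, 1e8).rate == 0.0

    def test_linearity_and_inverse_proportionality(self):
        base = yearly_rate(0.2, 1e8).rate
        assert yearly_rate(0.4, 1e8).rate == pytest.approx(2 * base)
        assert yearly_rate(0.2, 2e8).rate == pytest.approx(base / 2)

    def test_invalid_time(self):
        with pytest.raises(ValueError):
            yearly_rate(0.1, 0.0)


def _fake_estimate(ds, omega=0.3):
    from conifer_div.moldiv import DivergenceEstimate

    return DivergenceEstimate(
        locus_id="x", method="NG86", S=100.0, N=200.0, Sd=1.0, Nd=1.0,
        pS=0.01, pN=0.005, dS=ds, dN=ds * (omega or 0.0), omega=omega,
        n_codons_compared=100,
    )


def test_single_position_differences_sum_to_nucleotide_diff_count():
    # when every differing codon differs at exactly one position,
    # Sd + Nd equals the number of differing nucleotide positions
    from conifer_div.moldiv import ng86_counts

    row_a = "AAAGGGCTTTGC"
    row_b = "AAGGGACTCTGT"  # four codons changed at one position each
    _, _, Sd, Nd, _ = ng86_counts(CodonAlignment("a", "b", row_a, row_b))
    n_nt_diff = sum(a != b for a, b in zip(row_a, row_b))
    assert Sd + Nd == pytest.approx(n_nt_diff)


def test_ml_omega_bias_shrinks_with_alignment_length():
    # consistency: the omega error under the generating model is smaller
    # at 20k codons than at 2k, averaged over a few replicates
    def mean_abs_error(n_codons):
        errs = []
        for rep in range(5):
            truth = syndata.CodonPairTruth(omega=0.2, kappa=2.0, t=0.35,
                                           n_codons=n_codons, seed=500 + rep)
            seq_a, seq_b = syndata.simulate_codon_pair(truth)
            res = gy94_pairwise_ml(CodonAlignment("a", "b", seq_a, seq_b), seed=rep)
            errs.append(abs(res.omega - 0.2))
        return np.mean(errs)

    assert mean_abs_error(20_000) < mean_abs_error(2_000)
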