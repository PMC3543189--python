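"""The synthetic-data generators: determinism, planted structure, and
agreement between realised data and the generating parameters."""

import numpy as np
import pytest
from scipy import stats

from conifer_div import syndata
from conifer_div._codons import STOP_CODONS, revcomp
from conifer_div.moldiv import ng86
from conifer_div.ortho import CodonAlignment


def codons_of(seq):
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


class TestCodonPairs:
    def test_determinism(self):
        truth = syndata.CodonPairTruth(omega=0.2, kappa=2.0, t=0.35, n_codons=200, seed=12)
        assert syndata.simulate_codon_pair(truth) == syndata.simulate_codon_pair(truth)

    def test_zero_branch_length_gives_identical_sequences(self):
        truth = syndata.CodonPairTruth(omega=1.0, kappa=3.0, t=0.0, n_codons=100, seed=1)
        seq_a, seq_b = syndata.simulate_codon_pair(truth)
        assert seq_a == seq_b

    def test_no_internal_stops(self):
        truth = syndata.CodonPairTruth(omega=0.5, kappa=2.0, t=1.0, n_codons=500, seed=3)
        for seq in syndata.simulate_codon_pair(truth):
            assert len(seq) == 1500
            assert not any(c in STOP_CODONS for c in codons_of(seq))

    def test_omega_zero_forbids_amino_acid_change(self):
        from conifer_div.orf import translate

        truth = syndata.CodonPairTruth(omega=0.0, kappa=2.0, t=0.5, n_codons=10_000, seed=7)
        seq_a, seq_b = syndata.simulate_codon_pair(truth)
        assert seq_a != seq_b
        assert translate(seq_a) == translate(seq_b)

    def test_ng86_ds_tracks_generator_expectation(self):
        truth = syndata.CodonPairTruth(omega=0.2, kappa=2.0, t=0.35, n_codons=20_000, seed=21)
        seq_a, seq_b = syndata.simulate_codon_pair(truth)
        est = ng86(CodonAlignment("a", "b", seq_a, seq_b))
        ds_expected, _ = syndata.expected_ng86_divergence(truth)
        assert est.dS == pytest.approx(ds_expected, rel=0.10)

    def test_difference_count_matches_law_of_large_numbers(self):
        # observed differing-codon fraction -> 1 - sum_i pi_i P_ii(t)
        from scipy.linalg import expm

        from conifer_div import gy94

        truth = syndata.CodonPairTruth(omega=0.3, kappa=2.0, t=0.4, n_codons=50_000, seed=2)
        seq_a, seq_b = syndata.simulate_codon_pair(truth)
        diff = np.mean([a != b for a, b in zip(codons_of(seq_a), codons_of(seq_b))])
        pi = gy94.f3x4_frequencies(truth.position_freqs)
        P = expm(gy94.rate_matrix(truth.kappa, truth.omega, pi) * truth.t)
        expected = 1.0 - float(pi @ np.diag(P))
        assert diff == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("bad", [
        dict(omega=-0.1, kappa=2.0, t=0.1, n_codons=10),
        dict(omega=0.2, kappa=0.0, t=0.1, n_codons=10),
        dict(omega=0.2, kappa=2.0, t=-1.0, n_codons=10),
        dict(omega=0.2, kappa=2.0, t=0.1, n_codons=0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            syndata.simulate_codon_pair(syndata.CodonPairTruth(seed=0, **bad))


class TestTranscripts:
    def test_determinism(self):
        a = syndata.simulate_transcripts(20, seed=5)
        b = syndata.simulate_transcripts(20, seed=5)
        assert a == b

    def test_category_1_has_planted_stop_start_stop(self):
        mix = [1.0, 0, 0, 0, 0, 0]
        recs, truths = syndata.simulate_transcripts(20, category_mix=mix, seed=1,
                                                    both_strands=False)
        for rec, tr in zip(recs, truths):
            assert tr.category == 1
            orf_region = rec.seq[tr.start_nt : tr.end_nt]
            assert orf_region.startswith("ATG")
            assert rec.seq[tr.start_nt - 3 : tr.start_nt] in STOP_CODONS
            assert rec.seq[tr.end_nt : tr.end_nt + 3] in STOP_CODONS
            assert not any(c in STOP_CODONS for c in codons_of(orf_region))

    def test_category_6_is_featureless_in_planted_frame(self):
        mix = [0, 0, 0, 0, 0, 1.0]
        recs, truths = syndata.simulate_transcripts(20, category_mix=mix, seed=2,
                                                    both_strands=False)
        for rec, tr in zip(recs, truths):
            frame_codons = codons_of(rec.seq[tr.start_nt : tr.end_nt])
            assert "ATG" not in frame_codons
            assert not any(c in STOP_CODONS for c in frame_codons)

    def test_minus_strand_truth_coordinates(self):
        recs, truths = syndata.simulate_transcripts(60, seed=9)
        minus = [(r, t) for r, t in zip(recs, truths) if t.frame < 0]
        assert minus  # both strands exercised
        for rec, tr in minus:
            coding = revcomp(rec.seq[tr.start_nt : tr.end_nt])
            if tr.category in (1, 2, 3, 5):
                assert coding.startswith("ATG")
            assert not any(c in STOP_CODONS for c in codons_of(coding))

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            syndata.simulate_transcripts(5, category_mix=[0.5, 0.5], seed=0)
        with pytest.raises(ValueError):
            syndata.simulate_transcripts(5, orf_aa_range=(0, 5), seed=0)


class TestVariants:
    def test_determinism(self):
        t = syndata.VariantTruth(n_sites=2000)
        assert syndata.simulate_variants(t, seed=3) == syndata.simulate_variants(t, seed=3)

    def test_no_hets_no_errors_yields_no_candidates(self):
        t = syndata.VariantTruth(n_sites=5000, het_fraction=0.0, error_rate=0.0)
        records, truth = syndata.simulate_variants(t, seed=1)
        assert records == [] and truth == []

    def test_true_tstv_matches_target_within_binomial_band(self):
        t = syndata.VariantTruth(n_sites=50_000, het_fraction=0.2, error_rate=0.0,
                                 tstv_target=1.3)
        _, site_truth = syndata.simulate_variants(t, seed=11)
        ts = sum(1 for s in site_truth if s.is_transition)
        n = len(site_truth)
        p_expected = 1.3 / 2.3
        ci = stats.binomtest(ts, n, p_expected).proportion_ci(0.95)
        assert ci.low <= p_expected <= ci.high or abs(ts / n - p_expected) < 0.01

    def test_ase_skew_shifts_minor_allele_frequency(self):
        def low_maf_fraction(skew, seed):
            t = syndata.VariantTruth(n_sites=20_000, het_fraction=0.3, error_rate=0.0,
                                     ase_skew=skew)
            records, site_truth = syndata.simulate_variants(t, seed=seed)
            truth_by_id = {s.site_id: s for s in site_truth}
            mafs = [min(r.alt_frac, 1 - r.alt_frac) for r in records
                    if truth_by_id[r.site_id].is_variant]
            return np.mean([m < 0.25 for m in mafs])

        assert low_maf_fraction(0.9, 5) > 4 * low_maf_fraction(0.5, 5)

    def test_quality_monotone_in_alt_support(self):
        t = syndata.VariantTruth(n_sites=5000)
        records, _ = syndata.simulate_variants(t, seed=2)
        by_support = sorted(records, key=lambda r: r.alt_total)
        quals = [r.quality for r in by_support]
        assert all(a <= b for a, b in zip(quals, quals[1:]))


class TestReads:
    def test_determinism(self):
        assert syndata.simulate_reads(50, seed=8) == syndata.simulate_reads(50, seed=8)

    def test_truth_flags_describe_content(self):
        from conifer_div.readqc import find_adapter, homopolymer_pass, quality_pass

        reads, truths = syndata.simulate_reads(300, seed=4)
        for read, tr in zip(reads, truths):
            assert tr.adapter_pos == find_adapter(read.bases, syndata.ILLUMINA_ADAPTER)
            assert tr.has_long_homopolymer == (not homopolymer_pass(read))
            assert tr.passes_quality == quality_pass(read)

    def test_all_artifact_classes_appear(self):
        _, truths = syndata.simulate_reads(500, seed=6)
        assert any(t.adapter_pos >= 0 for t in truths)
        assert any(t.has_long_homopolymer for t in truths)
        assert any(not t.passes_quality for t in truths)
        assert any(
            t.adapter_pos == -1 and not t.has_long_homopolymer and t.passes_quality
            for t in truths
        )

    def test_short_read_length_rejected(self):
        with pytest.raises(ValueError):
            syndata.simulate_reads(5, read_len=20)


class TestWriters:
    def test_fasta_and_truth_tsv(self, tmp_path):
        recs, truths = syndata.simulate_transcripts(5, seed=1)
        syndata.write_fasta(recs, tmp_path / "t.fasta")
        syndata.write_truth_tsv(truths, tmp_path / "t.tsv")
        from Bio import SeqIO

        back = {r.id: str(r.seq) for r in SeqIO.parse(str(tmp_path / "t.fasta"), "fasta")}
        assert back == {r.id: r.seq for r in recs}
        lines = (tmp_path / "t.tsv").read_text().splitlines()
        assert lines[0].split("\t")[0] == "transcript_id"
        assert len(lines) == 6
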