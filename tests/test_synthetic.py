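import numpy as np
import pandas as pd
import pytest

from utrterm import synthetic
from utrterm.pas_motif import find_pas
from utrterm.peaklib import reproducible_peaks
from utrterm.riboprofile import DEFAULT_OFFSETS, assign_a_sites


class TestGenerateTranscriptome:
    def test_deterministic_given_seed_and_config(self):
        a1, t1 = synthetic.generate_transcriptome(n_genes=50, seed=11)
        a2, t2 = synthetic.generate_transcriptome(n_genes=50, seed=11)
        assert [a.sequence for a in a1] == [a.sequence for a in a2]
        assert t1.transcripts.equals(t2.transcripts)

    def test_all_polyadenylated_when_fraction_one(self):
        _, truth = synthetic.generate_transcriptome(
            n_genes=60, seed=1, frac_polyadenylated=1.0
        )
        assert (truth.transcripts["pas_local"] >= 0).all()

    def test_no_planting_when_fraction_zero(self):
        anns, truth = synthetic.generate_transcriptome(
            n_genes=60, seed=1, frac_polyadenylated=0.0
        )
        assert (truth.transcripts["pas_local"] == -1).all()
        # chance hexamer hits in the terminal window are rare (<~1%/UTR)
        chance = sum(
            1
            for a in anns
            if any(p >= a.utr3_len - 46 for p in find_pas(a.utr3_sequence))
        )
        assert chance <= 6

    def test_planted_pas_present_in_sequence(self):
        anns, truth = synthetic.generate_transcriptome(n_genes=40, seed=3)
        for a in anns:
            p = int(truth.transcripts.loc[a.transcript_id, "pas_local"])
            if p >= 0:
                assert a.utr3_sequence[p : p + 6] == "AATAAA"
                # motif sits 10-40 nt upstream of the 3' terminus
                assert 10 <= a.utr3_len - (p + 6) <= 40

    def test_utr3_intervals_do_not_overlap(self):
        anns, _ = synthetic.generate_transcriptome(n_genes=80, seed=5)
        ivs = sorted((a.utr3_interval.start, a.utr3_interval.end) for a in anns)
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))

    def test_truth_roundtrip_json(self, tmp_path):
        _, truth = synthetic.generate_transcriptome(n_genes=10, seed=2)
        truth.extras["apa_present"] = np.ones(10, dtype=bool)
        truth.to_json(tmp_path / "truth.json")
        back = synthetic.SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back.seed == truth.seed
        assert back.transcripts["utr3_len"].tolist() == truth.transcripts["utr3_len"].tolist()


class TestSimulatePeaks:
    def make(self, n=300, seed=4, **kw):
        anns, truth = synthetic.generate_transcriptome(n_genes=n, seed=seed)
        apa = synthetic.simulate_peaks(anns, truth, "APA", seed=seed, **kw)
        return anns, truth, apa

    def test_noiseless_reproducible_set_equals_planted_peaks(self):
        anns, truth, apa = self.make(dropout_rate=0.0, jitter_sd=0.0)
        repro = reproducible_peaks(apa)
        assert len(repro) == int(np.sum(truth.extras["apa_present"]))
        planted = {
            (p.interval.start, p.interval.end) for p in apa.replicates[0]
        }
        assert {(iv.start, iv.end) for iv in repro} == planted

    def test_dropout_shrinks_reproducible_set(self):
        anns, truth = synthetic.generate_transcriptome(n_genes=2000, seed=9)
        apa = synthetic.simulate_peaks(
            anns, truth, "APA", seed=9, dropout_rate=0.5, jitter_sd=0.0
        )
        n_present = int(np.sum(truth.extras["apa_present"]))
        n_repro = len(reproducible_peaks(apa))
        # survival of all three replicates: 0.5^3 = 1/8, binomial tolerance
        expected = n_present / 8
        sd = np.sqrt(n_present * (1 / 8) * (7 / 8))
        assert abs(n_repro - expected) < 4 * sd

    def test_clip_requires_apa_first(self):
        anns, truth = synthetic.generate_transcriptome(n_genes=20, seed=1)
        with pytest.raises(ValueError, match="APA"):
            synthetic.simulate_peaks(anns, truth, "CLIP", seed=1)

    def test_invalid_dropout_rejected(self):
        anns, truth = synthetic.generate_transcriptome(n_genes=20, seed=1)
        with pytest.raises(ValueError, match="dropout"):
            synthetic.simulate_peaks(anns, truth, "APA", dropout_rate=1.0)

    def test_marginal_clip_rate_held_at_base_rate(self):
        anns, truth = synthetic.generate_transcriptome(n_genes=5000, seed=6)
        synthetic.simulate_peaks(anns, truth, "APA", seed=6, apa_rate=0.3)
        synthetic.simulate_peaks(
            anns, truth, "CLIP", seed=7, target_odds_ratio=6.0, clip_base_rate=0.1
        )
        marginal = truth.extras["clip_present"].mean()
        assert marginal == pytest.approx(0.1, abs=3 * np.sqrt(0.1 * 0.9 / 5000))


class TestConditionalRates:
    def test_odds_ratio_and_marginal_satisfied(self):
        p0, p1 = synthetic.solve_conditional_rates(0.05, 0.1, 8.0)
        odds = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds == pytest.approx(8.0, rel=1e-9)
        assert 0.1 * p1 + 0.9 * p0 == pytest.approx(0.05, abs=1e-12)

    def test_unit_odds_ratio_collapses_to_marginal(self):
        assert synthetic.solve_conditional_rates(0.07, 0.4, 1.0) == (0.07, 0.07)

    def test_invalid_or_rejected(self):
        with pytest.raises(ValueError):
            synthetic.solve_conditional_rates(0.05, 0.1, 0.0)


class TestSimulateFootprints:
    def setup_method(self):
        self.anns, _ = synthetic.generate_transcriptome(
            n_genes=50, seed=8, frac_long_cds=1.0
        )
        self.ab, self.te = synthetic.simulate_expression(50, seed=9)

    def test_asite_inversion_is_exact(self):
        fp = synthetic.simulate_footprints(
            self.anns, self.ab, self.te, n_reads=20_000, seed=10
        )
        utr5 = fp["transcript_id"].map(
            {a.transcript_id: a.utr5_len for a in self.anns}
        ).to_numpy()
        codon = assign_a_sites(fp["five_prime_pos"].to_numpy(), utr5, DEFAULT_OFFSETS)
        assert (codon == fp["true_codon"].to_numpy()).all()

    def test_monosome_length_support(self):
        fp = synthetic.simulate_footprints(
            self.anns, self.ab, self.te, n_reads=5000, seed=2
        )
        assert fp["length"].between(32, 40).all()

    def test_disome_length_mixture(self):
        fp = synthetic.simulate_footprints(
            self.anns, self.ab, self.te, n_reads=20_000, seed=2, library="disome_lib"
        )
        frac_true = (fp["length"] >= 60).mean()
        assert frac_true == pytest.approx(0.6, abs=0.02)
        assert fp["length"].between(45, 75).all()

    def test_degenerate_te_gives_flat_te_estimate(self):
        # read mass proportional to abundance alone when TE == 1 everywhere
        te1 = np.ones(50)
        fp = synthetic.simulate_footprints(
            self.anns, self.ab, te1, n_reads=100_000, seed=3
        )
        counts = fp.groupby("transcript_id").size()
        share = counts / counts.sum()
        expected = pd.Series(
            self.ab / self.ab.sum(), index=[a.transcript_id for a in self.anns]
        )
        common = share.index
        ratio = share / expected[common]
        assert np.corrcoef(share, expected[common])[0, 1] > 0.99
        assert ratio.median() == pytest.approx(1.0, abs=0.1)


class TestCountMatrix:
    def test_nb_counts_match_planted_means(self, rng):
        weights = rng.lognormal(0, 1, 400)
        mat = synthetic.simulate_count_matrix(
            weights, [f"g{i}" for i in range(400)], ["s1", "s2"], 1e6,
            dispersion=0.05, seed=1,
        )
        mean = 1e6 * weights / weights.sum()
        # realized counts track planted means (rank scale is robust to the
        # heavy-tailed mean distribution)
        from scipy import stats

        assert stats.spearmanr(mat["s1"], mean).statistic > 0.95
        assert mat.to_numpy().min() >= 0
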