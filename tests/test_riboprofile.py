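import numpy as np
import pandas as pd
import pytest

from conftest import make_annotation
from utrterm.riboprofile import (
    DEFAULT_OFFSETS,
    FootprintAlignment,
    assign_a_site,
    bin_profile_lengths,
    cds_occupancy_counts,
    classify_footprint,
    metagene_profile,
)


class TestClassifyFootprint:
    def test_exhaustive_boundary_sweep(self):
        for L in range(1, 101):
            mono = classify_footprint(L, "monosome_lib")
            di = classify_footprint(L, "disome_lib")
            assert mono == ("monosome" if 32 <= L <= 40 else "unassigned")
            assert di == ("true_disome" if L >= 60 else "sub_disome")

    def test_unknown_library_rejected(self):
        with pytest.raises(ValueError):
            classify_footprint(35, "total_rna")


class TestAssignASite:
    def fp(self, pos):
        return FootprintAlignment("t1", pos, 34, "s")

    def test_frame0_arithmetic(self):
        ann = make_annotation(utr5=50, cds=300)
        assert assign_a_site(self.fp(50), ann) == 5  # a_site_nt 65 -> codon 5

    def test_frame2_arithmetic(self):
        ann = make_annotation(utr5=50, cds=300)
        assert assign_a_site(self.fp(52), ann) == 6  # offset 17 -> nt 69 -> codon 6

    def test_upstream_read_gives_negative_codon(self):
        ann = make_annotation(utr5=50, cds=300)
        assert assign_a_site(self.fp(20), ann) == -5  # nt 35, floor((35-50)/3)

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValueError):
            assign_a_site(self.fp(10), None)


def uniform_footprints(ann, length=34, sample="s1"):
    """One frame-0 read starting at every codon's first base minus offset 15."""
    rows = []
    for c in range(ann.n_codons):
        rows.append((ann.transcript_id, ann.utr5_len + 3 * c - 15, length, sample))
    return pd.DataFrame(rows, columns=["transcript_id", "five_prime_pos", "length", "sample"])


class TestOccupancyWindow:
    def test_uniform_coverage_counts_76_of_100_codons(self):
        ann = make_annotation(utr5=50, cds=300)  # 100 codons
        counts = cds_occupancy_counts(uniform_footprints(ann), [ann])
        assert counts.loc["g1", "s1"] == 76  # codons 15..90 inclusive

    def test_window_boundaries(self):
        ann = make_annotation(utr5=50, cds=300)

        def one_read_at_codon(c):
            df = pd.DataFrame(
                [(ann.transcript_id, ann.utr5_len + 3 * c - 15, 34, "s1")],
                columns=["transcript_id", "five_prime_pos", "length", "sample"],
            )
            return int(cds_occupancy_counts(df, [ann]).loc["g1", "s1"])

        assert one_read_at_codon(14) == 1   # 1-based codon 15: first counted
        assert one_read_at_codon(13) == 0   # 1-based codon 14: excluded
        assert one_read_at_codon(89) == 1   # 1-based codon 90: last counted
        assert one_read_at_codon(90) == 0   # 1-based codon 91: excluded


class TestMetagene:
    def ann(self, tid="t1", codons=200):
        return make_annotation(tid=tid, utr5=60, cds=codons * 3, utr3=80,
                               utr3_start=1000)

    def test_single_gene_self_normalization(self):
        ann = self.ann()
        profile = metagene_profile(uniform_footprints(ann), [ann],
                                   position_range=(-30, 60))
        # one read per codon => scale 1 => value 1.0 at every covered position
        covered = profile.position_sums()
        expected_positions = {3 * c - 15 for c in range(ann.n_codons)}
        for pos, v in zip(profile.positions, covered):
            if int(pos) in expected_positions:
                assert v == pytest.approx(1.0)
            else:
                assert v == 0.0

    def test_depth_rescaling_makes_profiles_depth_invariant(self):
        a1 = self.ann("t1")
        a2 = make_annotation(tid="t2", utr5=60, cds=600, utr3=80, utr3_start=5000)
        fp1 = uniform_footprints(a1, sample="s1")
        fp10 = pd.concat([uniform_footprints(a2, sample="s1")] * 10, ignore_index=True)
        both = pd.concat([fp1, fp10], ignore_index=True)
        p_both = metagene_profile(both, [a1, a2], position_range=(-30, 60))
        p_one = metagene_profile(fp1, [a1], position_range=(-30, 60))
        assert np.allclose(p_both.matrix, p_one.matrix, atol=1e-9)

    def test_three_gene_instance_matches_hand_tally(self):
        anns = [self.ann(f"t{i}", codons=150 + 10 * i) for i in range(3)]
        rows = []
        # gene i gets (i+1) reads at codon 20, length 33+i
        for i, a in enumerate(anns):
            for _ in range(i + 1):
                rows.append((a.transcript_id, a.utr5_len + 60 - 15, 33 + i, "s"))
            # plus one read per codon elsewhere to pass the >=1/codon filter
            for c in range(a.n_codons):
                rows.append((a.transcript_id, a.utr5_len + 3 * c - 15, 33 + i, "s"))
        df = pd.DataFrame(rows, columns=["transcript_id", "five_prime_pos", "length", "sample"])
        profile = metagene_profile(df, anns, position_range=(40, 50))
        # at relative position 45 (codon 20): gene i contributes
        # (i+2)/scale_i with scale_i = (n_codons_i + i + 1)/n_codons_i
        expected = np.zeros(profile.positions.size)
        idx45 = list(profile.positions).index(45)
        for i, a in enumerate(anns):
            scale = (a.n_codons + i + 1) / a.n_codons
            expected[idx45] += (i + 2) / scale
        other = [list(profile.positions).index(p) for p in (42, 48)]
        got = profile.position_sums()
        assert got[idx45] == pytest.approx(expected[idx45] / 3)
        for j in other:
            assert got[j] == pytest.approx(
                sum(1 / ((a.n_codons + i + 1) / a.n_codons) for i, a in enumerate(anns)) / 3
            )

    def test_conservation_single_gene(self):
        # sum(value * scale) over in-range positions == raw read count there
        ann = self.ann()
        fp = uniform_footprints(ann)
        profile = metagene_profile(fp, [ann], position_range=(-30, 60))
        scale = len(fp) / ann.n_codons
        in_range = sum(1 for c in range(ann.n_codons) if -30 <= 3 * c - 15 <= 60)
        assert profile.position_sums().sum() * scale == pytest.approx(in_range)

    def test_structure_filters_and_attrition_error(self):
        short = make_annotation(tid="t1", utr5=10, cds=300, utr3=80, utr3_start=100)
        with pytest.raises(ValueError, match="filters"):
            metagene_profile(uniform_footprints(short), [short])


class TestBinProfileLengths:
    def profile(self):
        ann = make_annotation(tid="t1", utr5=60, cds=600, utr3=80, utr3_start=100)
        rows = []
        for L in (58, 59, 60):
            for c in range(ann.n_codons):
                rows.append((ann.transcript_id, ann.utr5_len + 3 * c - 15, L, "s"))
        df = pd.DataFrame(rows, columns=["transcript_id", "five_prime_pos", "length", "sample"])
        return metagene_profile(df, [ann], position_range=(-15, 0))

    def test_bin_sums_rows(self):
        p = self.profile()
        binned = bin_profile_lengths(p, [(58, 60)])
        idx = list(binned.positions).index(-15)
        assert binned.matrix[0, idx] == pytest.approx(p.matrix[:, idx].sum())

    def test_singleton_bins_are_identity(self):
        p = self.profile()
        binned = bin_profile_lengths(p, [(58, 58), (59, 59), (60, 60)])
        assert np.allclose(binned.matrix, p.matrix)

    def test_empty_bin_zero(self):
        p = self.profile()
        binned = bin_profile_lengths(p, [(30, 40)])
        assert binned.matrix.sum() == 0.0

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            bin_profile_lengths(self.profile(), [(58, 60), (60, 62)])
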