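import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from truncmap.motifs import MotifSet
from truncmap.rnamaps import (
    cluster_motif_heatmap,
    discover_pentamers,
    end_nucleotide_composition,
    endpeak_grouped_heatmap,
    gaussian_smooth,
    intron_end_fraction,
    junction_map,
    reachability_flags,
    ytract_map,
)

from conftest import make_cdna, random_cdnas, random_sequences


class TestGaussianSmoothing:
    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(0, 1e6), min_size=1, max_size=200),
        st.sampled_from([5.0, 10.0]),
    )
    def test_mass_preserved(self, values, window):
        arr = np.array(values)
        out = gaussian_smooth(arr, window)
        assert abs(out.sum() - arr.sum()) <= 1e-9 * max(1.0, arr.sum())

    def test_nonnegative(self):
        out = gaussian_smooth(np.array([0.0, 5.0, 0.0, 0.0]), 5.0)
        assert np.all(out >= 0)


class TestJunctionMap:
    def test_hand_computed_formula(self):
        # 1 junction, 1 mRNA of length 500, all 10 starts at offset -24:
        # value = (10/10) * 500 / 1 = 500 at -24, 0 elsewhere
        L = 500
        reads = [make_cdna(ref="tx", start=300 - 24, length=20, umi=f"U{i}") for i in range(10)]
        m = junction_map(reads, [("tx", 300)], {"tx": L}, smooth=5)
        assert m.value_at(-24) == pytest.approx(L)
        mask = m.offsets != -24
        assert np.all(m.raw[mask] == 0)

    def test_uniform_library_converges_to_one(self):
        rng = np.random.default_rng(0)
        L = 2000
        n = 20000
        reads = [
            make_cdna(ref="tx", start=int(rng.integers(0, L)), length=20, umi=f"U{i}")
            for i in range(n)
        ]
        junctions = [("tx", p) for p in (500, 1000, 1500)]
        m = junction_map(reads, junctions, {"tx": L}, window=(-30, 30))
        # expectation exactly 1 at each offset; 3 sigma tolerance
        per_offset_counts = n * len(junctions) / L
        sigma = 1 / math.sqrt(per_offset_counts)
        assert abs(m.raw.mean() - 1) < 3 * sigma / math.sqrt(m.raw.size)
        assert abs(m.raw - 1).max() < 5 * sigma

    def test_zero_cdnas_rejected(self):
        with pytest.raises(ValueError):
            junction_map([], [("tx", 100)], {"tx": 500})

    def test_smoothed_preserves_total(self):
        reads = [make_cdna(ref="tx", start=280, length=20, umi=f"U{i}") for i in range(7)]
        m = junction_map(reads, [("tx", 300)], {"tx": 500})
        assert m.smoothed.sum() == pytest.approx(m.raw.sum(), abs=1e-9)


class TestYtractMap:
    def test_constant_counts_identity(self):
        # one read starting at every position: per-position counts constant
        reads = [make_cdna(ref="tx", start=s, length=20, umi=f"U{s}") for s in range(0, 480)]
        m = ytract_map(reads, [("tx", 200, 240)], search_flank=100)
        sel = (m.offsets >= -100) & (m.offsets <= 100)
        np.testing.assert_allclose(m.raw[sel], 1.0, atol=1e-12)

    def test_per_site_scale_invariance(self):
        # site abundance (identical per-position shape, n-fold depth)
        # cancels out through MaxCount normalization, exactly
        rng = np.random.default_rng(4)
        shape = {d: int(rng.integers(1, 6)) for d in range(-30, 60)}

        def site_reads(site_start, depth_factor):
            out = []
            for d, n in shape.items():
                for j in range(n * depth_factor):
                    out.append(
                        make_cdna(ref="tx", start=site_start + d, length=20,
                                  umi=f"U{site_start}_{d}_{j}")
                    )
            return out

        tracts = [("tx", 200, 230), ("tx", 700, 730)]
        scaled = site_reads(200, 1) + site_reads(700, 5)
        uniform = site_reads(200, 1) + site_reads(700, 1)
        m1 = ytract_map(scaled, tracts, search_flank=60, norm_flank=(40, 55))
        m2 = ytract_map(uniform, tracts, search_flank=60, norm_flank=(40, 55))
        np.testing.assert_allclose(m1.raw, m2.raw, atol=1e-12)

    def test_maxcount_zero_sites_excluded(self):
        reads = [make_cdna(ref="tx", start=100, length=20, umi="A")]
        m = ytract_map(reads, [("tx", 80, 120), ("tx", 4000, 4040)])
        assert m.flags["n_excluded_maxcount0"] == 1
        assert m.n_anchors == 1

    def test_downstream_zero_flagged(self):
        reads = [make_cdna(ref="tx", start=205, length=20, umi="A")]
        m = ytract_map(reads, [("tx", 180, 200)])
        assert m.flags["downstream_zero"]


class TestGroupedHeatmap:
    def test_identical_end_peaks_single_row(self):
        reads = [make_cdna(ref="tx", start=100, length=20, umi=f"U{i}") for i in range(5)]
        peaks = [(("tx", 120), -5), (("tx", 300), -5)]
        hm = endpeak_grouped_heatmap(reads, peaks)
        assert len(hm.row_keys) == 1

    def test_global_max_is_one(self):
        rng = np.random.default_rng(0)
        reads = [
            make_cdna(ref="tx", start=int(rng.integers(80, 140)), length=20, umi=f"U{i}")
            for i in range(60)
        ]
        peaks = [(("tx", 120), -5), (("tx", 130), 3)]
        hm = endpeak_grouped_heatmap(reads, peaks)
        assert hm.matrix.max() == pytest.approx(1.0)


class TestReachability:
    def test_geometry_cases(self):
        peaks = [(("tx", 100), -30), (("tx", 200), 0), (("tx", 300), -10), (("tx", 400), -3)]
        flags = reachability_flags(peaks)
        assert flags[("tx", 100)] == "peak_upstream"
        assert flags[("tx", 200)] == "reachable"
        assert flags[("tx", 300)] == "unreachable"
        assert flags[("tx", 400)] == "reachable"  # -3 - (-20) = 17, exactly reachable

    def test_uniform_peak_fraction_analytic(self, rng):
        # peaks uniform on [-20, 25]: reachable iff offset >= -3 -> 29/46
        offsets = rng.integers(-20, 26, size=4000)
        peaks = [(("tx", i), int(o)) for i, o in enumerate(offsets)]
        flags = reachability_flags(peaks)
        frac = np.mean([f == "reachable" for f in flags.values()])
        p = 29 / 46
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / 4000)


class TestEndComposition:
    def test_fractions_sum_to_one(self, rng):
        sequences = random_sequences(rng, n=2, length=800)
        reads = random_cdnas(rng, sequences, 200)
        frame = end_nucleotide_composition(reads, sequences)
        np.testing.assert_allclose(frame.sum(axis=1), 1.0, atol=1e-12)

    def test_iid_sequence_quarter_each(self, rng):
        sequences = random_sequences(rng, n=3, length=3000)
        reads = random_cdnas(rng, sequences, 3000)
        frame = end_nucleotide_composition(reads, sequences)
        assert np.abs(frame.to_numpy() - 0.25).max() < 4 * np.sqrt(0.25 * 0.75 / 3000)

    def test_cut_after_a_simulation(self):
        from truncmap import simulate as sim
        from truncmap.cdna_io import collapse_umis

        cfg = sim.SimConfig(
            seed=6, n_transcripts=3, n_molecules=600,
            cleavage_model=sim.CleavageModel(kind="sequence", after_base="A"),
            site_model=[sim.SiteSpec(kind="ytract", length=25, count=2)],
        )
        seqs, ann = sim.simulate_transcriptome(cfg)
        reads, _ = sim.simulate_reads(seqs, ann, cfg)
        frame = end_nucleotide_composition(collapse_umis(reads), seqs)
        assert frame.loc[0, "A"] == pytest.approx(1.0)

    def test_edge_windows_skipped(self):
        reads = [make_cdna(ref="tx", start=0, length=17, umi="A")]
        stats = {}
        end_nucleotide_composition(reads, {"tx": "A" * 20}, stats=stats)
        assert stats["n_skipped"] == 1


class TestIntronEndFraction:
    INTRONS = {"tx": [(100, 1100)]}

    def test_all_at_last_base(self):
        reads = [make_cdna(ref="tx", start=1099 - 19, length=20, umi=f"U{i}") for i in range(5)]
        assert intron_end_fraction(reads, self.INTRONS) == 1.0

    def test_uniform_analytic_expectation(self, rng):
        n = 20000
        ends = rng.integers(100, 1100, size=n)
        reads = [
            make_cdna(ref="tx", start=int(e) - 19, length=20, umi=f"U{i}")
            for i, e in enumerate(ends)
        ]
        frac = intron_end_fraction(reads, self.INTRONS)
        p = 2 / 1000
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_no_intronic_reads_flagged(self):
        reads = [make_cdna(ref="tx", start=2000, length=20, umi="A")]
        assert math.isnan(intron_end_fraction(reads, self.INTRONS))

    def test_invariant_to_pcr_after_collapse(self):
        from truncmap.cdna_io import collapse_umis

        reads = [make_cdna(ref="tx", start=1080, length=20, umi="AA")] * 4
        reads += [make_cdna(ref="tx", start=500, length=20, umi="CC")]
        collapsed = collapse_umis(reads)
        assert intron_end_fraction(collapsed, self.INTRONS) == intron_end_fraction(
            reads[:1] + reads[-1:], self.INTRONS
        )


class TestPentamers:
    def test_planted_pentamer_top_z(self, rng):
        sequences = {}
        peaks = []
        for i in range(40):
            ref = f"tx{i}"
            seq = list(rng.choice(list("ACGT"), size=200))
            seq[100:105] = list("TCTTT")  # planted at every peak
            sequences[ref] = "".join(seq)
            peaks.append((ref, 102))
        df = discover_pentamers(peaks, sequences, n_shuffles=30, seed=1)
        finite = df[~df["sd_zero"]]
        assert finite.iloc[0]["kmer"] == "TCTTT"

    def test_null_no_extreme_z(self, rng):
        sequences = random_sequences(rng, n=5, length=500)
        peaks = [(r, int(rng.integers(50, 450))) for r in sequences for _ in range(8)]
        df = discover_pentamers(peaks, sequences, n_shuffles=30, seed=2)
        finite = df[~df["sd_zero"]]
        assert finite["z"].max() < 10

    def test_sd_zero_flagged_separately(self, rng):
        sequences = {"tx": "ACGT" * 100}
        df = discover_pentamers([("tx", 50)], sequences, n_shuffles=5, seed=0)
        assert "sd_zero" in df.columns
        assert not df[df["sd_zero"]]["passed"].any()


class TestClusterMotifHeatmap:
    def make_clusters(self, n, rng):
        from truncmap.clusters import CrosslinkCluster

        out = []
        for i in range(n):
            length = int(rng.integers(5, 40))
            start = 100 + i * 200
            out.append(
                CrosslinkCluster(
                    ref_id="tx", start=start, end=start + length, count=10,
                    peak=start, peak_height=5, fdr=0.01, spacing=3,
                )
            )
        return out

    def test_row_count(self, rng):
        clusters = self.make_clusters(650, rng)
        seq = {"tx": "G" * (100 + 650 * 200 + 200)}
        ms = MotifSet(k=4, motifs=frozenset({"TTTT"}), excluded=frozenset())
        hm = cluster_motif_heatmap(clusters, ms, seq, row_size=300)
        assert len(hm.row_keys) == math.ceil(650 / 300)

    def test_full_coverage_inside_cluster(self, rng):
        from truncmap.clusters import CrosslinkCluster

        seq = {"tx": "T" * 2000}
        clusters = [
            CrosslinkCluster(
                ref_id="tx", start=500, end=520, count=5, peak=500,
                peak_height=5, fdr=0.01, spacing=3,
            )
        ]
        ms = MotifSet(k=4, motifs=frozenset({"TTTT"}), excluded=frozenset())
        hm = cluster_motif_heatmap(clusters, ms, seq, row_size=300, flank=10)
        assert hm.flags["single_row"]
        inside = (hm.offsets >= 0) & (hm.offsets < 20)
        np.testing.assert_allclose(hm.matrix[0][inside], 1.0)
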