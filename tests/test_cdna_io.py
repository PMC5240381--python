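import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from truncmap import simulate as sim
from truncmap.cdna_io import (
    AlignedCdna,
    collapse_umis,
    filter_short,
    length_category,
    load_alignments,
    read_fasta,
    revcomp,
    write_fasta,
    write_tsv,
)

from conftest import make_cdna


def build_bam(path, refs, records):
    """records: (name, ref, pos, reverse, cigar, seq, umi|None)"""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": r, "LN": ln} for r, ln in refs.items()],
    }
    tid = {r: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, ref, pos, reverse, cigar, seq, umi in records:
            a = pysam.AlignedSegment()
            a.query_name = name
            if ref is None:
                a.is_unmapped = True
                a.query_sequence = seq
            else:
                a.reference_id = tid[ref]
                a.reference_start = pos
                a.is_reverse = reverse
                a.cigarstring = cigar
                a.query_sequence = seq
                a.mapping_quality = 60
            if umi is not None:
                a.set_tag("RX", umi)
            bam.write(a)
    pysam.index(str(path))


class TestLoadBam:
    def test_plus_strand_deletion_offset(self, tmp_path):
        # read spans 100-129 with a 1-nt gap at reference position 104
        ref_seq = "A" * 200
        path = tmp_path / "a.bam"
        build_bam(
            path,
            {"chr": 200},
            [("r1", "chr", 100, False, "4M1D25M", "A" * 29, "ACGT")],
        )
        (c,) = load_alignments(path, "bam", {"chr": ref_seq})
        assert (c.start, c.end) == (100, 129)
        assert c.deletions == (4,)

    def test_minus_strand_orientation_flip(self, tmp_path):
        path = tmp_path / "a.bam"
        build_bam(
            path,
            {"chr": 400},
            [("r1", "chr", 200, True, "30M", "A" * 30, "ACGT")],
        )
        (c,) = load_alignments(path, "bam")
        assert (c.start, c.end) == (229, 200)
        assert c.length == 30

    def test_minus_strand_transition_is_genomic_a_to_g(self, tmp_path):
        # transcript-orientation T->C == genomic A->G on the minus strand
        genome = {"chr": "C" * 100 + "A" + "C" * 99}
        path = tmp_path / "a.bam"
        read = "G" * 10 + "G" + "G" * 9  # aligned 91..110, mismatch at 100
        build_bam(path, {"chr": 200}, [("r1", "chr", 91, True, "20M", read, "AA")])
        (c,) = load_alignments(path, "bam", genome)
        assert c.strand == "-"
        assert (c.start, c.end) == (110, 91)
        assert c.transitions == (110 - 100,)

    def test_unmapped_skipped_and_counted(self, tmp_path):
        path = tmp_path / "a.bam"
        build_bam(
            path,
            {"chr": 200},
            [
                ("r1", "chr", 10, False, "20M", "A" * 20, "AC"),
                ("r2", None, 0, False, None, "A" * 20, "AC"),
            ],
        )
        stats = {}
        cdnas = load_alignments(path, "bam", stats=stats)
        assert len(cdnas) == 1
        assert stats["n_unmapped"] == 1

    def test_missing_umi_error_and_surrogate(self, tmp_path):
        path = tmp_path / "a.bam"
        build_bam(path, {"chr": 200}, [("r1", "chr", 10, False, "20M", "A" * 20, None)])
        with pytest.raises(ValueError, match="UMI"):
            load_alignments(path, "bam")
        stats = {}
        (c,) = load_alignments(path, "bam", missing_umi="surrogate", stats=stats)
        assert stats["n_missing_umi"] == 1
        assert c.umi.startswith("__surrogate")

    def test_simulator_bam_roundtrip_matches_truth(self, tmp_path):
        cfg = sim.SimConfig(
            seed=3,
            n_transcripts=3,
            transcript_length=1500,
            n_molecules=500,
            truncation_rate=0.5,
            readthrough_deletion_rate=0.8,
            four_su=True,
            true_transition_rate=0.9,
            background_transition_rate=0.02,
            site_model=[sim.SiteSpec(kind="ytract", length=25, count=2)],
        )
        seqs, ann = sim.simulate_transcriptome(cfg)
        reads, truth = sim.simulate_reads(seqs, ann, cfg)
        path = tmp_path / "sim.bam"
        sim.write_bam(reads, seqs, path)
        loaded = {c.read_id: c for c in load_alignments(path, "bam", seqs)}
        assert len(loaded) == len(reads)
        for rec in truth.records:
            c = loaded[rec.read_id]
            assert (c.start, c.end) == (rec.start, rec.end)
            assert c.deletions == rec.del_offsets
            assert c.transitions == rec.trans_offsets
            assert c.umi == rec.umi


class TestCollapse:
    def test_same_start_same_umi_collapse_to_one(self):
        reads = [make_cdna(start=100, umi="AAAA") for _ in range(3)]
        out = collapse_umis(reads)
        assert len(out) == 1
        assert out[0].multiplicity == 3

    def test_same_start_different_umis_kept(self):
        reads = [make_cdna(start=100, umi="AAAA"), make_cdna(start=100, umi="CCCC")]
        assert len(collapse_umis(reads)) == 2

    def test_longest_end_retained(self):
        reads = [
            make_cdna(start=100, length=20, umi="AAAA"),
            make_cdna(start=100, length=35, umi="AAAA"),
        ]
        (c,) = collapse_umis(reads)
        assert c.length == 35

    def test_idempotent(self):
        reads = [
            make_cdna(start=s, umi=u)
            for s in (10, 10, 20)
            for u in ("AA", "AA", "CC")
        ]
        once = collapse_umis(reads)
        assert collapse_umis(once) == once

    def test_simulator_duplicates_collapse_exactly(self):
        cfg = sim.SimConfig(
            seed=9, n_transcripts=2, n_molecules=400, pcr_duplication=3.0,
            site_model=[sim.SiteSpec(kind="ytract", length=20, count=1)],
        )
        seqs, ann = sim.simulate_transcriptome(cfg)
        reads, truth = sim.simulate_reads(seqs, ann, cfg)
        assert len(collapse_umis(reads)) == len(truth.records)


class TestLengthHandling:
    def test_filter_short_boundary(self):
        kept = filter_short([make_cdna(length=39), make_cdna(length=40)])
        assert [c.length for c in kept] == [39]

    def test_filter_empty(self):
        assert filter_short([]) == []

    @pytest.mark.parametrize(
        "length,expected",
        [(17, "17-29"), (29, "17-29"), (30, "30-34"), (34, "30-34"),
         (35, "35-39"), (39, "35-39"), (40, ">39"), (100, ">39")],
    )
    def test_length_category(self, length, expected):
        assert length_category(make_cdna(length=length)) == expected

    def test_length_below_17_error(self):
        with pytest.raises(ValueError):
            length_category(make_cdna(length=16))

    def test_category_histogram_matches_bin_widths(self, rng):
        # uniform lengths 17..60: analytic bin probabilities by width
        n = 5000
        lengths = rng.integers(17, 61, size=n)
        cats = [length_category(make_cdna(length=int(L))) for L in lengths]
        widths = {"17-29": 13, "30-34": 5, "35-39": 5, ">39": 21}
        for cat, w in widths.items():
            p = w / 44
            se = np.sqrt(p * (1 - p) / n)
            assert abs(cats.count(cat) / n - p) < 4 * se


class TestRoundTripsAndInvariants:
    def test_tsv_round_trip(self, tmp_path):
        reads = [
            make_cdna(start=10, length=20, umi="AC", deletions=(3,), read_id="a"),
            make_cdna(start=50, length=30, strand="-", umi="GG", transitions=(1, 5)),
        ]
        path = tmp_path / "reads.tsv"
        write_tsv(reads, path)
        assert load_alignments(path, "tsv") == reads

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"a": "ACGT" * 30, "b": "TTTTGGGG"}
        path = tmp_path / "x.fa"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs

    def test_strand_symmetry(self, tmp_path):
        # reverse-complementing the genome and flipping strand leaves
        # transcript-orientation offsets unchanged
        rng = np.random.default_rng(0)
        genome = "".join(rng.choice(list("ACGT"), size=300))
        L = len(genome)
        plus = tmp_path / "plus.bam"
        seq = genome[100:104] + genome[105:130]  # 1-nt deletion at 104
        build_bam(plus, {"chr": L}, [("r", "chr", 100, False, "4M1D25M", seq, "AA")])
        (c_plus,) = load_alignments(plus, "bam", {"chr": genome})

        rc = revcomp(genome)
        minus = tmp_path / "minus.bam"
        # same physical alignment expressed on the reverse-complement genome
        rc_start = L - 130
        rc_seq = revcomp(seq)
        build_bam(
            minus, {"chr": L}, [("r", "chr", rc_start, True, "25M1D4M", rc_seq, "AA")]
        )
        (c_minus,) = load_alignments(minus, "bam", {"chr": rc})
        assert c_minus.strand == "-"
        assert c_minus.length == c_plus.length
        assert c_minus.deletions == c_plus.deletions
        assert c_minus.transitions == c_plus.transitions

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 50),  # start
                st.integers(17, 45),  # length
                st.sampled_from(["AA", "CC", "GG"]),
            ),
            max_size=30,
        )
    )
    def test_collapse_idempotence_property(self, triples):
        reads = [make_cdna(start=s, length=L, umi=u) for s, L, u in triples]
        once = collapse_umis(reads)
        assert collapse_umis(once) == once
        assert sum(c.multiplicity for c in once) == len(reads)

    def test_offsets_validated(self):
        with pytest.raises(ValueError):
            AlignedCdna("tx", "+", 10, 29, "AA", deletions=(25,))
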