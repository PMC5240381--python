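import numpy as np
import pytest

from truncmap import simulate as sim
from truncmap.cdna_io import AlignedCdna, collapse_umis


def make_cdna(
    ref="tx",
    start=100,
    length=30,
    strand="+",
    umi="AAAA",
    deletions=(),
    transitions=(),
    multiplicity=1,
    read_id=None,
):
    end = start + length - 1 if strand == "+" else start - length + 1
    return AlignedCdna(
        ref_id=ref,
        strand=strand,
        start=start,
        end=end,
        umi=umi,
        deletions=tuple(deletions),
        transitions=tuple(transitions),
        multiplicity=multiplicity,
        read_id=read_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def motif_library():
    """Simulated truncated library with crosslinks on planted TTGG sites."""
    cfg = sim.SimConfig(
        seed=7,
        n_transcripts=6,
        transcript_length=2500,
        n_molecules=4000,
        truncation_rate=1.0,
        site_model=[sim.SiteSpec(kind="motif", motif="TTGG", count=4)],
        cdna_length_dist=("uniform", 20, 45),
    )
    sequences, annotation = sim.simulate_transcriptome(cfg)
    reads, truth = sim.simulate_reads(sequences, annotation, cfg)
    return sequences, annotation, collapse_umis(reads), truth


def random_cdnas(rng, sequences, n, length_range=(17, 50)):
    """Uniform random reads over the given sequences (null library)."""
    refs = sorted(sequences)
    out = []
    for i in range(n):
        ref = refs[rng.integers(len(refs))]
        L = int(rng.integers(*length_range))
        start = int(rng.integers(20, len(sequences[ref]) - L - 20))
        out.append(
            make_cdna(ref=ref, start=start, length=L, umi=f"U{i}", read_id=f"r{i}")
        )
    return out


def random_sequences(rng, n=4, length=2000):
    return {
        f"tx{i:04d}": "".join(rng.choice(list("ACGT"), size=length))
        for i in range(n)
    }
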