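"""Synthetic transcriptomes and iCLIP-like reads with per-read ground truth.

The generative model: each molecule crosslinks at a position drawn from the
planted binding sites; the RNA fragment's 3' end comes from a cleavage
model (unconstrained, or constrained to explicit positions / a sequence
context); reverse transcription either truncates at the crosslink (cDNA
starts one nucleotide downstream of it) or reads through, optionally
leaving a deletion at the crosslink. 4SU mode injects T->C transitions at
crosslinks contained in the read plus background transitions at other Ts.
Reads shorter than 17 nt are discarded and counted; PCR duplicates share a
UMI and coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from truncmap.cdna_io import AlignedCdna, RegionAnnotation, write_bed, write_fasta

MIN_CDNA_LENGTH = 17
BASES = np.array(list("ACGT"))


@dataclass
class SiteSpec:
    """One binding-site planting rule.

    kind="motif": plant ``motif`` at per-nucleotide ``density`` (or a fixed
    ``count`` per transcript). kind="ytract": plant ``count`` pyrimidine
    tracts of ``length`` nt per transcript (pure T, or T/C mixed via
    ``c_fraction``).
    """

    kind: str = "motif"
    motif: str | None = None
    length: int | tuple[int, int] | None = None
    density: float | None = None
    count: int | None = None
    c_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("motif", "ytract"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.kind == "motif":
            if not self.motif or set(self.motif) - set("ACGT"):
                raise ValueError("motif sites need a non-empty ACGT motif")
            if self.density is None and self.count is None:
                raise ValueError("motif sites need density or count")
        else:
            if self.length is None:
                raise ValueError("ytract sites need a length")
            if self.count is None and self.density is None:
                self.count = 1


@dataclass
class CleavageModel:
    """RNase cleavage model for the fragment 3' end.

    kind="uniform": the cDNA-end falls wherever the sampled length puts it.
    kind="positional": cleavage restricted to explicit allowed positions
    (``positions`` per reference, or a regular grid every ``spacing`` nt).
    kind="sequence": cleavage only after ``after_base``.
    ``leak`` is the probability of falling back to unconstrained cleavage
    (residual non-specific fragmentation).
    """

    kind: str = "uniform"
    positions: Mapping[str, Sequence[int]] | None = None
    spacing: int | None = None
    after_base: str | None = None
    leak: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "positional", "sequence"):
            raise ValueError(f"unknown cleavage model {self.kind!r}")
        if self.kind == "positional" and self.positions is None and self.spacing is None:
            raise ValueError("positional cleavage needs positions or spacing")
        if self.kind == "sequence" and self.after_base not in list("ACGT"):
            raise ValueError("sequence cleavage needs after_base in ACGT")
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError("leak must be in [0,1]")


@dataclass
class SimConfig:
    seed: int = 0
    n_transcripts: int = 10
    transcript_length: int | tuple[int, int] = 2000
    site_model: list[SiteSpec] = field(default_factory=lambda: [SiteSpec(kind="ytract", length=30)])
    crosslink_offset_dist: str | int | Sequence[float] = "uniform"
    truncation_rate: float = 0.85
    readthrough_deletion_rate: float = 0.5
    readthrough_tail_p: float = 0.25
    four_su: bool = False
    true_transition_rate: float = 0.0
    background_transition_rate: float = 0.0
    cleavage_model: CleavageModel = field(default_factory=CleavageModel)
    cdna_length_dist: tuple = ("uniform", 20, 45)
    pcr_duplication: float = 0.0
    n_molecules: int = 1000
    n_exons: int = 1
    model_sequencing_error: bool = False
    sequencing_error_deletion_rate: float = 0.0

    def __post_init__(self) -> None:
        probs = {
            "truncation_rate": self.truncation_rate,
            "readthrough_deletion_rate": self.readthrough_deletion_rate,
            "true_transition_rate": self.true_transition_rate,
            "background_transition_rate": self.background_transition_rate,
            "sequencing_error_deletion_rate": self.sequencing_error_deletion_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} not in [0,1]")
        if not 0.0 < self.readthrough_tail_p <= 1.0:
            raise ValueError("readthrough_tail_p must be in (0,1]")
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be non-negative")
        if self.pcr_duplication < 0:
            raise ValueError("pcr_duplication must be non-negative")
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        if min(_length_support(self.cdna_length_dist)) < MIN_CDNA_LENGTH:
            raise ValueError(
                f"cdna_length_dist support must be >= {MIN_CDNA_LENGTH} nt"
            )
        self.site_model = [
            s if isinstance(s, SiteSpec) else SiteSpec(**s) for s in self.site_model
        ]
        if isinstance(self.cleavage_model, dict):
            self.cleavage_model = CleavageModel(**self.cleavage_model)


def _length_support(dist: tuple) -> tuple[int, int]:
    kind = dist[0]
    if kind == "uniform":
        _, lo, hi = dist
        return int(lo), int(hi)
    if kind == "choice":
        values = dist[1]
        return int(min(values)), int(max(values))
    if kind == "fixed":
        return int(dist[1]), int(dist[1])
    raise ValueError(f"unknown cdna_length_dist kind {kind!r}")


def _sample_length(dist: tuple, rng: np.random.Generator) -> int:
    kind = dist[0]
    if kind == "uniform":
        return int(rng.integers(dist[1], dist[2] + 1))
    if kind == "choice":
        values, probs = dist[1], (dist[2] if len(dist) > 2 else None)
        return int(rng.choice(np.asarray(values), p=probs))
    if kind == "fixed":
        return int(dist[1])
    raise ValueError(kind)


def _sample_transcript_length(spec, rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


@dataclass
class TruthRecord:
    read_id: str
    ref_id: str
    crosslink: int
    truncated: bool
    cleavage: int
    start: int
    end: int
    umi: str
    n_copies: int
    del_offsets: tuple[int, ...] = ()
    trans_offsets: tuple[int, ...] = ()


@dataclass
class SimGroundTruth:
    records: list[TruthRecord] = field(default_factory=list)
    n_molecules: int = 0
    n_dropped_short: int = 0
    n_dropped_no_cut: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.records])

    def write_tsv(self, path: str | Path) -> None:
        cols = (
            "read_id ref_id crosslink truncated cleavage start end umi "
            "n_copies del_offsets trans_offsets"
        ).split()
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                dels = ",".join(map(str, r.del_offsets)) or "."
                trans = ",".join(map(str, r.trans_offsets)) or "."
                fh.write(
                    f"{r.read_id}\t{r.ref_id}\t{r.crosslink}\t{int(r.truncated)}\t"
                    f"{r.cleavage}\t{r.start}\t{r.end}\t{r.umi}\t{r.n_copies}\t"
                    f"{dels}\t{trans}\n"
                )


# ---------------------------------------------------------------------------
# transcriptome


def simulate_transcriptome(
    config: SimConfig,
) -> tuple[dict[str, str], RegionAnnotation]:
    """Generate random-background transcripts with planted sites, Y-tracts
    and exon-exon junctions; every planted feature is annotated."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ann = RegionAnnotation()
    sequences: dict[str, str] = {}
    for i in range(config.n_transcripts):
        ref = f"tx{i:04d}"
        length = _sample_transcript_length(config.transcript_length, rng)
        seq = rng.choice(BASES, size=length)

        for spec in config.site_model:
            if spec.kind == "motif":
                site_len = len(spec.motif)
                if site_len > length:
                    raise ValueError(
                        f"site of length {site_len} longer than transcript {ref} ({length} nt)"
                    )
                if spec.count is not None:
                    n_plant = spec.count
                else:
                    n_plant = int(rng.binomial(length, spec.density))
                lo, hi = _plant_bounds(length, site_len)
                for _ in range(n_plant):
                    pos = int(rng.integers(lo, hi + 1))
                    seq[pos : pos + site_len] = list(spec.motif)
                    ann.sites.append((ref, pos, pos + site_len, f"motif:{spec.motif}"))
            else:
                if isinstance(spec.length, int):
                    tract_lens = [spec.length]
                else:
                    t_lo, t_hi = spec.length
                    tract_lens = None  # sampled per plant
                n_plant = spec.count if spec.count is not None else int(
                    rng.binomial(length, spec.density)
                )
                for _ in range(n_plant):
                    tl = (
                        tract_lens[0]
                        if tract_lens
                        else int(rng.integers(t_lo, t_hi + 1))
                    )
                    if tl > length:
                        raise ValueError(
                            f"Y-tract of length {tl} longer than transcript {ref} ({length} nt)"
                        )
                    lo, hi = _plant_bounds(length, tl)
                    pos = int(rng.integers(lo, hi + 1))
                    tract = np.where(
                        rng.random(tl) < spec.c_fraction, "C", "T"
                    )
                    seq[pos : pos + tl] = tract
                    ann.sites.append((ref, pos, pos + tl, "ytract"))
                    ann.ytracts.append((ref, pos, pos + tl))

        sequences[ref] = "".join(seq)
        ann.transcript_lengths[ref] = length
        if config.n_exons > 1:
            bounds = np.linspace(0, length, config.n_exons + 1).astype(int)
            ann.exons[ref] = [
                (int(bounds[j]), int(bounds[j + 1])) for j in range(config.n_exons)
            ]
            ann.junctions[ref] = [int(b) for b in bounds[1:-1]]
        else:
            ann.exons[ref] = [(0, length)]
            ann.junctions[ref] = []
    return sequences, ann


def _plant_bounds(length: int, site_len: int, margin: int = 130) -> tuple[int, int]:
    # keep sites away from the edges when the transcript is long enough, so
    # flank-dependent analyses (maps, motif windows) are not edge-truncated
    lo, hi = 0, length - site_len
    if length >= site_len + 2 * margin:
        lo, hi = margin, length - site_len - margin
    return lo, hi


# ---------------------------------------------------------------------------
# reads


def _crosslink_offset(dist, site_len: int, rng: np.random.Generator) -> int:
    if isinstance(dist, str):
        if dist == "uniform":
            return int(rng.integers(0, site_len))
        raise ValueError(f"unknown crosslink_offset_dist {dist!r}")
    if isinstance(dist, int):
        return min(dist, site_len - 1)
    probs = np.asarray(dist, dtype=float)[:site_len]
    probs = probs / probs.sum()
    return int(rng.choice(len(probs), p=probs))


def _umi_for(idx: int) -> str:
    # deterministic, globally unique 12-mer so that UMI collapse recovers
    # the molecule count exactly
    chars = []
    for _ in range(12):
        chars.append("ACGT"[idx & 3])
        idx >>= 2
    return "".join(chars)


def _allowed_cuts(model: CleavageModel, ref: str, seq: str) -> np.ndarray:
    if model.kind == "positional":
        if model.positions is not None:
            pos = np.asarray(sorted(model.positions.get(ref, ())), dtype=int)
        else:
            pos = np.arange(model.spacing - 1, len(seq), model.spacing)
        return pos
    if model.kind == "sequence":
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        return np.nonzero(arr == ord(model.after_base))[0]
    raise AssertionError


def simulate_reads(
    sequences: Mapping[str, str],
    annotation: RegionAnnotation,
    config: SimConfig,
) -> tuple[list[AlignedCdna], SimGroundTruth]:
    """Emit aligned reads plus ground truth for ``config.n_molecules``
    molecules crosslinked on the annotated sites."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sites = [s for s in annotation.sites if s[0] in sequences]
    if not sites:
        raise ValueError("no crosslink sites planted on any transcript")

    cut_cache: dict[str, np.ndarray] = {}
    model = config.cleavage_model
    if model.kind != "uniform":
        for ref, seq in sequences.items():
            cut_cache[ref] = _allowed_cuts(model, ref, seq)

    truth = SimGroundTruth(n_molecules=config.n_molecules)
    reads: list[AlignedCdna] = []

    site_idx = rng.integers(0, len(sites), size=config.n_molecules)
    for i in range(config.n_molecules):
        ref, s_lo, s_hi, _label = sites[site_idx[i]]
        seq = sequences[ref]
        tlen = len(seq)
        xl = s_lo + _crosslink_offset(config.crosslink_offset_dist, s_hi - s_lo, rng)
        length_target = _sample_length(config.cdna_length_dist, rng)

        # fragment 3' end (cDNA-end, inclusive)
        use_uniform = model.kind == "uniform" or (
            model.leak > 0 and rng.random() < model.leak
        )
        if use_uniform:
            end = xl + length_target
            if end >= tlen:
                truth.n_dropped_no_cut += 1
                continue
        else:
            cuts = cut_cache[ref]
            lo = np.searchsorted(cuts, xl + MIN_CDNA_LENGTH)
            legal = cuts[lo:]
            legal = legal[legal < tlen]
            if legal.size == 0:
                truth.n_dropped_no_cut += 1
                continue
            end = int(legal[np.argmin(np.abs(legal - (xl + length_target)))])

        truncated = bool(rng.random() < config.truncation_rate)
        deletions: list[int] = []
        if truncated:
            start = xl + 1
        else:
            start = max(0, xl - int(rng.geometric(config.readthrough_tail_p)))
            if rng.random() < config.readthrough_deletion_rate:
                deletions.append(xl - start)

        length = end - start + 1
        if length < MIN_CDNA_LENGTH:
            truth.n_dropped_short += 1
            continue

        if config.model_sequencing_error and config.sequencing_error_deletion_rate > 0:
            if rng.random() < config.sequencing_error_deletion_rate:
                off = int(rng.integers(0, length))
                if off not in deletions:
                    deletions.append(off)

        transitions: list[int] = []
        if config.four_su:
            if (
                start <= xl <= end
                and seq[xl] == "T"
                and rng.random() < config.true_transition_rate
            ):
                transitions.append(xl - start)
            if config.background_transition_rate > 0:
                body = np.frombuffer(seq[start : end + 1].encode(), dtype=np.uint8)
                t_offsets = np.nonzero(body == ord("T"))[0]
                hit = t_offsets[
                    rng.random(t_offsets.size) < config.background_transition_rate
                ]
                transitions.extend(int(o) for o in hit)
            # a deleted base cannot also show a mismatch
            transitions = sorted(set(transitions) - set(deletions))

        umi = _umi_for(i)
        n_copies = 1 + (
            int(rng.poisson(config.pcr_duplication)) if config.pcr_duplication > 0 else 0
        )
        read_id = f"m{i:07d}"
        rec = AlignedCdna(
            ref_id=ref,
            strand="+",
            start=start,
            end=end,
            umi=umi,
            deletions=tuple(sorted(deletions)),
            transitions=tuple(transitions),
            read_id=read_id,
        )
        for j in range(n_copies):
            reads.append(
                rec if j == 0 else replace(rec, read_id=f"{read_id}.d{j}")
            )
        truth.records.append(
            TruthRecord(
                read_id=read_id,
                ref_id=ref,
                crosslink=xl,
                truncated=truncated,
                cleavage=end,
                start=start,
                end=end,
                umi=umi,
                n_copies=n_copies,
                del_offsets=tuple(sorted(deletions)),
                trans_offsets=tuple(transitions),
            )
        )
    return reads, truth


# ---------------------------------------------------------------------------
# writers


def write_outputs(
    sequences: Mapping[str, str],
    annotation: RegionAnnotation,
    reads: Iterable[AlignedCdna],
    truth: SimGroundTruth,
    outdir: str | Path,
    bam: bool = False,
) -> dict[str, Path]:
    """Write FASTA / BED6 / reads TSV / truth TSV (and optionally BAM)."""
    from truncmap.cdna_io import write_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcripts.fa",
        "sites": outdir / "sites.bed",
        "junctions": outdir / "junctions.bed",
        "ytracts": outdir / "ytracts.bed",
        "reads": outdir / "reads.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(sequences, paths["fasta"])
    write_bed(
        [(r, lo, hi, name) for r, lo, hi, name in annotation.sites], paths["sites"]
    )
    write_bed(
        [
            (ref, pos, pos + 1, f"junction{j}")
            for ref, positions in annotation.junctions.items()
            for j, pos in enumerate(positions)
        ],
        paths["junctions"],
    )
    write_bed(
        [(r, lo, hi, "ytract") for r, lo, hi in annotation.ytracts], paths["ytracts"]
    )
    reads = list(reads)
    write_tsv(reads, paths["reads"])
    truth.write_tsv(paths["truth"])
    if bam:
        paths["bam"] = outdir / "reads.bam"
        write_bam(reads, sequences, paths["bam"])
    return paths


def write_bam(
    reads: Iterable[AlignedCdna],
    sequences: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write simulated plus-strand reads as a coordinate-sorted, indexed BAM
    with UMIs in the RX tag, deletions in the CIGAR and transitions as
    sequence mismatches."""
    import pysam

    refs = sorted(sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": r, "LN": len(sequences[r])} for r in refs],
    }
    tid = {r: i for i, r in enumerate(refs)}
    records = sorted(reads, key=lambda c: (c.ref_id, min(c.start, c.end)))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for c in records:
            if c.strand != "+":
                raise ValueError("write_bam only supports simulated plus-strand reads")
            a = pysam.AlignedSegment()
            a.query_name = c.read_id or "read"
            a.reference_id = tid[c.ref_id]
            a.reference_start = c.start
            a.mapping_quality = 60
            ref_seq = sequences[c.ref_id][c.start : c.end + 1]
            dels = set(c.deletions)
            query = [
                ("C" if off in c.transitions else base)
                for off, base in enumerate(ref_seq)
                if off not in dels
            ]
            a.query_sequence = "".join(query)
            a.cigartuples = _cigar_from_deletions(c.length, sorted(dels))
            a.set_tag("RX", c.umi)
            bam.write(a)
    pysam.index(str(path))


def _cigar_from_deletions(length: int, deletions: list[int]) -> list[tuple[int, int]]:
    cigar: list[tuple[int, int]] = []
    prev = 0
    for off in deletions:
        if off > prev:
            cigar.append((0, off - prev))
        if cigar and cigar[-1][0] == 2:
            cigar[-1] = (2, cigar[-1][1] + 1)
        else:
            cigar.append((2, 1))
        prev = off + 1
    if length > prev:
        cigar.append((0, length - prev))
    return cigar
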