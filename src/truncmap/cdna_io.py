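"""Alignment I/O, mutation-offset extraction, UMI collapse and length filters.

All coordinates are 0-based. A read is represented in *transcript
orientation*: ``start`` is the cDNA-start (first transcribed nucleotide) and
``end`` the cDNA-end (last transcribed nucleotide, inclusive). On
minus-strand genomic alignments the cDNA-start therefore maps to the highest
genomic coordinate and ``start > end`` numerically.

Deletion and transition offsets are measured in reference space from the
cDNA-start (offset 0 = the start nucleotide itself). Transitions are fixed
to reference-T -> read-C in transcript orientation (on a minus-strand
genomic alignment this is a genomic A -> G mismatch).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: ordered length-category labels used throughout the analyses
LENGTH_CATEGORIES = ("17-29", "30-34", "35-39", ">39")

TSV_COLUMNS = (
    "read_id",
    "ref",
    "start",
    "end",
    "strand",
    "umi",
    "del_offsets",
    "trans_offsets",
    "multiplicity",
)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignedCdna:
    """One mapped, UMI-tagged cDNA in transcript orientation."""

    ref_id: str
    strand: str
    start: int
    end: int
    umi: str
    deletions: tuple[int, ...] = ()
    transitions: tuple[int, ...] = ()
    multiplicity: int = 1
    read_id: str | None = None

    @property
    def length(self) -> int:
        """Reference-space length in nt (deleted bases included)."""
        return abs(self.end - self.start) + 1

    def position_at(self, offset: int) -> int:
        """Reference coordinate of the nucleotide at ``offset`` from the
        cDNA-start, following transcript orientation."""
        return self.start + offset if self.strand == "+" else self.start - offset

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        for off in (*self.deletions, *self.transitions):
            if not 0 <= off < self.length:
                raise ValueError(
                    f"mutation offset {off} outside read of length {self.length}"
                )


@dataclass
class RegionAnnotation:
    """Planted / annotated features on a reference set.

    ``junctions`` maps reference -> sorted exon-exon junction positions,
    where a junction position is the first nucleotide of the downstream
    exon. ``exons`` and ``introns`` are half-open intervals.
    """

    transcript_lengths: dict[str, int] = field(default_factory=dict)
    junctions: dict[str, list[int]] = field(default_factory=dict)
    ytracts: list[tuple[str, int, int]] = field(default_factory=list)
    sites: list[tuple[str, int, int, str]] = field(default_factory=list)
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    introns: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def gene_spans(self) -> list[tuple[str, int, int]]:
        return [(ref, 0, ln) for ref, ln in self.transcript_lengths.items()]

    def internal_junctions(self) -> list[tuple[str, int]]:
        """Junctions excluding the first and last one of each transcript."""
        out: list[tuple[str, int]] = []
        for ref, positions in self.junctions.items():
            for pos in sorted(positions)[1:-1]:
                out.append((ref, pos))
        return out


class ReferenceLookup:
    """Uniform access to reference sequence, from a dict or a FASTA path."""

    def __init__(self, reference: Mapping[str, str] | str | Path):
        if isinstance(reference, (str, Path)):
            self._seqs = read_fasta(reference)
        else:
            self._seqs = dict(reference)

    def fetch(self, ref_id: str, start: int, end: int) -> str:
        return self._seqs[ref_id][max(start, 0) : end]

    def base(self, ref_id: str, pos: int) -> str:
        seq = self._seqs[ref_id]
        if not 0 <= pos < len(seq):
            return "N"
        return seq[pos]

    def length(self, ref_id: str) -> int:
        return len(self._seqs[ref_id])

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._seqs


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# loading


def _offsets_str(offsets: Sequence[int]) -> str:
    return ",".join(str(o) for o in offsets) if offsets else "."


def _parse_offsets(text: str) -> tuple[int, ...]:
    if text in (".", ""):
        return ()
    return tuple(int(x) for x in text.split(","))


def write_tsv(cdnas: Iterable[AlignedCdna], path: str | Path) -> None:
    """Write the documented TSV dialect (see TSV_COLUMNS)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for c in cdnas:
            writer.writerow(
                [
                    c.read_id or ".",
                    c.ref_id,
                    c.start,
                    c.end,
                    c.strand,
                    c.umi,
                    _offsets_str(c.deletions),
                    _offsets_str(c.transitions),
                    c.multiplicity,
                ]
            )


def _load_tsv(path: str | Path) -> list[AlignedCdna]:
    out: list[AlignedCdna] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                AlignedCdna(
                    ref_id=row["ref"],
                    strand=row["strand"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    umi=row["umi"],
                    deletions=_parse_offsets(row["del_offsets"]),
                    transitions=_parse_offsets(row["trans_offsets"]),
                    multiplicity=int(row.get("multiplicity", 1) or 1),
                    read_id=None if row["read_id"] == "." else row["read_id"],
                )
            )
    return out


def _load_bam(
    path: str | Path,
    reference: ReferenceLookup | None,
    umi_tag: str,
    missing_umi: str,
    stats: dict,
) -> list[AlignedCdna]:
    import pysam

    out: list[AlignedCdna] = []
    surrogate = 0
    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped:
                stats["n_unmapped"] += 1
                continue
            if rec.has_tag(umi_tag):
                umi = str(rec.get_tag(umi_tag))
            elif missing_umi == "error":
                raise ValueError(f"read {rec.query_name} lacks UMI tag {umi_tag}")
            else:
                umi = f"__surrogate{surrogate}"
                surrogate += 1
                stats["n_missing_umi"] += 1
            strand = "-" if rec.is_reverse else "+"
            g_lo = rec.reference_start
            g_hi = rec.reference_end - 1  # inclusive
            if strand == "+":
                start, end = g_lo, g_hi
            else:
                start, end = g_hi, g_lo

            deletions: list[int] = []
            ref_pos = g_lo
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):  # M, =, X consume both
                    ref_pos += ln
                elif op == 2:  # D: reference bases absent from the read
                    for j in range(ln):
                        g = ref_pos + j
                        deletions.append(g - start if strand == "+" else start - g)
                    ref_pos += ln
                elif op == 3:  # N
                    ref_pos += ln
                # I, S, H, P do not consume reference

            transitions: list[int] = []
            if reference is not None and rec.reference_name in reference:
                want_ref, want_read = ("T", "C") if strand == "+" else ("A", "G")
                seq = rec.query_sequence or ""
                for q, g in rec.get_aligned_pairs(matches_only=True):
                    if reference.base(rec.reference_name, g) == want_ref and seq[q] == want_read:
                        transitions.append(g - start if strand == "+" else start - g)

            out.append(
                AlignedCdna(
                    ref_id=rec.reference_name,
                    strand=strand,
                    start=start,
                    end=end,
                    umi=umi,
                    deletions=tuple(sorted(deletions)),
                    transitions=tuple(sorted(transitions)),
                    read_id=rec.query_name,
                )
            )
    return out


def load_alignments(
    path: str | Path,
    format: str = "tsv",
    reference: Mapping[str, str] | str | Path | ReferenceLookup | None = None,
    umi_tag: str = "RX",
    missing_umi: str = "error",
    stats: dict | None = None,
) -> list[AlignedCdna]:
    """Load aligned cDNAs from BAM or the TSV dialect.

    Parameters
    ----------
    format
        ``"bam"`` or ``"tsv"``.
    reference
        Needed for transition extraction from BAM (dict, FASTA path or
        :class:`ReferenceLookup`).
    missing_umi
        ``"error"`` or ``"surrogate"`` (assign a unique surrogate UMI and
        count it in ``stats``).
    stats
        Optional dict filled with ``n_unmapped`` / ``n_missing_umi``.
    """
    if stats is None:
        stats = {}
    stats.setdefault("n_unmapped", 0)
    stats.setdefault("n_missing_umi", 0)
    if format == "tsv":
        return _load_tsv(path)
    if format == "bam":
        if reference is not None and not isinstance(reference, ReferenceLookup):
            reference = ReferenceLookup(reference)
        return _load_bam(path, reference, umi_tag, missing_umi, stats)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# UMI collapse and length handling


def collapse_umis(cdnas: Iterable[AlignedCdna]) -> list[AlignedCdna]:
    """Collapse PCR duplicates: records identical in (ref, strand, start,
    umi) become one record. The representative is the record with the
    longest reference span; multiplicities are summed.
    """
    groups: dict[tuple[str, str, int, str], AlignedCdna] = {}
    mult: dict[tuple[str, str, int, str], int] = {}
    for c in cdnas:
        key = (c.ref_id, c.strand, c.start, c.umi)
        mult[key] = mult.get(key, 0) + c.multiplicity
        best = groups.get(key)
        if best is None or c.length > best.length:
            groups[key] = c
    out = [replace(groups[k], multiplicity=mult[k]) for k in groups]
    out.sort(key=lambda c: (c.ref_id, c.strand, c.start, c.umi))
    return out


def filter_short(
    cdnas: Iterable[AlignedCdna], max_length_exclusive: int = 40
) -> list[AlignedCdna]:
    """Keep cDNAs strictly shorter than ``max_length_exclusive`` nt."""
    return [c for c in cdnas if c.length < max_length_exclusive]


def length_category(cdna: AlignedCdna) -> str:
    """Bin a cDNA into the four length categories 17-29 / 30-34 / 35-39 / >39."""
    n = cdna.length
    if n < 17:
        raise ValueError(f"cDNA length {n} < 17")
    if n <= 29:
        return "17-29"
    if n <= 34:
        return "30-34"
    if n <= 39:
        return "35-39"
    return ">39"


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]],
    path: str | Path,
    strand: str = "+",
) -> None:
    """Write (ref, start, end, name) intervals as BED6 (score = 0)."""
    with open(path, "w") as fh:
        for ref, lo, hi, name in intervals:
            fh.write(f"{ref}\t{lo}\t{hi}\t{name}\t0\t{strand}\n")
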