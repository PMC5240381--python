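"""Crosslink-associated (CL) motif definition and positional profiling.

CL-motifs are k-mers enriched at the nucleotide preceding cDNA-starts
(offset -1) relative to a far upstream control offset (-10). A k-mer
"overlaps" an offset when any of its k occurrence registers covers that
nucleotide. Profiles and classifications operate on collapsed cDNAs, each
counted once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from truncmap.cdna_io import AlignedCdna, ReferenceLookup, revcomp


@dataclass
class PositionalProfile:
    """Per-offset counts or proportions relative to an anchor."""

    anchor: str
    lo: int
    hi: int
    values: np.ndarray
    denominator: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.hi - self.lo + 1:
            raise ValueError("values do not span [lo, hi]")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def value_at(self, offset: int) -> float:
        return float(self.values[offset - self.lo])

    def argmax_offset(self) -> int:
        return int(self.lo + int(np.argmax(self.values)))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tvalue\tdenominator\n")
            for off, val in zip(self.offsets, self.values):
                fh.write(f"{off}\t{val:.10g}\t{self.denominator}\n")


@dataclass
class MotifSet:
    k: int
    motifs: frozenset[str]
    enrichment: dict[str, float] = field(default_factory=dict)
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.motifs = frozenset(self.motifs)
        self.excluded = frozenset(self.excluded)
        bad = {m for m in self.motifs if len(m) != self.k or set(m) - set("ACGT")}
        if bad:
            raise ValueError(f"invalid motifs {bad}")
        if self.motifs & self.excluded:
            raise ValueError("excluded motif present in motif set")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in sorted(self.motifs, key=lambda m: -self.enrichment.get(m, 0)):
                fh.write(f"{m}\t{self.enrichment.get(m, float('nan')):.6g}\n")


def _window_in_orientation(
    ref: ReferenceLookup, cdna: AlignedCdna, lo: int, hi: int
) -> str | None:
    """Sequence covering offsets [lo, hi] from the cDNA-start, transcript
    orientation; None if the window leaves the reference."""
    if cdna.strand == "+":
        a, b = cdna.start + lo, cdna.start + hi
        if a < 0 or b >= ref.length(cdna.ref_id):
            return None
        return ref.fetch(cdna.ref_id, a, b + 1)
    a, b = cdna.start - hi, cdna.start - lo
    if a < 0 or b >= ref.length(cdna.ref_id):
        return None
    return revcomp(ref.fetch(cdna.ref_id, a, b + 1))


def _kmers_covering(
    ref: ReferenceLookup, cdna: AlignedCdna, offset: int, k: int
) -> set[str] | None:
    """All k-mers whose occurrence covers the nucleotide at ``offset``."""
    window = _window_in_orientation(ref, cdna, offset - k + 1, offset + k - 1)
    if window is None:
        return None
    return {window[i : i + k] for i in range(k)}


def define_cl_motifs(
    cdnas: Iterable[AlignedCdna],
    sequences: Mapping[str, str] | ReferenceLookup,
    k: int = 4,
    near_offset: int = -1,
    far_offset: int = -10,
    min_fold: float = 1.5,
    exclude: Sequence[str] = ("TTTT",),
    stats: dict | None = None,
) -> MotifSet:
    """k-mers enriched > ``min_fold`` at ``near_offset`` vs ``far_offset``
    relative to the cDNA-start, minus ``exclude``.

    A k-mer is counted once per cDNA when any occurrence overlaps the
    nucleotide at the given offset. cDNAs too close to the reference edge
    are skipped and counted in ``stats['n_skipped']``.
    """
    ref = sequences if isinstance(sequences, ReferenceLookup) else ReferenceLookup(sequences)
    near: Counter[str] = Counter()
    far: Counter[str] = Counter()
    skipped = 0
    for c in cdnas:
        kn = _kmers_covering(ref, c, near_offset, k)
        kf = _kmers_covering(ref, c, far_offset, k)
        if kn is None or kf is None:
            skipped += 1
            continue
        near.update(kn)
        far.update(kf)
    if stats is not None:
        stats["n_skipped"] = skipped
    enrichment: dict[str, float] = {}
    passing: set[str] = set()
    for kmer, n in near.items():
        f = far.get(kmer, 0)
        ratio = n / f if f > 0 else float("inf")
        enrichment[kmer] = ratio
        if ratio > min_fold and kmer not in exclude:
            passing.add(kmer)
    return MotifSet(
        k=k,
        motifs=frozenset(passing),
        enrichment={m: enrichment[m] for m in passing},
        excluded=frozenset(exclude),
    )


def motif_occurrences(seq: str, motifs: Iterable[str]) -> list[tuple[int, int]]:
    """(start, end) half-open spans of every motif occurrence in ``seq``."""
    out = []
    for m in motifs:
        k = len(m)
        pos = seq.find(m)
        while pos != -1:
            out.append((pos, pos + k))
            pos = seq.find(m, pos + 1)
    return out


def motif_coverage_profile(
    cdnas: Iterable[AlignedCdna],
    motifs: MotifSet,
    sequences: Mapping[str, str] | ReferenceLookup,
    window: tuple[int, int] = (-20, 40),
) -> PositionalProfile:
    """Fraction of cDNAs with any motif occurrence covering the nucleotide
    at each offset from the cDNA-start."""
    if not motifs.motifs:
        raise ValueError("empty motif set")
    ref = sequences if isinstance(sequences, ReferenceLookup) else ReferenceLookup(sequences)
    lo, hi = window
    k = motifs.k
    counts = np.zeros(hi - lo + 1, dtype=float)
    n = 0
    for c in cdnas:
        n += 1
        # scan an extended window so occurrences straddling the edges count
        ext = _window_in_orientation(ref, c, lo - k + 1, hi + k - 1)
        if ext is None:
            # clip to what the reference provides; offsets outside stay uncovered
            ext_lo = lo - k + 1
            if c.strand == "+":
                a = max(0, c.start + ext_lo)
                b = min(ref.length(c.ref_id) - 1, c.start + hi + k - 1)
                ext = ref.fetch(c.ref_id, a, b + 1)
                ext_lo = a - c.start
            else:
                a = max(0, c.start - (hi + k - 1))
                b = min(ref.length(c.ref_id) - 1, c.start - ext_lo)
                ext = revcomp(ref.fetch(c.ref_id, a, b + 1))
                ext_lo = c.start - b
        else:
            ext_lo = lo - k + 1
        covered = np.zeros(hi - lo + 1, dtype=bool)
        for s, e in motif_occurrences(ext, motifs.motifs):
            o_lo = max(s + ext_lo, lo)
            o_hi = min(e - 1 + ext_lo, hi)
            if o_lo <= o_hi:
                covered[o_lo - lo : o_hi - lo + 1] = True
        counts += covered
    values = counts / n if n else counts
    return PositionalProfile("cdna_start", lo, hi, values, n)


def mutation_density_profile(
    cdnas: Iterable[AlignedCdna],
    kind: str,
    max_position: int | None = None,
) -> PositionalProfile:
    """Fraction of cDNAs carrying a deletion/transition at each 1-based
    position along the read."""
    if kind not in ("deletion", "transition"):
        raise ValueError(f"unknown mutation kind {kind!r}")
    cdnas = list(cdnas)
    if max_position is None:
        max_position = max((c.length for c in cdnas), default=1)
    counts = np.zeros(max_position, dtype=float)
    for c in cdnas:
        offsets = c.deletions if kind == "deletion" else c.transitions
        for off in offsets:
            if off < max_position:
                counts[off] += 1
    n = len(cdnas)
    values = counts / n if n else counts
    return PositionalProfile("cdna_start_1based", 1, max_position, values, n)


def _mutations(cdna: AlignedCdna, kind: str) -> tuple[int, ...]:
    if kind == "deletion":
        return cdna.deletions
    if kind == "transition":
        return cdna.transitions
    raise ValueError(f"unknown mutation kind {kind!r}")


def classify_by_mutation(
    cdnas: Iterable[AlignedCdna], kind: str, first_zone: int = 7
) -> dict[str, list[AlignedCdna]]:
    """Partition into first7 / elsewhere / none by the most 5' mutation
    (1-based positions 1..7 -> first7)."""
    out: dict[str, list[AlignedCdna]] = {"first7": [], "elsewhere": [], "none": []}
    for c in cdnas:
        muts = _mutations(c, kind)
        if not muts:
            out["none"].append(c)
        elif min(muts) < first_zone:  # offset 0..6 == positions 1..7
            out["first7"].append(c)
        else:
            out["elsewhere"].append(c)
    return out


def subdivide_first7(
    cdnas_first7: Iterable[AlignedCdna],
    motifs: MotifSet,
    sequences: Mapping[str, str] | ReferenceLookup,
    precedence: str = "mutation_first",
) -> dict[str, list[AlignedCdna]]:
    """Split mutation-at-start cDNAs by motif placement.

    "mutation_zone": a motif occurrence begins within the read and overlaps
    1-based positions 1-10 (offsets 0..9). "start": a motif occurrence
    covers the cDNA-start nucleotide (offset 0), typically extending
    upstream of the read. cDNAs qualifying for both go to whichever class
    ``precedence`` checks first; the rest are "neither".
    """
    if precedence not in ("start_first", "mutation_first"):
        raise ValueError(f"unknown precedence {precedence!r}")
    ref = sequences if isinstance(sequences, ReferenceLookup) else ReferenceLookup(sequences)
    k = motifs.k
    out: dict[str, list[AlignedCdna]] = {"start": [], "mutation_zone": [], "neither": []}
    for c in cdnas_first7:
        ext_lo = -k  # enough upstream context to see start-covering occurrences
        window = _window_in_orientation(ref, c, ext_lo, 9 + k - 1)
        start_hit = zone_hit = False
        if window is not None:
            for s, e in motif_occurrences(window, motifs.motifs):
                o_s, o_e = s + ext_lo, e - 1 + ext_lo  # inclusive offset span
                if o_s <= 0 <= o_e:
                    start_hit = True
                if 0 <= o_s <= 9:
                    zone_hit = True
        if precedence == "start_first":
            label = "start" if start_hit else ("mutation_zone" if zone_hit else "neither")
        else:
            label = "mutation_zone" if zone_hit else ("start" if start_hit else "neither")
        out[label].append(c)
    return out
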