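"""FDR crosslink-cluster calling and cDNA-start / cDNA-end peak assignment.

Clusters are called per region: cDNA-start counts are summed in a
symmetric +/- ``spacing`` window at each position carrying a start; the
null is the same number of starts repositioned uniformly within the
region, and the per-height empirical FDR is expected-over-observed counts
of positions reaching that height. FDR-passing start positions closer
than ``merge_gap`` are merged; the cluster spans the extremal retained
starts.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from truncmap.cdna_io import AlignedCdna, RegionAnnotation


@dataclass(frozen=True)
class Region:
    ref_id: str
    start: int
    end: int  # half-open
    strand: str = "+"
    name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CrosslinkCluster:
    ref_id: str
    start: int
    end: int  # half-open
    count: int
    peak: int
    peak_height: int
    fdr: float
    spacing: int
    strand: str = "+"
    flagged_short_region: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakCall:
    region_id: str
    peak: int | None
    count: int
    passed_median_filter: bool = True

    @property
    def empty(self) -> bool:
        return self.peak is None


def start_counts(cdnas: Iterable[AlignedCdna]) -> dict[tuple[str, str], Counter]:
    """(ref, strand) -> Counter of cDNA-start positions.

    Each record counts once: after UMI collapse, ``multiplicity`` is PCR
    bookkeeping, not an analysis weight.
    """
    out: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for c in cdnas:
        out[(c.ref_id, c.strand)][c.start] += 1
    return dict(out)


def end_counts(cdnas: Iterable[AlignedCdna]) -> dict[tuple[str, str], Counter]:
    out: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for c in cdnas:
        out[(c.ref_id, c.strand)][c.end] += 1
    return dict(out)


def regions_from_annotation(annotation: RegionAnnotation) -> list[Region]:
    return [
        Region(ref, lo, hi, "+", ref) for ref, lo, hi in annotation.gene_spans()
    ]


def _windowed(counts: np.ndarray, spacing: int) -> np.ndarray:
    kernel = np.ones(2 * spacing + 1)
    return np.convolve(counts, kernel, mode="same")


def _empirical_fdr(
    obs_heights: np.ndarray, perm_heights: np.ndarray, n_permutations: int
) -> dict[float, float]:
    """height -> FDR = mean permuted #positions >= h over observed #positions >= h."""
    fdr: dict[float, float] = {}
    obs_sorted = np.sort(obs_heights)
    perm_sorted = np.sort(perm_heights)
    for h in np.unique(obs_heights):
        obs_ge = obs_sorted.size - np.searchsorted(obs_sorted, h, side="left")
        null_ge = (perm_sorted.size - np.searchsorted(perm_sorted, h, side="left")) / n_permutations
        fdr[float(h)] = min(1.0, null_ge / obs_ge) if obs_ge else 1.0
    return fdr


def call_clusters(
    starts: Mapping[tuple[str, str], Counter] | Iterable[AlignedCdna],
    regions: Sequence[Region],
    spacing: int = 15,
    fdr_threshold: float = 0.05,
    merge_gap: int = 21,
    n_permutations: int = 100,
    seed: int = 0,
) -> list[CrosslinkCluster]:
    """Call FDR-significant crosslink clusters of cDNA-starts per region."""
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    if not isinstance(starts, Mapping):
        starts = start_counts(starts)
    rng = np.random.default_rng(seed)
    clusters: list[CrosslinkCluster] = []
    for region in regions:
        ctr = starts.get((region.ref_id, region.strand), Counter())
        positions = [p for p in ctr if region.start <= p < region.end]
        if not positions:
            continue
        flagged = region.length < 2 * spacing + 1
        counts = np.zeros(region.length, dtype=float)
        for p in positions:
            counts[p - region.start] = ctr[p]
        windowed = _windowed(counts, spacing)
        cand = np.array(sorted(p - region.start for p in positions))
        obs_heights = windowed[cand]

        total = int(counts.sum())
        perm_pos = rng.integers(0, region.length, size=(n_permutations, total))
        perm_height_chunks = []
        for perm in perm_pos:
            pc = np.bincount(perm, minlength=region.length).astype(float)
            pw = _windowed(pc, spacing)
            perm_height_chunks.append(pw[np.unique(perm)])
        fdr_by_height = _empirical_fdr(
            obs_heights, np.concatenate(perm_height_chunks), n_permutations
        )

        retained = cand[
            [fdr_by_height[float(h)] < fdr_threshold for h in obs_heights]
        ]
        if retained.size == 0:
            continue
        runs: list[list[int]] = [[int(retained[0])]]
        for p in retained[1:]:
            if p - runs[-1][-1] < merge_gap:
                runs[-1].append(int(p))
            else:
                runs.append([int(p)])
        for run in runs:
            lo, hi = run[0], run[-1] + 1
            span = counts[lo:hi]
            peak_local = _argmax_tiebreak(span, region.strand)
            peak = region.start + lo + peak_local
            clusters.append(
                CrosslinkCluster(
                    ref_id=region.ref_id,
                    start=region.start + lo,
                    end=region.start + hi,
                    count=int(span.sum()),
                    peak=peak,
                    peak_height=int(counts[lo + peak_local]),
                    fdr=fdr_by_height[float(windowed[lo + peak_local])],
                    spacing=spacing,
                    strand=region.strand,
                    flagged_short_region=flagged,
                )
            )
    return clusters


def _argmax_tiebreak(values: np.ndarray, strand: str) -> int:
    """Index of the maximum; ties go to the position closest to the
    region's 5' boundary (leftmost on +, rightmost on -)."""
    m = values.max()
    idx = np.nonzero(values == m)[0]
    return int(idx[0] if strand == "+" else idx[-1])


def find_peak(
    region: Region,
    positions: Mapping[int, int],
    tie_rule: str = "closest_to_region_start",
) -> PeakCall:
    """Position with the maximum count inside ``region``; ties resolved to
    the position nearest the region's 5' boundary."""
    if tie_rule != "closest_to_region_start":
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    inside = {p: n for p, n in positions.items() if region.start <= p < region.end}
    if not inside:
        return PeakCall(region.name or region.ref_id, None, 0, passed_median_filter=False)
    best_count = max(inside.values())
    candidates = sorted(p for p, n in inside.items() if n == best_count)
    peak = candidates[0] if region.strand == "+" else candidates[-1]
    return PeakCall(region.name or region.ref_id, peak, best_count)


def apply_median_filter(peaks: Sequence[PeakCall]) -> list[PeakCall]:
    """Mark peaks with count below the median of all peak counts as failed
    and return the passing subset."""
    if not peaks:
        raise ValueError("no peaks to filter")
    non_empty = [p for p in peaks if not p.empty]
    if not non_empty:
        return []
    med = float(np.median([p.count for p in non_empty]))
    passing = []
    for p in peaks:
        p.passed_median_filter = (not p.empty) and p.count >= med
        if p.passed_median_filter:
            passing.append(p)
    return passing


def select_top_clusters(
    clusters: Sequence[CrosslinkCluster], n: int = 1000, min_length: int = 31
) -> list[CrosslinkCluster]:
    """Clusters at least ``min_length`` nt long (">30 nt"), top ``n`` by
    total cDNA count, stable order among ties."""
    eligible = [c for c in clusters if c.length >= min_length]
    eligible.sort(key=lambda c: -c.count)
    return eligible[:n]


def junction_end_peak(
    cdnas: Iterable[AlignedCdna],
    annotation: RegionAnnotation,
    search_window: tuple[int, int] = (-20, 25),
    exon_min_length: int = 100,
    coverage_quantile: float = 0.5,
    stats: dict | None = None,
) -> list[tuple[tuple[str, int], PeakCall]]:
    """cDNA-end peak per exon-exon junction.

    Junctions are kept when their upstream exon is strictly longer than
    ``exon_min_length`` nt and its collapsed-cDNA coverage is at or above
    the ``coverage_quantile`` of eligible exons. The peak is the offset
    (relative to the junction) with the maximum end count inside
    ``search_window``; ties go to the most upstream offset.
    """
    cdnas = list(cdnas)
    ends = end_counts(cdnas)
    starts_by_ref: dict[str, Counter] = defaultdict(Counter)
    for c in cdnas:
        starts_by_ref[c.ref_id][c.start] += 1

    candidates: list[tuple[str, int, int, int]] = []  # ref, jpos, exon_lo, coverage
    for ref, jpositions in annotation.junctions.items():
        exons = sorted(annotation.exons.get(ref, []))
        for jpos in jpositions:
            up = [e for e in exons if e[1] == jpos]
            if not up:
                continue
            exon_lo, exon_hi = up[0]
            if exon_hi - exon_lo <= exon_min_length:
                continue
            cov = sum(
                n for p, n in starts_by_ref.get(ref, {}).items() if exon_lo <= p < exon_hi
            )
            candidates.append((ref, jpos, exon_lo, cov))

    if stats is not None:
        stats["n_candidate_junctions"] = len(candidates)
        stats["n_no_ends"] = 0
    if not candidates:
        return []
    cov_cut = float(np.quantile([c[3] for c in candidates], coverage_quantile))
    lo, hi = search_window
    out: list[tuple[tuple[str, int], PeakCall]] = []
    for ref, jpos, _exon_lo, cov in candidates:
        if cov < cov_cut:
            continue
        ctr = ends.get((ref, "+"), Counter())
        offset_counts = {
            p - jpos: n for p, n in ctr.items() if lo <= p - jpos <= hi
        }
        if not offset_counts:
            if stats is not None:
                stats["n_no_ends"] += 1
            continue
        call = find_peak(
            Region(ref, lo, hi + 1, "+", f"{ref}:{jpos}"), offset_counts
        )
        out.append(((ref, jpos), call))
    return out


def write_clusters_bed(clusters: Iterable[CrosslinkCluster], path: str | Path) -> None:
    """BED6+ with peak position and FDR in extra columns."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            fh.write(
                f"{c.ref_id}\t{c.start}\t{c.end}\tcluster{i}\t{c.count}\t{c.strand}"
                f"\t{c.peak}\t{c.fdr:.6g}\n"
            )
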