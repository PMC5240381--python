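"""Relationships between cDNA-starts and cDNA-ends.

Includes the non-coinciding-start offset matrix (start positions of one
length category cross-correlated against a reference category), the
cDNA-end-constraint log2 peak-to-flank ratio, length-stratified anchored
profiles, and start ECDFs around start peaks.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from truncmap.cdna_io import LENGTH_CATEGORIES, AlignedCdna, length_category
from truncmap.motifs import PositionalProfile


@dataclass
class OffsetMatrix:
    row_labels: list[str]
    offsets: np.ndarray
    matrix: np.ndarray  # rows normalized to 1 where non-empty
    reference_bin: str

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self.row_labels.index(label)]

    def modal_offset(self, label: str) -> int:
        r = self.row(label)
        return int(self.offsets[int(np.argmax(r))])

    def coinciding_mass(self, label: str) -> float:
        return float(self.row(label)[self.offsets == 0][0])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\t" + "\t".join(map(str, self.offsets)) + "\n")
            for label, row in zip(self.row_labels, self.matrix):
                fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class ConstraintScore:
    region_id: str
    value: float
    defined: bool


def _starts_by_category(
    cdnas: Iterable[AlignedCdna],
) -> dict[str, dict[tuple[str, str], Counter]]:
    out: dict[str, dict[tuple[str, str], Counter]] = defaultdict(
        lambda: defaultdict(Counter)
    )
    for c in cdnas:
        out[length_category(c)][(c.ref_id, c.strand)][c.start] += 1
    return out


def start_offset_matrix(
    cdnas: Iterable[AlignedCdna],
    reference_bin: str = ">39",
    comparison_bins: Sequence[str] | None = None,
    window: int = 40,
) -> OffsetMatrix:
    """Normalized co-occurrence of comparison-bin cDNA-starts at offsets
    from reference-bin starts.

    For each position p bearing reference-bin starts (count r_p), the
    comparison-bin start count at p + delta is accumulated with weight r_p;
    each row is normalized to sum to 1. delta is measured in transcript
    orientation.
    """
    if comparison_bins is None:
        comparison_bins = [b for b in LENGTH_CATEGORIES if b != reference_bin]
    by_cat = _starts_by_category(cdnas)
    ref_starts = by_cat.get(reference_bin, {})
    if not ref_starts:
        raise ValueError(f"no cDNAs in reference bin {reference_bin!r}")
    offsets = np.arange(-window, window + 1)
    matrix = np.zeros((len(comparison_bins), offsets.size))
    for i, cat in enumerate(comparison_bins):
        comp = by_cat.get(cat, {})
        for key, ref_ctr in ref_starts.items():
            comp_ctr = comp.get(key)
            if not comp_ctr:
                continue
            sign = 1 if key[1] == "+" else -1
            comp_pos = np.array(sorted(comp_ctr))
            comp_cnt = np.array([comp_ctr[q] for q in comp_pos], dtype=float)
            for p, r in ref_ctr.items():
                i0 = np.searchsorted(comp_pos, p - window)
                i1 = np.searchsorted(comp_pos, p + window, side="right")
                if i0 == i1:
                    continue
                d = sign * (comp_pos[i0:i1] - p)
                np.add.at(matrix[i], d + window, r * comp_cnt[i0:i1])
        s = matrix[i].sum()
        if s > 0:
            matrix[i] /= s
    return OffsetMatrix(list(comparison_bins), offsets, matrix, reference_bin)


def end_constraint_score(
    region_id: str,
    ends: Mapping[int, int],
    peak: int,
    flank: tuple[int, int] = (5, 25),
    strand: str = "+",
) -> ConstraintScore:
    """log2 of end count at ``peak`` over the mean end count across the
    downstream flank (zero-count flank positions included in the mean)."""
    sign = 1 if strand == "+" else -1
    flank_positions = [peak + sign * d for d in range(flank[0], flank[1] + 1)]
    flank_mean = float(np.mean([ends.get(p, 0) for p in flank_positions]))
    peak_count = ends.get(peak, 0)
    if flank_mean == 0 or peak_count == 0:
        return ConstraintScore(region_id, float("nan"), False)
    return ConstraintScore(region_id, float(np.log2(peak_count / flank_mean)), True)


def anchored_length_profiles(
    cdnas: Iterable[AlignedCdna],
    anchors: Sequence[tuple[str, int]],
    what: str = "starts",
    categories: Sequence[str] = LENGTH_CATEGORIES,
    window: tuple[int, int] = (-60, 60),
    strand: str = "+",
) -> dict[str, PositionalProfile]:
    """Per length category, counts of cDNA starts/ends at each offset from
    the anchors (transcript orientation)."""
    if what not in ("starts", "ends"):
        raise ValueError(f"unknown selector {what!r}")
    lo, hi = window
    sign = 1 if strand == "+" else -1
    anchor_by_ref: dict[str, list[int]] = defaultdict(list)
    for ref, pos in anchors:
        anchor_by_ref[ref].append(pos)
    values = {cat: np.zeros(hi - lo + 1) for cat in categories}
    denom = {cat: 0 for cat in categories}
    for c in cdnas:
        cat = length_category(c)
        if cat not in values:
            continue
        denom[cat] += 1
        pos = c.start if what == "starts" else c.end
        for a in anchor_by_ref.get(c.ref_id, ()):
            d = sign * (pos - a)
            if lo <= d <= hi:
                values[cat][d - lo] += 1
    return {
        cat: PositionalProfile(f"anchor_{what}", lo, hi, values[cat], denom[cat])
        for cat in categories
    }


@dataclass
class EcdfCurve:
    category: str
    grid: np.ndarray
    fractions: np.ndarray
    n: int


def start_ecdf(
    cdnas: Iterable[AlignedCdna],
    start_peaks: Sequence[tuple[str, int]],
    half_window: int = 25,
    categories: Sequence[str] = LENGTH_CATEGORIES,
) -> dict[str, EcdfCurve]:
    """Empirical cumulative distribution of start offsets within
    +/- ``half_window`` of the start peaks, one curve per length category."""
    peaks_by_ref: dict[str, list[int]] = defaultdict(list)
    for ref, pos in start_peaks:
        peaks_by_ref[ref].append(pos)
    offsets: dict[str, list[int]] = {cat: [] for cat in categories}
    for c in cdnas:
        cat = length_category(c)
        if cat not in offsets:
            continue
        sign = 1 if c.strand == "+" else -1
        for a in peaks_by_ref.get(c.ref_id, ()):
            d = sign * (c.start - a)
            if -half_window <= d <= half_window:
                offsets[cat].append(d)
    grid = np.arange(-half_window, half_window + 1)
    out = {}
    for cat in categories:
        vals = np.sort(np.array(offsets[cat]))
        if vals.size:
            fractions = np.searchsorted(vals, grid, side="right") / vals.size
        else:
            fractions = np.zeros_like(grid, dtype=float)
        out[cat] = EcdfCurve(cat, grid, fractions, int(vals.size))
    return out
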