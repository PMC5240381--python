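"""Metagene RNA maps, sequence summaries and motif heatmaps.

Two normalizations are implemented:

* junction maps: counts at each offset are scaled by
  (cDNAs[n] / sum(cDNAs)) * length(mRNAs) / count(junctions), so a
  uniformly distributed library converges to 1 at every offset;
* binding-site (Y-tract) maps: per-site counts are divided by the site's
  MaxCount (the maximum per-position count within the site +/- the search
  flank), averaged over sites, then divided by the average over a
  downstream flank.

Gaussian smoothing uses sigma = window / 2, truncated at 3 sigma, with
per-position kernel renormalization at the edges so that total mass is
preserved exactly.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from truncmap.cdna_io import AlignedCdna, ReferenceLookup, revcomp
from truncmap.motifs import MotifSet, motif_occurrences


def gaussian_smooth(values: np.ndarray, window: float) -> np.ndarray:
    """Mass-preserving Gaussian smoothing (sigma = window/2, 3-sigma kernel).

    Each input point spreads its mass over the in-range outputs only, so
    sum(out) == sum(in) to floating-point accuracy.
    """
    values = np.asarray(values, dtype=float)
    sigma = window / 2.0
    radius = int(np.ceil(3 * sigma))
    d = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (d / sigma) ** 2)
    kernel /= kernel.sum()
    n = values.size

    def conv(x: np.ndarray) -> np.ndarray:
        # centre slice of the full convolution: robust when the kernel is
        # longer than the signal (np.convolve 'same' is not)
        return np.convolve(x, kernel, mode="full")[radius : radius + n]

    weight_in_range = conv(np.ones(n))
    return conv(values / weight_in_range)


@dataclass
class RnaMap:
    anchor: str
    offsets: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    smoothing: str
    n_anchors: int
    flags: dict = field(default_factory=dict)

    def value_at(self, offset: int, smoothed: bool = False) -> float:
        arr = self.smoothed if smoothed else self.raw
        return float(arr[np.nonzero(self.offsets == offset)[0][0]])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# anchor={self.anchor} smoothing={self.smoothing} n_anchors={self.n_anchors}\n")
            fh.write("offset\traw\tsmoothed\n")
            for o, r, s in zip(self.offsets, self.raw, self.smoothed):
                fh.write(f"{o}\t{r:.10g}\t{s:.10g}\n")


@dataclass
class GroupedHeatmap:
    row_keys: list
    offsets: np.ndarray
    matrix: np.ndarray
    normalization: str
    flags: dict = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("row\t" + "\t".join(map(str, self.offsets)) + "\n")
            for key, row in zip(self.row_keys, self.matrix):
                fh.write(f"{key}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _position_counts(cdnas: Iterable[AlignedCdna], what: str) -> dict[str, Counter]:
    if what not in ("starts", "ends"):
        raise ValueError(f"unknown selector {what!r}")
    out: dict[str, Counter] = defaultdict(Counter)
    for c in cdnas:
        pos = c.start if what == "starts" else c.end
        out[c.ref_id][pos] += 1
    return out


def junction_map(
    cdnas: Iterable[AlignedCdna],
    junctions: Sequence[tuple[str, int]],
    mrna_lengths: Mapping[str, int],
    what: str = "starts",
    window: tuple[int, int] = (-50, 50),
    smooth: float = 5.0,
) -> RnaMap:
    """Junction-anchored density map with the uniform-expectation
    normalization: value[n] = (cDNAs[n]/sum(cDNAs)) * length(mRNAs) /
    count(junctions)."""
    cdnas = list(cdnas)
    refs = {ref for ref, _ in junctions}
    total = sum(1 for c in cdnas if c.ref_id in refs)
    if total == 0:
        raise ValueError("zero cDNAs on the junction-bearing mRNAs")
    if not junctions:
        raise ValueError("no junctions supplied")
    counts_by_ref = _position_counts((c for c in cdnas if c.ref_id in refs), what)
    lo, hi = window
    raw_counts = np.zeros(hi - lo + 1)
    for ref, jpos in junctions:
        ctr = counts_by_ref.get(ref)
        if not ctr:
            continue
        for p, n in ctr.items():
            d = p - jpos
            if lo <= d <= hi:
                raw_counts[d - lo] += n
    length_mrnas = sum(mrna_lengths[r] for r in sorted(refs))
    norm = (raw_counts / total) * length_mrnas / len(junctions)
    return RnaMap(
        anchor=f"junction_{what}",
        offsets=np.arange(lo, hi + 1),
        raw=norm,
        smoothed=gaussian_smooth(norm, smooth),
        smoothing=f"gaussian(window={smooth},sigma={smooth / 2})",
        n_anchors=len(junctions),
    )


def ytract_map(
    cdnas: Iterable[AlignedCdna],
    ytracts: Sequence[tuple[str, int, int]],
    what: str = "starts",
    search_flank: int = 120,
    norm_flank: tuple[int, int] = (50, 100),
    smooth: float = 10.0,
) -> RnaMap:
    """Binding-site map with MaxCount and downstream-flank normalization.

    Offsets are anchored at the tract 3' end (offset 0 = first nucleotide
    downstream of the tract); tract bodies occupy negative offsets.
    """
    counts_by_ref = _position_counts(cdnas, what)
    max_len = max((e - s for _, s, e in ytracts), default=0)
    lo = -(search_flank + max_len)
    hi = search_flank
    grid = np.arange(lo, hi + 1)
    acc = np.zeros(grid.size)
    cover = np.zeros(grid.size)
    n_excluded = 0
    n_used = 0
    for ref, s, e in ytracts:
        ctr = counts_by_ref.get(ref, Counter())
        span_lo, span_hi = s - search_flank, e + search_flank  # inclusive bounds
        site_counts = np.array(
            [ctr.get(p, 0) for p in range(span_lo, span_hi + 1)], dtype=float
        )
        max_count = site_counts.max()
        if max_count == 0:
            n_excluded += 1
            continue
        n_used += 1
        normalized = site_counts / max_count
        offs = np.arange(span_lo, span_hi + 1) - e
        sel = (offs >= lo) & (offs <= hi)
        acc[offs[sel] - lo] += normalized[sel]
        cover[offs[sel] - lo] += 1
    flags = {"n_excluded_maxcount0": n_excluded, "downstream_zero": False}
    with np.errstate(invalid="ignore", divide="ignore"):
        average = np.where(cover > 0, acc / np.maximum(cover, 1), 0.0)
    down_sel = (grid >= norm_flank[0]) & (grid <= norm_flank[1])
    downstream = float(average[down_sel].mean()) if down_sel.any() else 0.0
    if downstream == 0 or n_used == 0:
        flags["downstream_zero"] = True
        values = average
    else:
        values = average / downstream
    return RnaMap(
        anchor=f"ytract_end_{what}",
        offsets=grid,
        raw=values,
        smoothed=gaussian_smooth(values, smooth),
        smoothing=f"gaussian(window={smooth},sigma={smooth / 2})",
        n_anchors=n_used,
        flags=flags,
    )


def endpeak_grouped_heatmap(
    cdnas: Iterable[AlignedCdna],
    junction_peaks: Sequence[tuple[tuple[str, int], int]],
    what: str = "starts",
    window: tuple[int, int] = (-60, 30),
) -> GroupedHeatmap:
    """Rows = junctions grouped by cDNA-end-peak offset; cells = average
    counts per offset across the group's junctions, divided by the global
    maximum."""
    counts_by_ref = _position_counts(cdnas, what)
    lo, hi = window
    groups: dict[int, list[tuple[str, int]]] = defaultdict(list)
    for (ref, jpos), peak_offset in junction_peaks:
        groups[peak_offset].append((ref, jpos))
    row_keys = sorted(groups)
    matrix = np.zeros((len(row_keys), hi - lo + 1))
    for i, key in enumerate(row_keys):
        for ref, jpos in groups[key]:
            ctr = counts_by_ref.get(ref)
            if not ctr:
                continue
            for p, n in ctr.items():
                d = p - jpos
                if lo <= d <= hi:
                    matrix[i, d - lo] += n
        matrix[i] /= len(groups[key])
    gmax = matrix.max()
    if gmax > 0:
        matrix /= gmax
    return GroupedHeatmap(row_keys, np.arange(lo, hi + 1), matrix, "global_max")


def reachability_flags(
    junction_peaks: Sequence[tuple[tuple[str, int], int]],
    target_region: tuple[int, int] = (-24, -20),
    min_cdna: int = 17,
) -> dict[tuple[str, int], str]:
    """Can crosslinks in the target region be captured by >= ``min_cdna``-nt
    cDNAs ending at the junction's end peak?

    Returns per junction: "reachable", "unreachable" (end peak closer than
    ``min_cdna`` nt to the region's 3' edge) or "peak_upstream" (end peak
    upstream of the region).
    """
    region_lo, region_hi = target_region
    out: dict[tuple[str, int], str] = {}
    for junction, peak_offset in junction_peaks:
        if peak_offset < region_lo:
            out[junction] = "peak_upstream"
        elif peak_offset - region_hi < min_cdna:
            out[junction] = "unreachable"
        else:
            out[junction] = "reachable"
    return out


def end_nucleotide_composition(
    cdnas: Iterable[AlignedCdna],
    sequences: Mapping[str, str] | ReferenceLookup,
    window: tuple[int, int] = (-10, 10),
    stats: dict | None = None,
):
    """Base fractions at each offset from the cDNA-end (transcript
    orientation); edge-truncated windows skipped and counted."""
    import pandas as pd

    ref = sequences if isinstance(sequences, ReferenceLookup) else ReferenceLookup(sequences)
    lo, hi = window
    counts = {b: np.zeros(hi - lo + 1) for b in "ACGT"}
    n_used = 0
    n_skipped = 0
    for c in cdnas:
        if c.strand == "+":
            a, b = c.end + lo, c.end + hi
            if a < 0 or b >= ref.length(c.ref_id):
                n_skipped += 1
                continue
            seq = ref.fetch(c.ref_id, a, b + 1)
        else:
            a, b = c.end - hi, c.end - lo
            if a < 0 or b >= ref.length(c.ref_id):
                n_skipped += 1
                continue
            seq = revcomp(ref.fetch(c.ref_id, a, b + 1))
        n_used += 1
        for i, base in enumerate(seq):
            if base in counts:
                counts[base][i] += 1
    if stats is not None:
        stats["n_skipped"] = n_skipped
        stats["n_used"] = n_used
    frame = pd.DataFrame(counts, index=np.arange(lo, hi + 1))
    totals = frame.sum(axis=1)
    return frame.div(totals.where(totals > 0, 1), axis=0)


def intron_end_fraction(
    cdnas: Iterable[AlignedCdna],
    introns: Mapping[str, Sequence[tuple[int, int]]],
) -> float:
    """Among cDNAs ending inside an intron, the fraction ending at the last
    or second-to-last intronic nucleotide. NaN when no cDNA ends in an
    intron."""
    n_intronic = 0
    n_terminal = 0
    for c in cdnas:
        for s, e in introns.get(c.ref_id, ()):
            if s <= c.end < e:
                n_intronic += 1
                if c.end >= e - 2:
                    n_terminal += 1
                break
    if n_intronic == 0:
        return float("nan")
    return n_terminal / n_intronic


def discover_pentamers(
    peaks: Sequence[tuple[str, int]],
    sequences: Mapping[str, str] | ReferenceLookup,
    region: tuple[int, int] = (-10, 10),
    k: int = 5,
    z_threshold: float = 5.0,
    n_shuffles: int = 100,
    seed: int = 0,
):
    """k-mers enriched around peaks versus mononucleotide-shuffled windows.

    z = (observed - mean_shuffled) / sd_shuffled per k-mer; rows with
    sd = 0 get z = inf (observed above background) and are flagged.
    Returns a DataFrame sorted by z, with a ``passed`` column for
    z > ``z_threshold``.
    """
    import pandas as pd

    ref = sequences if isinstance(sequences, ReferenceLookup) else ReferenceLookup(sequences)
    rng = np.random.default_rng(seed)
    lo, hi = region
    windows: list[str] = []
    for r, pos in peaks:
        a, b = pos + lo, pos + hi
        if a < 0 or b >= ref.length(r):
            continue
        windows.append(ref.fetch(r, a, b + 1))

    def count_kmers(seqs: list[str]) -> Counter:
        ctr: Counter = Counter()
        for s in seqs:
            for i in range(len(s) - k + 1):
                ctr[s[i : i + k]] += 1
        return ctr

    observed = count_kmers(windows)
    all_kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    bg = np.zeros((n_shuffles, len(all_kmers)))
    idx = {m: i for i, m in enumerate(all_kmers)}
    arrays = [np.array(list(w)) for w in windows]
    for s in range(n_shuffles):
        shuffled = ["".join(rng.permutation(a)) for a in arrays]
        for m, n in count_kmers(shuffled).items():
            bg[s, idx[m]] = n
    mean_bg = bg.mean(axis=0)
    sd_bg = bg.std(axis=0, ddof=1) if n_shuffles > 1 else np.zeros(len(all_kmers))
    rows = []
    for m in all_kmers:
        obs = observed.get(m, 0)
        mu, sd = mean_bg[idx[m]], sd_bg[idx[m]]
        if sd > 0:
            z = (obs - mu) / sd
            inf_flag = False
        else:
            z = np.inf if obs > mu else (-np.inf if obs < mu else 0.0)
            inf_flag = True
        rows.append((m, obs, mu, sd, z, inf_flag))
    frame = pd.DataFrame(
        rows, columns=["kmer", "observed", "mean_bg", "sd_bg", "z", "sd_zero"]
    )
    frame["passed"] = (frame["z"] > z_threshold) & ~frame["sd_zero"]
    frame = frame.sort_values(
        ["sd_zero", "z", "observed"], ascending=[True, False, False], kind="stable"
    )
    return frame.reset_index(drop=True)


def cluster_motif_heatmap(
    clusters: Sequence,
    motif_set: MotifSet,
    sequences: Mapping[str, str] | ReferenceLookup,
    row_size: int = 300,
    flank: int = 20,
) -> GroupedHeatmap:
    """Average per-nucleotide motif coverage for clusters chunked into rows
    of ``row_size`` after sorting by length.

    Each row uses a length-anchored coordinate: offsets up to half the
    row's median length are anchored at cluster starts, the rest at cluster
    ends (offset m maps to the nucleotide following the median end).
    """
    ref = sequences if isinstance(sequences, ReferenceLookup) else ReferenceLookup(sequences)
    ordered = sorted(clusters, key=lambda c: c.length)
    flags = {"single_row": len(ordered) < row_size}
    chunks = [ordered[i : i + row_size] for i in range(0, len(ordered), row_size)] or [[]]
    max_median = 0
    medians = []
    for chunk in chunks:
        m = int(np.median([c.length for c in chunk])) if chunk else 0
        medians.append(m)
        max_median = max(max_median, m)
    grid = np.arange(-flank, max_median + flank + 1)
    matrix = np.zeros((len(chunks), grid.size))
    row_keys = []
    for i, (chunk, m) in enumerate(zip(chunks, medians)):
        row_keys.append(f"median_len={m}")
        if not chunk:
            continue
        boundary = m // 2
        for c in chunk:
            cov = _cluster_coverage(ref, c, motif_set, flank)
            for gi, o in enumerate(grid):
                if o > m + flank:
                    continue
                if o <= boundary:
                    p = c.start + o
                else:
                    p = c.end + (o - m)  # end-anchored (c.end is half-open)
                local = p - (c.start - flank)
                if 0 <= local < cov.size:
                    matrix[i, gi] += cov[local]
        matrix[i] /= len(chunk)
    return GroupedHeatmap(row_keys, grid, matrix, "row_average", flags)


def _cluster_coverage(ref: ReferenceLookup, cluster, motif_set: MotifSet, flank: int) -> np.ndarray:
    lo = max(0, cluster.start - flank)
    hi = min(ref.length(cluster.ref_id), cluster.end + flank)
    seq = ref.fetch(cluster.ref_id, lo, hi)
    cov = np.zeros(hi - lo)
    for s, e in motif_occurrences(seq, motif_set.motifs):
        cov[s:e] = 1.0
    if lo != cluster.start - flank:  # left-pad when clipped at the reference edge
        pad = (cluster.start - flank) - lo
        cov = np.concatenate([np.zeros(-pad), cov]) if pad < 0 else cov
    return cov
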