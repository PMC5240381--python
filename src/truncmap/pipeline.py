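"""End-to-end pipeline: simulate -> load -> motifs -> clusters -> geometry
-> maps -> QC report, driven by a single YAML-able config with one global
seed fanned out deterministically to the stages."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from truncmap import cdna_io, clusters as cl, geometry, motifs as mo, rnamaps, simulate

logger = logging.getLogger("truncmap")

_KNOWN_KEYS = {
    "seed",
    "input",
    "simulate",
    "collapse_umis",
    "max_length_exclusive",
    "motifs",
    "clusters",
    "geometry",
    "maps",
}


@dataclass
class RunConfig:
    seed: int = 0
    input: dict[str, Any] | None = None  # {"path":..., "format":..., "fasta":...}
    simulate: dict[str, Any] | None = None  # SimConfig fields
    collapse_umis: bool = True
    max_length_exclusive: int = 40
    motifs: dict[str, Any] = field(default_factory=dict)
    clusters: dict[str, Any] = field(
        default_factory=lambda: {
            "spacing": 15,
            "fdr_threshold": 0.05,
            "merge_gap": 21,
            "n_permutations": 100,
        }
    )
    geometry: dict[str, Any] = field(default_factory=dict)
    maps: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class QcReport:
    library_size_pre_collapse: int
    library_size_post_collapse: int
    length_histogram: dict[int, int]
    fraction_shorter_40: float
    deletion_rate: float
    transition_rate: float
    median_end_constraint: float | None
    coinciding_start_mass: float | None
    intron_end_fraction: float | None

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, float) and np.isnan(val):
                d[key] = None
        return d


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n)]


def qc_report(
    raw_count: int,
    collapsed: list[cdna_io.AlignedCdna],
    constraint_scores: list[geometry.ConstraintScore] | None = None,
    offset_matrix: geometry.OffsetMatrix | None = None,
    intron_fraction: float | None = None,
) -> QcReport:
    n = len(collapsed)
    hist: dict[int, int] = {}
    for c in collapsed:
        hist[c.length] = hist.get(c.length, 0) + 1
    frac40 = sum(v for k, v in hist.items() if k < 40) / n if n else 0.0
    del_rate = sum(1 for c in collapsed if c.deletions) / n if n else 0.0
    tr_rate = sum(1 for c in collapsed if c.transitions) / n if n else 0.0
    med = None
    if constraint_scores:
        defined = [s.value for s in constraint_scores if s.defined]
        med = float(np.median(defined)) if defined else None
    mass = None
    if offset_matrix is not None and offset_matrix.row_labels:
        mass = float(
            np.mean([offset_matrix.coinciding_mass(l) for l in offset_matrix.row_labels])
        )
    return QcReport(
        library_size_pre_collapse=raw_count,
        library_size_post_collapse=n,
        length_histogram=dict(sorted(hist.items())),
        fraction_shorter_40=frac40,
        deletion_rate=del_rate,
        transition_rate=tr_rate,
        median_end_constraint=med,
        coinciding_start_mass=mass,
        intron_end_fraction=intron_fraction,
    )


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run all stages, writing TSV/BED/JSON artifacts plus the resolved
    config; deterministic under a fixed seed. A stage failure raises with
    the stage name attached."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    seeds = _spawn_seeds(config.seed, 4)
    stage = "config"
    try:
        with open(outdir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        stage = "simulate/load"
        if config.simulate is not None:
            sim_cfg = simulate.SimConfig(**{"seed": seeds[0], **config.simulate})
            sequences, annotation = simulate.simulate_transcriptome(sim_cfg)
            reads, truth = simulate.simulate_reads(sequences, annotation, sim_cfg)
            simulate.write_outputs(sequences, annotation, reads, truth, outdir / "sim")
            logger.info(
                "simulated %d reads (%d molecules, %d dropped short, %d no cut)",
                len(reads), truth.n_molecules, truth.n_dropped_short, truth.n_dropped_no_cut,
            )
        elif config.input is not None:
            sequences = cdna_io.read_fasta(config.input["fasta"])
            reads = cdna_io.load_alignments(
                config.input["path"],
                format=config.input.get("format", "tsv"),
                reference=sequences,
            )
            annotation = cdna_io.RegionAnnotation(
                transcript_lengths={r: len(s) for r, s in sequences.items()}
            )
        else:
            raise ValueError("config needs either 'simulate' or 'input'")

        raw_count = len(reads)
        collapsed = cdna_io.collapse_umis(reads) if config.collapse_umis else list(reads)
        cdna_io.write_tsv(collapsed, outdir / "collapsed.tsv")
        short = cdna_io.filter_short(collapsed, config.max_length_exclusive)

        stage = "motifs"
        motif_set = mo.define_cl_motifs(short, sequences, **config.motifs)
        motif_set.write(outdir / "cl_motifs.txt")
        if motif_set.motifs:
            prof = mo.motif_coverage_profile(short, motif_set, sequences)
            prof.write_tsv(outdir / "motif_coverage.tsv")
        mo.mutation_density_profile(short, "deletion").write_tsv(
            outdir / "deletion_profile.tsv"
        )
        mo.mutation_density_profile(short, "transition").write_tsv(
            outdir / "transition_profile.tsv"
        )

        stage = "clusters"
        regions = cl.regions_from_annotation(annotation)
        called = cl.call_clusters(
            collapsed, regions, seed=seeds[1], **config.clusters
        )
        cl.write_clusters_bed(called, outdir / "clusters.bed")
        counter = cl.start_counts(collapsed)
        peaks = [
            cl.find_peak(
                cl.Region(c.ref_id, c.start, c.end, c.strand, f"cluster{i}"),
                counter.get((c.ref_id, c.strand), {}),
            )
            for i, c in enumerate(called)
        ]
        passing = cl.apply_median_filter(peaks) if peaks else []
        with open(outdir / "peaks.tsv", "w") as fh:
            fh.write("region\tpeak\tcount\tpassed_median_filter\n")
            for p in peaks:
                fh.write(f"{p.region_id}\t{p.peak}\t{p.count}\t{int(p.passed_median_filter)}\n")

        stage = "geometry"
        matrix = None
        scores: list[geometry.ConstraintScore] = []
        try:
            matrix = geometry.start_offset_matrix(collapsed, **config.geometry)
            matrix.write_tsv(outdir / "offset_matrix.tsv")
        except ValueError as exc:
            logger.info("offset matrix skipped: %s", exc)
        ends = cl.end_counts(collapsed)
        for c, p in zip(called, peaks):
            if p.empty:
                continue
            end_region = cl.Region(c.ref_id, c.start, c.end + 30, c.strand)
            end_peak = cl.find_peak(end_region, ends.get((c.ref_id, c.strand), {}))
            if not end_peak.empty:
                scores.append(
                    geometry.end_constraint_score(
                        p.region_id, ends.get((c.ref_id, c.strand), {}), end_peak.peak
                    )
                )
        with open(outdir / "end_constraint.tsv", "w") as fh:
            fh.write("region\tlog2_ratio\tdefined\n")
            for s in scores:
                fh.write(f"{s.region_id}\t{s.value:.6g}\t{int(s.defined)}\n")

        stage = "maps"
        junctions = annotation.internal_junctions()
        intron_fraction = None
        if junctions:
            jmap = rnamaps.junction_map(
                collapsed, junctions, annotation.transcript_lengths,
                **config.maps.get("junction", {}),
            )
            jmap.write_tsv(outdir / "junction_map.tsv")
        if annotation.ytracts:
            ymap = rnamaps.ytract_map(collapsed, annotation.ytracts)
            ymap.write_tsv(outdir / "ytract_map.tsv")
        comp = rnamaps.end_nucleotide_composition(collapsed, sequences)
        comp.to_csv(outdir / "end_composition.tsv", sep="\t")
        if annotation.introns:
            intron_fraction = rnamaps.intron_end_fraction(collapsed, annotation.introns)

        stage = "qc"
        report = qc_report(raw_count, collapsed, scores, matrix, intron_fraction)
        with open(outdir / "qc.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
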