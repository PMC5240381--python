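# truncmap

Computational analyses for truncation-based CLIP data (iCLIP, eCLIP,
irCLIP): crosslink-site assignment from cDNA-starts, crosslink-associated
(CL) motif and mutation profiling, FDR permutation calling of crosslink
clusters, cDNA-start/end peak assignment, cDNA-end-constraint diagnostics,
and metagene RNA maps around exon-exon junctions and pyrimidine tracts —
plus a synthetic read generator with per-read ground truth (truncated vs
readthrough cDNAs, constrained vs unconstrained RNase cleavage, 4SU
T-to-C transitions, UMI/PCR duplication) so that every stage is testable
without external data.

## Layout

| module | role |
| --- | --- |
| `truncmap.simulate` | synthetic transcriptomes, binding sites and iCLIP-like reads with ground truth |
| `truncmap.cdna_io` | BAM/TSV loading, deletion/transition offset extraction, UMI collapse, length filters |
| `truncmap.motifs` | CL-motif definition (1.5-fold, −1 vs −10 rule), coverage and mutation-density profiles, cDNA classification |
| `truncmap.clusters` | FDR crosslink-cluster calling (±15 nt window, shuffled null, merge < 21 nt), peak finding, median filter, junction end peaks |
| `truncmap.geometry` | non-coinciding-start offset matrices, end-constraint log2 scores, anchored length profiles, start ECDFs |
| `truncmap.rnamaps` | junction/Y-tract RNA maps with the printed normalizations, grouped heatmaps, end-nucleotide composition, pentamer discovery |
| `truncmap.pipeline` / `truncmap.cli` | YAML-configured end-to-end runs and the `truncmap` command |

Coordinates are 0-based and transcript-oriented throughout: the cDNA-start
is the first transcribed nucleotide, the cDNA-end the last (inclusive),
and the crosslink site of a truncated cDNA is `start − 1`. cDNAs shorter
than 17 nt are never emitted; analyses of mutation profiles use cDNAs
shorter than 40 nt.

## CLI

```sh
truncmap simulate --seed 1 --n-molecules 10000 --out simdir
truncmap load simdir/reads.tsv --out collapsed.tsv
truncmap motifs define --reads collapsed.tsv --fasta simdir/transcripts.fa --out motifs.txt
truncmap clusters call --reads collapsed.tsv --fasta simdir/transcripts.fa --out clusters.bed
truncmap run --config run.yaml --out outdir
```

A minimal `run.yaml`:

```yaml
seed: 1
simulate:
  n_transcripts: 4
  n_molecules: 5000
  n_exons: 4
  site_model:
    - {kind: ytract, length: 30, count: 2}
```

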