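# cifi

Toolkit for long-read chromatin-conformation-capture (3C) concatemer data.
A single long read carries many ligated restriction fragments (monomers);
this package splits such reads at restriction sites, expands each read's
monomers into all pairwise contacts, builds balanced contact matrices, and
computes the standard QC and domain-structure comparisons — plus a
simulator that generates genomes and concatemer reads with known contact
structure so the entire pipeline is testable offline.

## Modules

| module            | purpose |
|-------------------|---------|
| `cifi.restriction`| enzyme definitions (DpnII, HindIII, NlaIII, custom IUPAC), genome fragment maps, in-silico read digestion, segment statistics |
| `cifi.contacts`   | alignment ingestion (BAM or oracle TSV), one-placement-per-segment selection, C(n,2) pairwise expansion, duplicate flagging, 4DN `.pairs` I/O |
| `cifi.matrix`     | binning into sparse symmetric matrices, Knight–Ruiz balancing (Sinkhorn fallback), triplet dump, coarsening, log1p Pearson correlation |
| `cifi.qc`         | distance-decay profiles with slope fitting, MAPQ-stratified mapping rates per annotation class, sliding-window coverage comparison |
| `cifi.tads`       | window-signal domain calling and Measure of Concordance between partitions |
| `cifi.simulate`   | seeded genomes (optional planted duplication), concatemer reads with power-law cis decay, trans fraction, planted domain blocks, PCR-duplicate injection; emits truth tables and perfect oracle alignments |
| `cifi.cli`        | `cifi` command-line entry point and the end-to-end pipeline with a run manifest |

## CLI

```sh
# simulate a dataset (genome, reads, truth, oracle alignments)
cifi simulate --config sim.toml --out-dir sim/

# full pipeline: digest -> ingest -> pairs -> matrices -> QC (-> TADs)
cifi run --config run.toml --out-dir out/

# individual stages
cifi digest --enzyme DpnII --min-seg-len 20 --reads reads.fq.gz --out-prefix X
cifi pairs --oracle sim/oracle_alignments.tsv --chromsizes sim/genome.chrom.sizes \
           --mapq-min 1 --out run.pairs
cifi matrix --pairs run.pairs --res 50000,2500000 --balance kr --out-prefix mat
cifi dump --matrix mat.50000.tsv --region chr1
cifi qc decay --pairs run.pairs --out decay.tsv
cifi qc mapq --oracle sim/oracle_alignments.tsv --bed alu=alu.bed --out mapq.tsv
cifi qc coverage --oracle sim/oracle_alignments.tsv --chromsizes g.sizes --out cov.bg
cifi tads --matrix mat.50000.tsv --chrom chr1 --w 5 --out-bed domains.bed
cifi moc --a a.bed --b b.bed --chromsizes g.sizes --res 50000 --chroms chr1,chr2
```

A minimal `run.toml`:

```toml
reads = "sim/reads.fastq"
chromsizes = "sim/genome.chrom.sizes"
oracle = "sim/oracle_alignments.tsv"   # or: bam = "segments.bam"
enzyme = "DpnII"
mapq_min = 1
resolutions = [50000, 2500000]
balance = true
[tads]
chroms = ["chr1"]
w = 5
```

Segment FASTQ records are named `{read_id}:{ordinal}:{read_start}:{read_end}`,
which is the contract the BAM ingestion path expects after alignment.

## Conventions

Coordinates are 0-based half-open internally; `.pairs`, BED and bedGraph
outputs follow their formats' conventions (1-based for pairs positions).
All randomness flows through explicit seeds; identical config + seed gives
byte-identical outputs.
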