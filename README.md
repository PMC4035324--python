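# tagdge — tag-based digital gene expression analysis

`tagdge` implements the classic restriction-anchored tag (SAGE-like) digital
gene expression workflow used to profile transcription across mushroom
fruiting-body development, where four successive stipe stages — button (BU),
egg (EG), elongation (EL) and maturation (MA) — are compared by counting
3′ cDNA tags. It is written for transcriptomics researchers and method
developers who need a tested, reproducible reimplementation of that
pipeline: from raw 21-mer tag reads to differential-expression calls,
stage-set accounting and qPCR cross-checks, with a synthetic-data generator
so every step can be validated against known ground truth.

## The method

Each mRNA is represented by its **canonical tag**: the anchoring enzyme
(NlaIII) cuts at every `CATG`, the tagging enzyme (MmeI) cuts 17 bp
downstream, and because the library is oligo-dT primed, the sequenced tag is
the 21-mer (`CATG` + 17 bp) at the 3′-most eligible `CATG` of the
transcript. The pipeline:

1. **Reference construction** — extract each gene's canonical tag from a
   FASTA catalog; tags shared verbatim by several genes are *ambiguous* and
   excluded from counting.
2. **Cleaning** — drop adaptor-only reads, wrong-length reads, low-quality
   reads (any N, or any base below Phred 10), then remove tags seen exactly
   once in the library; the survivors are *clean tags*.
3. **Quantification** — assign each clean tag with best-hit semantics:
   exact match to a unique reference tag, else a unique gene at Hamming
   distance 1 over the 17-bp variable region (the anchor must match
   exactly); anything matching several genes is excluded. Expression is
   normalized to transcripts per million clean tags:
   `TPM = count × 10⁶ / N`.
4. **DEG screen** — for each successive transition (T1: BU→EG, T2: EG→EL,
   T3: EL→MA) every gene detected in at least one of the two stages is
   tested with the exact two-library count test (Audic–Claverie): given
   `x` tags in a library of `N1`,

   `P(y|x) = (N2/N1)^y · (x+y)! / (x!·y!·(1+N2/N1)^(x+y+1))`,

   with a two-sided p-value of twice the smallest tail over both library
   orientations (capped at 1, hence exactly symmetric in the libraries).
   Benjamini–Hochberg adjustment is applied per transition, and a gene is a
   DEG when **FDR ≤ 0.001 and |log2 fold change| ≥ 1** (TPM scale). DEGs
   fall in half-open fold classes 2–4×, 4–8×, ≥8×, or *on/off* when
   detected in exactly one of the two stages.
5. **Stage sets** — expressed-gene sets per stage (count ≥ 1), the 15-region
   4-way Venn partition, and percentages of the genome and of all expressed
   genes.
6. **Category report** — up/down DEG tallies per functional category from a
   user-supplied gene→category table (COG letters, pathway subgroups, …).
7. **qPCR verification** — 2^−ΔΔCt relative quantification against a
   reference gene and calibrator stage.

A synthetic-data module generates gene catalogs, four-stage expression
truths with designed fold-change classes and on/off genes, and
error-bearing tag libraries, so the whole pipeline is testable end to end
without any downloads.

## Worked example

```python
from tagdge import (SimulationConfig, generate_catalog, generate_truth,
                    simulate_library, TagIndex, clean_reads, map_tags, DGEModel)

cfg = SimulationConfig(n_genes=2000, library_sizes=(500_000,)*4,
                       error_rate=0.01, seed=7)
catalog = generate_catalog(cfg)
truth = generate_truth(cfg, catalog)
index = TagIndex.build(catalog)

profiles = []
for i, stage in enumerate(cfg.stages):
    reads = simulate_library(catalog, truth, stage, cfg.library_sizes[i],
                             cfg.error_rate, seed=100 + i)
    table, stats = clean_reads(reads)
    profiles.append(map_tags(table, index, gene_universe=index.gene_ids))

model = DGEModel.from_profiles(profiles, genome_size=len(catalog))
results = model.fit()          # FDR <= 0.001, |log2FC| >= 1
print(results.summary())
```

This prints:

```
Tag DGE screen
============================================================
genes in catalog: 2000; stages: BU, EG, EL, MA
clean tags/library: BU=457,094, EG=458,638, EL=458,863, MA=460,464
thresholds: FDR <= 0.001, |log2FC| >= 1, expressed = count >= 1
expressed in >=1 stage: 1934 (96.7% of genome); in all four: 1719 (86.0% of genome, 88.9% of expressed)
------------------------------------------------------------
transition     DEGs     up   down   on  off     %up
T1 BU>EG        205    120     85   24   34    58.5
T2 EG>EL        181    117     64   30   23    64.6
T3 EL>MA        189    110     79   25   34    58.2
```

Reading the output: each library retained ~92% of its 500,000 simulated
tags after cleaning (the losses are mostly singleton tags created by the 1%
per-base sequencing error). Nearly all genes are detected at this depth,
~89% of expressed genes are expressed in all four stages, and each
transition yields roughly the DEG count implied by the simulation design
(~9% of genes differential per transition plus stage-specific on/off
genes), split by direction, with on/off genes also tallied separately.

The same analysis is scriptable from the shell (`tagdge simulate`,
`tagdge build-ref`, `tagdge clean`, `tagdge quantify`, `tagdge saturation`,
`tagdge venn`, `tagdge deg`, `tagdge categories`, `tagdge qpcr`,
`tagdge run-all`); `tagdge run-all --config run.json` executes the whole
pipeline and writes every table plus a reproducible run manifest.

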