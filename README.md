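# coexmotif

An integrative pipeline for bacterial gene regulation analysis: CLR
mutual-information co-expression networks, FIMO-style promoter motif scanning
with exact p-values, motif-library deduplication via consensus similarity and
Markov clustering, and Fisher/FDR motif enrichment in transcription-factor
network neighborhoods tested against two permutation nulls.

A first-class synthetic-data module generates every input with known
regulatory structure (TF-driven expression modules, promoters with planted
PSSM instances, redundant motif libraries, module-linked GO-like labels) and
a ground-truth ledger, so every stage is testable without external data.

## Modules

| module        | purpose |
|---------------|---------|
| `synthetic`   | expression / genome / motif / annotation generators + ground truth |
| `expression`  | expression TSV I/O, complete-sample subsetting, gene filtering |
| `inference`   | plug-in mutual information (quantile bins, bits), CLR z-scores, thresholded networks |
| `netanalysis` | degree/betweenness centrality, neighborhoods, MCL, cluster graphs, label-shuffled nulls, GML |
| `meme`        | position probability matrices, MEME minimal format I/O |
| `scan`        | GFF3-based promoter extraction, PSSM scanning with exact convolution p-values and per-motif BH q-values |
| `motiflib`    | IUPAC consensus, ungapped similarity network, central-motif selection |
| `enrich`      | exact Fisher tests, BH FDR, neighborhood enrichment, random-gene-list and shuffled-network nulls, parameter sweep |
| `pipeline`    | resumable nine-stage orchestration with a deterministic manifest |

## CLI

```bash
# full synthetic pipeline into ./out (resumable; rerun skips current stages)
coexmotif run-all --outdir out --seed 1

# individual stages operate purely on files
coexmotif simulate --outdir out --seed 1
coexmotif infer-network --expression out/expression.tsv --out out/edges.tsv --store-min 3
coexmotif extract-promoters --genome out/genome.fasta --gff out/genes.gff3 --out out/prom.tsv
coexmotif scan --promoters out/prom.tsv --motifs out/motifs.meme --out out/hits.tsv
coexmotif dedup-motifs --motifs out/motifs.meme --out-clusters out/clusters.tsv --out-central out/central.meme
coexmotif centrality --edges out/edges.tsv --tau 4 --out out/centrality.tsv
coexmotif cluster --edges out/edges.tsv --tau 4 --out out/gene_clusters.tsv
coexmotif enrich --edges out/edges.tsv --tau 4 --hits out/hits.tsv \
    --categories out/categories.tsv --out out/enrichment.tsv
coexmotif coverage --hits out/hits.tsv --out out/coverage.tsv
```

`run-all` accepts a YAML config (`--config`) mirroring
`coexmotif.pipeline.PipelineConfig`; all randomness flows through named
seeds, and a rerun with the same config produces byte-identical TSVs and
manifest.

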