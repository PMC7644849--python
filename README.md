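# cisreg

Promoter regulatory-element mapping and assay quantification, exercised
entirely on synthetic fixtures with known ground truth.

The pipeline extracts the 10 kb immediately upstream of each gene's start
codon, scans it base-pair by base-pair on both strands against JASPAR-format
position weight matrices, keeps sites whose min–max-normalised ("percent
match") score exceeds 0.89, filters them by chromatin state (presence of
H3K4me3/H3K36me3/H3K27ac and absence of H3K27me3 near the site) and by TF
ChIP-seq cluster evidence (score ≥ 500 of 1000), and compares the surviving
per-gene TF sets across promoters as a Venn partition. A separate
quantification module implements comparative-Ct (ΔΔCt) relative expression,
expression–morphology correlation, dual-luciferase fold changes, and
tubular/spherical cell categorisation from particle-length tables.

## Layout

| module | what it does |
| --- | --- |
| `cisreg.motif_model` | JASPAR PFM parsing/writing, log-odds PWMs, relative score, consensus, binding efficiency |
| `cisreg.promoter_scan` | strand-aware promoter extraction, dual-strand scanning, genomic coordinate mapping, hit TSV/BED I/O |
| `cisreg.chromatin_filter` | histone-mark activity filter and ChIP-seq evidence filter over BED tracks |
| `cisreg.promoter_compare` | per-gene TF sets, 2–3-way Venn partitions, gene lookup by TF |
| `cisreg.quantification` | ΔΔCt expression, Pearson profile correlation, luciferase folds, morphology calls |
| `cisreg.synthetic_data` | ground-truth generators: planted-motif promoters + tracks, reporter-construct pair, Ct/luminescence tables |
| `cisreg.pipeline` / `cisreg.cli` | orchestration, report bundles, and the `cisreg` command line |

## CLI

```sh
# generate the packaged three-promoter comparison fixture
cisreg simulate --out fixture/ --seed 42

# full run: scan -> chromatin/evidence filters -> shared-TF partition
cisreg pipeline \
    --genome fixture/genome.fa --anchors fixture/anchors.tsv \
    --motifs fixture/motifs.jaspar --histone fixture/histone.bed \
    --clusters fixture/clusters.bed --out report/

# individual stages
cisreg scan --genome ... --anchors ... --motifs ... --out hits.tsv
cisreg filter --hits hits.tsv --histone ... --clusters ... --out flagged.tsv
cisreg compare --hits surviving.tsv --out venn.json

# quantification utilities
cisreg qpcr --ct-table ct.tsv --out out/
cisreg luciferase --plate plate.tsv --out out/
cisreg morphology --particles cells.tsv --out out/
```

`cisreg pipeline` writes `hits.tsv`, `surviving.tsv`, `tf_sets.json`,
`venn.json`, `venn_counts.tsv`, a `run_log.json` with per-stage counts and
the serialized configuration, and a `manifest.json`. Reruns with the same
inputs are byte-identical.

Input formats: FASTA genome; anchors as 4-column TSV
(`gene_id  chrom  strand  start_codon_pos`, 0-based) or BED6; histone and
cluster tracks as BED (4th column label, 5th score); Ct tables as TSV with
columns `gene  time_h  replicate  ct`; luminescence plates as TSV with
`construct  treatment  replicate  fluc1  fluc2  fluc3  rluc`; morphology as
TSV with `cell_id  condition  particle_lengths` (comma-separated µm).

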