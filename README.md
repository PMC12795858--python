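# tfbranch

Link the structural (DNA-binding-domain) hierarchy of transcription
factors to the similarity of their binding-site motifs.

`tfbranch` compares position frequency matrices TomTom-style — gapless
alignment over all offsets and both strands, Pearson correlation as the
column score, and a p-value from a null of database columns — and
aggregates the resulting `-log10(p)` scores into TF-pair, per-TF, and
TF-set similarity metrics (the five order statistics Min/Q1/Q2/Q3/Max).
It then partitions the hierarchy into **branches**: maximal unions of
sister units (classes, families, subfamilies, or single TFs) whose
median TF-pair similarity exceeds a significance threshold
(`-log10 p > 3` by default). It also builds agglomerative similarity
trees with recomputed median linkage, flags TFs whose own motifs are
significantly dissimilar, and ships a synthetic-data generator with
planted branch structure for end-to-end validation.

## Data formats

* Motifs: JASPAR PFM (`jaspar_pfm`), MEME minimal (`meme_minimal`), or
  Hocomoco-style PCM (`hocomoco_pcm`) text; rows are canonicalized to
  A,C,G,T and counts are normalized to column-stochastic frequencies.
* Annotation: a TSV with columns `motif_id`, `tf_name`, and a dotted
  hierarchy path (`superclass.class.family.subfamily`, deeper levels
  optional), e.g. `MA1456.1  Dref  2.3.5`.

`data/` contains the JASPAR2024 *D. melanogaster* CORE collection
(all matrix versions, 346 motifs / 281 TFs) in JASPAR PFM text plus its
annotation table, extracted once by `scripts/fetch_jaspar_dmel.py`.

## Command line

```sh
# synthetic collection with planted branches
tfbranch synth --out demo --seed 1 --kappa-in 32

# motif-pair scores (permutation null caps scores at log10(n_null + 1);
# use --null dp_exact for scores beyond ~3)
tfbranch compare --motifs demo/motifs.pfm --n-null 1000 --out scores.tsv

# set-level metrics for sister families of one class
tfbranch metrics --motifs demo/motifs.pfm --annot demo/annotation.tsv \
    --level family --within 1.1

# branch partition + merge log + trees + manifest
tfbranch branches --motifs demo/motifs.pfm --annot demo/annotation.tsv \
    --thr 3.0 --out results/

# similarity tree of the child units of one hierarchy node
tfbranch tree --motifs demo/motifs.pfm --annot demo/annotation.tsv --within 1.1

# full pipeline from a YAML config
tfbranch report --config run.yaml
```

All randomness flows from `--seed`; each motif pair derives its own
null-model seed from the pair identifiers, so results are independent of
evaluation order and score caches can be reused bit-identically.

## Package layout

| module | contents |
| --- | --- |
| `tfbranch.motif_io` | motif/hierarchy data model, dialect parsers and writers |
| `tfbranch.motif_compare` | column score, alignment, permutation and exact nulls |
| `tfbranch.similarity_metrics` | TF-pair aggregation, heterogeneity, set quartiles |
| `tfbranch.branch_finder` | greedy branch search, agglomerative trees, Newick |
| `tfbranch.synthetic_motifs` | planted-branch generator, partition recovery (ARI) |
| `tfbranch.report` / `tfbranch.cli` | pipeline orchestration and the `tfbranch` CLI |
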