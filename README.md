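# phyloprof

Tested, reusable implementations of three analysis stages that often appear
together in transcriptome/phylogenomics studies:

1. **Site stripping + clade support** — rank alignment columns by per-site
   evolutionary rate, progressively remove the fastest sites in 5% steps
   (19 nested subsets by default), and measure support for a clade of
   interest as its bipartition frequency across bootstrap tree samples
   (UFBOOT-style newick-per-line files), including majority-rule consensus
   and support-vs-removal curves.
2. **Binary ortholog-profile comparison** — species × ortholog count tables
   binarized to 0/1 profiles, pairwise Pearson similarity (phi), the
   complementary distance `D = 1 − r`, PCoA with broken-stick assessment of
   the leading axes, Ward clustering (ward1/ward2 dialects) of species and
   orthologs, and deterministic heatmap ordering.
3. **Annotation rule engines** — bestsum taxonomic assignment from ranked
   hit tables, cellular-origin and host (first-hit / percent-identity)
   contaminant screens, 100%-identity deduplication, MCL protein-family
   clustering with a minimum-organism retention rule, KEGG-ortholog ID
   transfer at an inclusive 80% bit-score threshold, and thresholded
   presence/absence calling.

A seeded `synthetic_data` module generates every input the pipeline
consumes (alignments with gamma site rates and an optional conflicting
signal block in the fastest sites, tree samples with a planted clade
frequency, grouped ortholog profiles, hit tables with planted contaminant
composition) with known ground truth, so everything is testable offline.

## CLI

```bash
phyloprof simulate --seed 1 --out-dir sim/            # synthetic inputs + truth files
phyloprof strip --alignment sim/alignment.fasta --rates sim/alignment.rate --out-dir strips/
phyloprof support --trees sim/sample.ufboot --clade sim/truth_focal_clade.txt
phyloprof curve --manifest curve.tsv --clade clade.txt --out curve_out.tsv --plot curve.png
phyloprof profile --counts sim/counts.tsv --axes 2 --cluster ward2 --out-dir prof/
phyloprof decontam --hits sim/hits.tsv --out kept.txt --report report.tsv
phyloprof mcl --edges edges.tsv --organisms orgs.tsv --out clusters.tsv
phyloprof kegg-transfer --table families.tsv --out transfers.tsv
phyloprof presence --hits hmm_hits.tsv --map hmm2kegg.tsv --out presence.tsv
```

`simulate` accepts a YAML/JSON config mirroring `SimulationConfig`
(`n_taxa`, `alignment_length`, `gamma_shape`, `conflict_fraction`,
`planted_frequency`, `groups`, `hit_composition`, ...).

## Layout

```
src/phyloprof/
  seqio_trees.py       alignment/tree I/O, bipartitions, concatenation
  synthetic_data.py    seeded generators with ground truth
  site_stripping.py    rate ranking and progressive stripping
  clade_support.py     clade frequency, consensus, support curves
  profile_compare.py   profiles, Pearson/1-r, PCoA, broken stick, Ward
  annotation_rules.py  decontamination screens, MCL, KEGG transfer, presence
  cli.py               click command group
tests/                 unit, property and acceptance tests
scripts/acceptance.py  acceptance report generator
```
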