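# ystrkit

Forensic Y-STR haplotype statistics and population-structure analysis.

`ystrkit` works with haplotype tables of Y-chromosomal short tandem repeat
(Y-STR) profiles — one row per male individual, one column per marker, with
YHRD-style allele notation including microvariants (`13.1`) and multi-allele
cells (`11-14`). It provides:

- **Data model & IO** (`ystrkit.data`): alleles, locus calls, haplotypes,
  TSV reader/writer, a registry of five nested forensic marker panels
  (Minimal ⊂ PowerPlex Y12 ⊂ Yfiler ⊂ PowerPlex Y23 ⊂ Microreader 24Y),
  panel projection and haplotype multiplicity counting.
- **Forensic statistics** (`ystrkit.forensic`): haplotype diversity
  `HD = N(1 − Σpᵢ²)/(N − 1)`, match probability `HMP = Σpᵢ²`,
  discrimination capacity `DC = M/N`, per-locus allele frequencies and gene
  diversity, and multi-panel summary tables.
- **Population structure** (`ystrkit.structure`): pairwise Rst via a
  two-level AMOVA over squared repeat-count differences, permutation
  p-values, Bonferroni thresholds, classical MDS of the Rst matrix, and
  neighbor-joining trees with Newick output.
- **Synthetic data** (`ystrkit.simulate`): an exact multiplicity-spectrum
  dataset constructor (including a nested multi-panel variant), a
  single-step symmetric stepwise-mutation-model simulator of structured
  populations, and a bundled 910-individual reference fixture.

## CLI

```sh
# forensic parameters per panel + per-locus gene diversity
ystrkit summarize --input cohort.tsv --out results/

# pairwise Rst with permutation p-values and Bonferroni report
ystrkit compare --input popA.tsv --input popB.tsv --input popC.tsv \
    --permutations 9999 --seed 1 --out results/

# downstream embeddings of a distance matrix
ystrkit mds  --matrix results/rst.tsv --out results/coords.tsv
ystrkit tree --matrix results/rst.tsv --out results/tree.nwk

# simulate structured populations under the stepwise mutation model
ystrkit simulate --config sim.yaml --seed 7 --out sims/
```

Every command writes a `manifest.json` (inputs, parameters, seed, version)
and refuses to overwrite outputs without `--overwrite`. Stochastic commands
require an explicit `--seed`.

Haplotype tables are UTF-8 TSV with header `sample_id`, `population`, then
locus names; multi-allele cells are joined with `-`; missing values are
empty cells by default.

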