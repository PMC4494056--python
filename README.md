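# hsreg

Identification and characterization of candidate human-specific,
transposable-element-derived transcription-factor-binding loci, built as a
tested, reusable pipeline and exercised end-to-end on a synthetic
multi-species genome with known ground truth.

## What it does

Starting from TF-binding peak intervals, pairwise genome-alignment chains
for a panel of rodent/primate species, repeat annotations, LAD/PMD interval
sets, gene tables with evolutionary-rate attributes, base-resolution
5hmC calls and per-individual presence calls, the pipeline:

- classifies each 200-bp site window as **shared / primate-specific /
  human-specific** from best-single-chain block coverage at a configurable
  `min_match` (default 0.95), requiring unique mapping under
  alternate-assembly chains for the human-specific call
  (`hsreg.lineage_specificity`);
- quantifies repeat association, TE family breakdowns, and
  full-length (5,962–6,189 bp) vs truncated L1 censuses
  (`hsreg.repeat_association`);
- scores LAD/PMD colocalization against random-placement expectations and
  derives human-specific LADs from mouse four-cell-type LAD panels
  (`hsreg.domain_colocalization`);
- runs proximity-placement analysis around gene sets with
  mean-nearest-target-distance thresholds, rate correlations and 10-kb
  colocalization scoring (`hsreg.proximity_enrichment`);
- enumerates single-/double-site C→T mutants of a seed oligonucleotide and
  censuses exact-match loci across genomes (`hsreg.deamination_kmer_scan`);
- detects strand-asymmetric three-call 5hmC patterns near sites
  (`hsreg.hydroxymethyl_patterns`);
- scores per-individual (modern/archaic) sequence conservation and
  attributes site emergence relative to the population split
  (`hsreg.archaic_conservation`);
- models per-lineage creation rates of novel binding sites (sites per
  100,000 years, years per site, lineage acceleration ratios)
  (`hsreg.creation_rates`).

Shared statistics (hypergeometric/Fisher/chi-square tests, binomial
expectations, Pearson correlation, chromosome-binned density profiles) live
in `hsreg.enrichment_stats`; interval/chain/format primitives in
`hsreg.core_genomics`. `hsreg.synthetic_cohort` generates a fully specified
toy multi-species dataset — ancestral genome plus branch-tracked TE
insertions, exact chains, planted sites/domains/5hmC/genes, per-individual
presence — so every stage is testable offline with known truth.

## CLI

```bash
# generate synthetic fixtures
hsreg simulate --seed 1 --outdir fixtures/

# full pipeline from a YAML config (see tests/test_pipeline_cli.py for the schema)
hsreg run --config pipeline.yaml

# individual stages
hsreg classify --sites sites.bed --panel panel.yaml --min-match 0.95 --out class.tsv
hsreg kmer-scan --seed-fasta seed.fa --min-len 12 --max-len 24 \
    --genomes human.fa,chimp.fa --out scan.tsv
hsreg density --events sites.bed --bin 1000000 --out density.tsv
hsreg rates --out rates.tsv
hsreg report --outdir hsreg_out/
```

The pipeline writes one TSV per stage, a `manifest.json` with content
hashes, and a `report.md` whose percentages are recomputed from counts.
Identical config + fixtures yield byte-identical bundles.

## Layout

```
src/hsreg/
  core_genomics/        intervals, chains, format I/O, intersection engine
  synthetic_cohort.py   ground-truthed multi-species simulator
  lineage_specificity.py repeat_association.py domain_colocalization.py
  proximity_enrichment.py deamination_kmer_scan.py hydroxymethyl_patterns.py
  archaic_conservation.py creation_rates.py enrichment_stats.py
  pipeline.py cli.py
tests/                  unit + property + acceptance suites
scripts/acceptance.py   acceptance-target report
```
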