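# poresift

Accounting and evaluation toolkit for nanopore **adaptive sampling** (Read
Until) sequencing runs, focused on host-DNA depletion of clinical
metagenomes. It joins basecalled FASTQ reads with the sequencer's decision
log, splits reads into the `accepted` / `rejected` / `no_decision`
categories, and computes:

* **yield metrics** — total reads/bases, rejection rates, microbial bases
  from the kept fractions, bp-to-decision distributions, fold changes and
  paired-cohort summaries (mean ± sample SD, with small-category exclusion);
* **composition** — per-taxon abundance tables at genus/species rank with a
  configurable minimum-read filter and denominator policy (whole run
  including rejected reads, or per category), plus per-category
  human/bacterial content;
* **concordance** — control-vs-depletion comparison: per-taxon fold
  deviations binned by count strata, Bray–Curtis dissimilarity over the
  union of retained taxa, and Spearman correlation with a pairwise-case
  exclusion rule (exact permutation p-values up to n=8 shared taxa);
* **mock-community representation** — observed vs expected composition from
  PAF alignments (summed primary-alignment block lengths), per-organism fold
  representation and Gram/yeast group summaries;
* **synthetic runs** — a generator for adaptive-sampling runs
  (FASTQ + decision CSV + truth TSV, and PAF for mock fixtures) with named
  presets, deterministic 15-sample paired cohorts, and an optional
  pore-time model in which rejection frees pore time and increases yield.

Everything runs at desk scale; no external downloads are required. Real
classifier output (centrifuge/kraken2-style TSV) and real decision logs are
consumed directly; on synthetic data a truth-oracle classifier stands in
for the classifier.

## CLI

A single entry point `poresift` with subcommands:

```bash
# generate a synthetic depletion run (FASTQ + decision CSV + truth TSV)
poresift simulate --preset single_sample_depletion --n 10000 --seed 1 --out run/

# split by decision category
poresift split --fastq run/single_sample_depletion.fastq \
    --decisions run/single_sample_depletion.read_until.csv --out split/

# run summary (reads, bases, rejected %, microbial bases, bp-to-decision)
poresift summarize --fastq run/single_sample_depletion.fastq \
    --decisions run/single_sample_depletion.read_until.csv \
    --truth run/single_sample_depletion.truth.tsv \
    --lineage run/lineage.tsv --out summary.json

# abundance table + per-category content
poresift composition --fastq ... --truth ... --lineage ... --out comp/

# concordance for one control/depletion pair of abundance tables
poresift compare --table-a comp_ctrl/abundance.tsv \
    --table-b comp_dep/abundance.tsv --out pair.tsv

# mock-community representation from a PAF
poresift mock --paf mock.paf --expected expected.tsv --out representation.tsv

# full pipeline over a simulated 15-pair cohort
poresift simulate --preset cohort15 --n 5000 --seed 1 --out cohort/
poresift all --cohort-dir cohort/ --out report/
```

Named presets: `single_sample_control`, `single_sample_depletion`,
`single_sample_enrichment`, `cohort15`. Policies (min reads per taxon,
min reads per category, denominator, microbial definition) can be set via
flags or a YAML config (`--config`); flags take precedence.

## Notes

* Decision-log dialect: header row; read-id column `read_id`/`read-id`/`id`;
  decision column `decision`/`action`/`end_reason`; decision synonyms are
  normalized case-insensitively (`unblock|rejected`, `stop_receiving|
  accepted|stop`, `no_decision|proceed|none`). Multiple rows per read: the
  last row in file order wins.
* Reported cohort dispersion is the sample standard deviation (ddof=1).
* "Microbial" defaults to superkingdom Bacteria/Archaea; use the
  `non_human_classified` policy to widen it to any classified non-human
  lineage.
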