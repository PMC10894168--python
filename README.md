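# cismr

Drug-target Mendelian randomization (MR) from GWAS summary statistics.

`cismr` implements a two-sample MR pipeline for genetically proxied
lipid-lowering drug targets: cis-instrument selection for the PCSK9, HMGCR,
and NPC1L1 gene regions (GRCh37) from LDL GWAS summary statistics, allele
harmonization against a case-control outcome GWAS, and an estimator /
sensitivity suite — IVW with multiplicative random effects, MR-Egger,
weighted median, weighted mode, Cochran's Q, leave-one-out, instrument-
strength F statistics, and a trait-association pleiotropy screen. A
synthetic two-sample GWAS generator with known ground truth makes every
stage testable offline.

## Layout

| module | purpose |
| --- | --- |
| `cismr.gwas_io` | read/write summary statistics and LD matrices; embedded per-target instrument tables; allele harmonization |
| `cismr.instruments` | cis windows, greedy LD clumping, F statistics (Wald and explained-variance forms), instrument building |
| `cismr.estimators` | Wald ratios, IVW-MRE, MR-Egger, weighted median/mode, Cochran's Q, leave-one-out, OR conversion |
| `cismr.pleiotropy_screen` | exclude instruments associated with confounding traits via a local lookup table |
| `cismr.synthetic_data` | simulate exposure + case-control outcome summary statistics, LD matrices, positive-control outcomes |
| `cismr.pipeline` / `cismr.cli` | full-study orchestration, reports, figures, command line |

## Command line

```bash
# emit the embedded per-target instrument tables
cismr fixtures --out fixtures/

# simulate a two-sample study with a known causal effect
cismr simulate --out sim/ --seed 7 --n-variants 30 --causal-effect -0.5

# full study from a YAML config (instruments, 4 estimators, Q,
# leave-one-out, screen, primary + validation outcomes, figures)
cismr run --config config.yaml --out results/

# positive-control outcome analysis with pass/fail flag
cismr positive-control --config config.yaml
```

Minimal `config.yaml`:

```yaml
seed: 7
exposure_path: sim/exposure.tsv   # omit to use the embedded tables
outcome_path: sim/outcome.tsv
ld_path: sim/ld.tsv               # optional; omit = treat variants as independent
validation_path: null             # optional second outcome GWAS
trait_table_path: null            # optional SNP/TRAIT/P screen table
include_genomewide: false         # add the genome-wide exposure instrument
n_boot: 2000
```

All effects are reported per unit exposure *increase* on both log-odds and
OR scales; each estimate also carries `or_inhibition = exp(-beta)`, the OR
for genetically proxied target inhibition, which drives the
positive-control pass flag.

## File formats

Everything is tab-delimited text: summary statistics
(`SNP CHR POS EA OA EAF BETA SE P N`, remappable), square LD r² matrices
with an rsID header row/column, and trait tables (`SNP TRAIT P`). Reports
are written as TSV tables plus a deterministic, byte-stable
`summary.json`.
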