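# mrmediate

Two-step, two-sample Mendelian randomisation (MR) with multivariable-MR
mediation analysis, built on GWAS summary statistics.

Given per-SNP summary association tables (variant id, alleles, effect-allele
frequency, beta, SE, p, n) for an exposure, an outcome and candidate
mediators, the package:

- **harmonises** exposure/outcome/mediator associations to a common effect
  allele per SNP, with configurable handling of palindromic (A/T, C/G) SNPs
  and a full exclusion log (`summary_io`);
- **estimates causal effects** by the Wald ratio, inverse-variance-weighted
  (IVW) combination, weighted-median estimator (parametric-bootstrap SE) and
  Egger regression with a directional-pleiotropy intercept, plus
  instrument-strength diagnostics (R², F-statistic) (`estimators`);
- **screens bidirectional effects** among all instrumented traits (IVW matrix)
  and runs the two-step mediation workflow — step one: exposure → mediators;
  step two: mediators → outcome; triage of mediators with consistent support —
  (`pipeline`);
- **quantifies mediation** via multivariable IVW (outcome betas regressed on
  exposure + mediator betas with inverse-variance weights, no intercept) and
  the attenuation formula `100·(1 − β_direct/β_total)` (`mediation`);
- **simulates** complete two-sample summary-statistics studies with known
  causal structure — configurable horizontal pleiotropy (balanced,
  directional, InSIDE-violating) and mediation chains — so every stage is
  testable offline (`simulate`).

## CLI

The `mrmediate` entry point exposes six verbs:

```bash
# write a synthetic consortium-style study with an embedded truth file
mrmediate simulate --profile single_mediator --out-dir study/ --seed 7

# align two tables to a common effect allele
mrmediate harmonise --exposure-file study/X_instruments.tsv \
    --outcome-file study/Y_associations.tsv --out harmonised.tsv \
    --exclusions excluded.tsv --policy drop_ambiguous --window 0.42,0.58

# IVW + weighted-median + Egger on one pair
mrmediate estimate --exposure-file study/X_instruments.tsv \
    --outcome-file study/Y_associations.tsv --seed 7 --binary-outcome

# bidirectional IVW screen of every instrumented trait against the rest
mrmediate screen --config study/config.yaml

# two-step mediation analysis without / with the screen
mrmediate mediate --config study/config.yaml
mrmediate run --config study/config.yaml --out-dir report/
```

`run` emits `step_one.tsv`, `step_two.tsv`, `screen.tsv`, `mediation.tsv`, a
machine-readable `results.json` holding the identical numbers, and a
`run_log.txt` recording seeds, policies and per-SNP exclusions. Reruns with
the same config and seed are bit-identical.

### Config format

YAML, with file paths relative to the config file:

```yaml
exposure: X
outcome: Y
mediators: [M1]
seed: 7
n_boot: 1000
palindrome_policy: drop_ambiguous   # drop_ambiguous | drop_all | keep
eaf_ambiguity_window: [0.42, 0.58]
out_dir: results
traits:
  - name: X
    type: continuous      # or binary (effects on the log-odds scale)
    unit: SD
    instruments: X_instruments.tsv    # this trait's own instrument table
    associations: X_associations.tsv  # all SNPs of interest vs this trait
```

Tables are TSV (or CSV) with logical columns
`variant_id, effect_allele, other_allele, beta, se` and optional
`eaf, pvalue, n`; names can be remapped via `read_association_table`'s
`column_map`.

## Library use

```python
import mrmediate as mr

exposure = mr.read_association_table("bmi_instruments.tsv", trait_name="BMI")
outcome = mr.read_association_table("chd_associations.tsv", trait_name="CHD",
                                    trait_type="binary")
h = mr.harmonise(exposure, outcome)
print(mr.ivw(h).with_or_scale().to_dict())
print(mr.weighted_median(h, n_boot=1000, seed=1).to_dict())
print(mr.egger(h).to_dict())
```

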