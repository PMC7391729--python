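# bidimr

Bidirectional two-sample Mendelian randomization (MR) from GWAS summary
statistics.

Given per-trait summary-statistic tables (one SNP per row: rsid, alleles,
beta, SE, p, optional EAF and N) and a pairwise LD table, `bidimr`:

1. **selects instruments** — significance filter (default p < 5e-8) plus
   deterministic greedy LD pruning (default R² < 0.2), with per-SNP
   F statistics (squared z);
2. **harmonizes** exposure instruments against the outcome study's allele
   orientation (sign flips, strand complements, configurable palindromic
   policy with EAF-based inference);
3. **estimates** the causal effect — Wald ratio for a single instrument,
   inverse-variance-weighted (IVW) meta-analysis otherwise, plus MR-Egger,
   weighted/simple median, Cochran's Q and MR-PRESSO (global test, outlier
   flagging, outlier-corrected estimate);
4. **orchestrates** a family of forward and reverse analyses with a
   Bonferroni family-wise threshold, a sensitivity suite (stricter LD
   pruning, tightened p cutoffs, keep/drop rsid lists) and deterministic
   TSV/JSON outputs;
5. **simulates** two-sample GWAS summary statistics with known ground
   truth (individual-level genotype mode with LD blocks, or a fast
   asymptotic mode) for testing and calibration.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (printed-value
arithmetic, estimator oracles, parameter-recovery/calibration suites,
MR-PRESSO detection rates, harmonization oracle, end-to-end determinism).

## CLI

```bash
# simulate a bundled fixture set (several instrument-count regimes) and a
# ready-to-run pipeline config
bidimr simulate --seed 1 --out-dir sim/

# full config-driven bidirectional run
bidimr run --config sim/config.yaml --out-dir results/

# individual stages
bidimr select sim/met05.tsv --ld sim/ld.tsv
bidimr harmonize sim/met05.tsv sim/complex_fw_met05.tsv --out pairs.tsv
bidimr estimate pairs.tsv --seed 1
bidimr threshold --n-forward 10 --n-reverse 8   # -> 2.78E-03
```

`bidimr run` writes `results.tsv` (fixed column order, estimates to 4
significant digits, p-values like `6.26E-04`, infeasible analyses as
`NA`) and `manifest.json` (config hash, seed, per-stage counts).  Runs
are pure functions of (config, inputs, seed): reruns are byte-identical.

## Notes

- Effect sizes are used on their native per-study scales; no rescaling is
  attempted across sources, so estimates from heterogeneous platforms are
  comparable only in sign/significance.
- LD enters as a precomputed table; pairs absent from it are treated as
  independent by default (`--unknown-ld-dependent` style flags provide
  the conservative alternative in the API).
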