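# paleosex

Three-track sex estimation for archaeological skeletal samples, and the
statistics to compare the tracks against each other:

* **genomic** — karyotype classification from per-chromosome mapped-read
  counts (samtools-idxstats dialect) using two ratio statistics: the
  Y-fraction of sex-chromosome reads (`R_Y`, Wald binomial 95% CI; male
  > 0.075, female < 0.016) and the mean X/autosome read-rate ratio (`R_X`;
  male < 0.60, female > 0.80). Confidence intervals entirely inside a
  decision region give definitive calls, intervals crossing exactly one
  boundary give conditional ("consistent with …") calls, and the rest are
  indeterminate.
* **proteomic** — amelogenin peptide tables from tooth enamel are filtered
  for X/Y isoform specificity (substring containment with modification
  stripping and optional I/L equivalence), chromosome-specific signal is
  summed into cumulative intensity per mg enamel, and sex is called from the
  unique AMELY peptide count (male) or a four-parameter logistic probability
  of female sex on log10 AMELX CI/mg.
* **osteological** — a 20-trait scoring data model (9 pelvic, 6
  cranial/mandibular, 5 robusticity) with ingestion of expert categorical
  labels (`F`, `M`, probable/possible tiers, `Indet`) and an optional
  surrogate weighted-mean aggregator.

A 55-sample published cohort ships as a packaged fixture
(`paleosex.data/table2_cohort.tsv`), and `paleosex.concordance` reproduces
the cross-method agreement tables, read-depth-stratified conflict counts,
read census, and the log-scale preservation statistics from it. A
synthetic-cohort generator (`paleosex.simulate`) emulates the generative
structure all of this assumes — multinomial chromosome counts under known
karyotype with Y mismapping, age-dependent DNA depth decay (~1 order of
magnitude per ~2,000 years), age-invariant lognormal amelogenin signal, and
sex-conditional trait expression with juvenile missingness — so every stage
is testable end to end without external data.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact headline
counts recomputed from the packaged fixture, a brute-force oracle for the
interval classifier, analytic checks on the Pr(F) logistic, and synthetic
cohort properties (no genomic-vs-truth conflicts above 100,000 reads, rising
uncertainty at low depth, proteomic signal independent of DNA depth).

## CLI

```bash
paleosex genomic sample1.idxstats.tsv sample2.idxstats.tsv   # R_Y/R_X calls
paleosex proteomic --mass 10 sample1.peptides.csv            # proteomic calls
paleosex concord --fixture                                   # cohort concordance report
paleosex simulate --seed 1 --n 50 --out sim/                 # synthetic cohort on disk
```

Reports carry a header with tool version, seed and threshold values; logging
goes to stderr. Exit codes: 0 success, 2 input error, 3 config error.

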