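# ampliclone

Rare-clone detection and passage-enrichment analysis for ultra-deep amplicon
read counts.

Given tab-separated count tables (one row per individual × culture passage ×
replicate, with total and mutant-allele read counts), the package provides:

- **Background thresholding** — transform reference-sample allele fractions
  to log-odds, trim the extremes, and set a k-sigma (default 6) detection
  threshold with its implied significance level (~2×10⁻⁹ at 6 SD).
- **Positivity calling** — depth QC (default ≥500 reads) and strict
  full-precision comparison of each sample's allele fraction against the
  threshold, aggregated to individual-level tallies per cohort.
- **Association** — exact two-sided Fisher test (probability-mass convention,
  full enumeration via log-gamma) with odds ratio and prevalences.
- **Enrichment** — mixed-effects negative-binomial regression of mutant
  counts on passage number with log total reads as exposure offset. Default
  random effect is the classic panel-NB beta parameterization; a
  normal-intercept NB2 integrated by 15-node adaptive Gauss–Hermite
  quadrature and plain fixed-effects fits are also available. Segment fits
  (e.g. passages 0→4 and 4→9) and replicate-concordance ICC included.
- **Simulation** — fully seeded generators for error-only reference samples
  (logit-normal), mutant-bearing patient series (logit-linear growth with an
  optional plateau), and two-group cohort studies, for end-to-end testing
  without external data.

A 19-individual × 3-passage published count table ships as a bundled fixture
(`ampliclone.load_table1_fixture()`).

## Command line

```bash
ampliclone threshold --reference ref.tsv --k-sigma 6 --trim 2 --out model.json
ampliclone call      --table cohort.tsv --model model.json --passage 9 --out calls.tsv
ampliclone associate --table cohort.tsv --model model.json --passage 9 --out assoc.json
ampliclone enrich    --table cohort.tsv --segments --out fit.json
ampliclone simulate  --config sim.yaml --seed 17 --out synthetic.tsv
ampliclone run       --reference ref.tsv --cohort cohort.tsv --out-dir out/
ampliclone report    --table cohort.tsv --model model.json --out-prefix out/fig
```

`run` executes threshold → call → associate → enrich and writes
`model.json`, `calls.tsv`, `assoc.json`, `fit.json`, `summary.json` and a
human-readable `summary.txt`; it can also be driven by a YAML config
(`--config pipeline.yaml`, flags override).

## File format

Tab-separated, UTF-8, mandatory header:
`sample_id individual_id family_id cohort disease component passage
replicate total_reads alt_reads` (+ extra columns, preserved verbatim).
`cohort` is one of `WM_FAMILY`, `MM_FAMILY`, `REFERENCE`; `passage` 0 means
pre-immortalization blood. Invariants (`0 ≤ alt_reads ≤ total_reads`, unique
individual/passage/replicate keys) are enforced on read.
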