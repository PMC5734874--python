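# quiemut

Analysis toolkit for mutation-accumulation experiments in quiescent
(non-dividing) cell populations, built around a loss-of-function reporter
assay and whole-genome count data:

- **spectrum** — mutation records, clonal-redundancy filtering, and the
  spectrum statistics (Ts:Tv, AT bias, deletion/insertion balance, net
  base-pair change, signed indel size histogram).
- **gene_model** — enumeration of all 9 × n_aa potential single-nucleotide
  substitutions of a CDS with codon-level effect classification
  (synonymous / non-synonymous / STOP-gain), and hits-per-target
  "k-distributions" at residue or site level.
- **saturation** — integer maximum-likelihood estimation of the hidden
  target count from a k-distribution under the exchangeable multinomial
  occupancy model, with flat-prior 95% credibility intervals, plus a
  STOP-saturation equating estimator. Three routes to the fraction *f* of
  non-synonymous SNVs that cause the phenotype.
- **correction** — conversion of phenotypic (reporter) mutation rates into
  total rates via *f* (SNVs: divide by p_stop + f·p_ns; indels: inflate
  in-frame 3/6-nt classes), and genome-length extrapolation.
- **accumulation** — least-squares slope of mutant frequency versus days.
- **genome_counts** — chi-square test of Poisson homogeneity for
  per-genome mutation counts.
- **synthetic_data** — seeded simulators for every stage (uniform target
  hits, phenotype-filtered SNV assays, linear accumulation with noise,
  Poisson genome counts), so the whole pipeline runs without external data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` re-derives the published summary numbers from
their printed inputs and runs the simulation-based calibration checks.

## Command line

```sh
quiemut fixtures --outdir demo --seed 0          # synthetic demo dataset
quiemut pipeline --mutations demo/mutations.tsv \
    --cds demo/cds.fasta --outdir out \
    --snv-rate 0.14e-7 --indel-rate 0.41e-7      # full analysis
quiemut spectrum demo/mutations.tsv --out spectrum.tsv
quiemut saturate demo/k_distribution.tsv --out sat.tsv --n-targets 265
quiemut accumulate demo/accumulation.tsv --out fit.tsv
quiemut poisson demo/genome_counts.tsv --out gof.tsv
quiemut correct --snv-rate 0.14e-7 --f 0.35 \
    --p-stop 0.05 --p-ns 0.73 --p-syn 0.22 --out corr.tsv
```

All tables are tab-separated UTF-8 with a header row; positions are 1-based
within the CDS; `-` (or an empty field) marks the absent side of a pure
insertion/deletion. Exit codes: 0 success, 1 user error, 2 internal error.

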