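# qsarchance

Randomization tests and chance-correlation audits for QSAR models.

## The problem

QSAR modelling routinely fits a response measured on a few dozen compounds
against a pool of hundreds of candidate molecular descriptors. Searching
such a pool for the best small linear equation (or a shallow decision tree)
*guarantees* impressive-looking training statistics even when the
descriptors carry no information at all: on 21 compounds and an
89-descriptor pool, the best 3-variable model fitted to pure noise averages
r² ≈ 0.7. Ordinary goodness-of-fit statistics, and even internal
cross-validation, cannot separate such chance correlations from real
structure–activity signal.

The affordable defence is to simulate the predictive power of pure chance:

* **y-scrambling** (response randomization) — permute the activity values
  across compounds, leaving descriptors intact;
* **x-scrambling** — permute each descriptor column independently,
  preserving its marginal distribution;
* **pseudo-descriptors** — replace descriptor columns by draws from a
  chosen distribution (uniform, normal, binomial, Poisson, exponential)
  with parameters fitted to the originals.

Repeating the *entire* model search on N such randomized sets and
collecting the best score from each yields the **mean highest r²** (mhr²)
and **mean highest q²** (mhq²) with their SDs. A real model is credible
only if its statistics clear `mh + 2.3·SD` — roughly the 99th percentile of
chance under normality (the empirical percentile is reported too).

`qsarchance` is a library (plus a thin CLI) for the whole audit: it reads
and writes descriptor/activity tables in CSV and MDL SD files (byte-
faithful outside the randomized fields), generates the randomized sets
reproducibly from a Mersenne-Twister master seed, provides the model
engines the audit needs (OLS, exhaustive/genetic best-subset search,
depth-limited CART trees, constant/intercorrelation pool filtering), and
computes the full validation panel:

* q² = 1 − PRESS/SS_tot by leave-one-out and exhaustive leave-m-out;
* regression through the origin: slope k = Σyŷ/Σŷ², R0²;
* Golbraikh–Tropsha criteria (q² > 0.5, R² > 0.6, (R²−R0²)/R² < 0.1,
  0.85 ≤ k ≤ 1.15);
* cRp² = √(r²·(r² − Rr²)) against a randomized-model baseline Rr²;
* rm(test)² = R²·(1 − √(R² − R0²));
* Wold permutation intercepts R²int/Q²int (valid below 0.4 / 0.05);
* ACC, PREC, SENS, SPEC, FALL and F1 from confusion counts for
  classification models (NaN on empty denominators, never silent zeros).

It is aimed at QSAR / cheminformatics practitioners who want the
randomization tests to be a one-liner next to their existing modelling
code rather than a spreadsheet exercise.

## Worked example

`examples/03_chance_audit_regression.py` plants a genuine signal
(population R² = 0.9) in a 21-compound, 10-descriptor table, finds the best
≤3-variable model, and audits it against 300 y-scrambled sets:

```text
fixture: n=21, pool=10, population R^2 = 0.90
real-data best model: ('d1', 'd4', 'd9'), r^2 = 0.893

chance performance over 300 y-scrambled sets:
     mean     SD  +1 SD  +2.3 SD  +3 SD
r2  0.361  0.124  0.484    0.645  0.732
q2  0.005  0.214  0.220    0.498  0.648

real r^2 0.893 vs mh+2.3SD threshold 0.645 -> better than chance: True
empirical percentile within chance scores: 100.0%
```

Read the chance table first: scrambled activities — which contain *no*
information — still reach r² = 0.36 on average and 0.65 at the +2.3 SD bar,
purely because the search picks the luckiest 3 of 10 descriptors each time.
The real model's 0.893 clears that bar, so its fit cannot be explained by
selection alone. The other examples cover SD-file randomization
(`02`), the regression validation panel (`04`) and the classification audit
on a 1:36 actives:decoys deck (`05`).

The same audits are available from a shell:

```bash
qsarchance chance-test --input data.sdf --activity LOGK --mode y-scramble \
    --n 300 --seed 42 --engine mlr-subset --max-vars 3 --report chance.csv
qsarchance scramble --input data.csv --id-column id --activity ACT \
    --fields ACT --n 300 --seed 42 --out-dir runs/
qsarchance pseudo --input data.sdf --activity LOGK --fields all-descriptors \
    --distribution uniform --n 300 --seed 42 --out-dir runs/
```

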