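# ehgpreterm

Preterm-labor prediction from electrohysterogram (EHG) signals.

The electrohysterogram records the electrical activity of the uterus from
abdominal surface electrodes. Because uterine contractions become stronger
and more frequent as delivery approaches, EHG recorded weeks before labor
carries information about whether delivery will be preterm (before the 37th
gestational week). This package implements a complete prediction pipeline
for three-channel, 20 Hz EHG recordings of the kind collected in the
Term-Preterm ElectroHysteroGram database (TPEHG, PhysioNet), and a synthetic
cohort generator so every stage can be exercised without a data download.

## Method

For a recording with channels CH1-CH3:

1. **Preprocess** — band-pass each channel to 0.08-4 Hz (fourth-order
   Butterworth, zero-phase), discard the first and last 5 minutes.
2. **Decompose** — empirical mode decomposition by sifting:
   `x[n] = Σᵢ IMFᵢ[n] + r[n]`; keep the first four intrinsic mode
   functions, where contraction energy lives.
3. **Features** — per channel × IMF, six parameter-free descriptors:
   RMS, mean Teager-Kaiser energy `⟨x[n]² − x[n−1]x[n+1]⟩`, log-energy
   entropy `Σ ln x[n]²`, histogram Shannon entropy (bits), Katz fractal
   dimension `ln(N−1)/(ln(N−1)+ln(D/L))`, and the rescaled-range Hurst
   exponent `ln(R/S)/ln N` — 72 features in all.
4. **Balance** — self-adaptive synthetic over-sampling: minority-class
   feature rows are interpolated between adaptively chosen real minority
   neighbours until term/preterm counts are equal.
5. **Screen** — Mann-Whitney U test per feature (term vs preterm); keep
   features with p < 0.05.
6. **Classify** — min-max normalise on training statistics, tune
   AdaBoost / SVM / decision-tree / random-forest hyperparameters by
   Gaussian-process Bayesian optimisation over stratified 10-fold CV AUC,
   and report sensitivity, specificity, accuracy and ROC AUC on the test
   set. **Protocol rule:** every *real* preterm row is reserved for
   testing; only balancer-generated preterm rows train the model. The
   sensitivity restricted to real preterm recordings is reported
   separately — the honest figure an artificially balanced evaluation
   hides.

## Worked example

```sh
ehgpreterm simulate --n-term 10 --n-preterm 3 --seed 1 --out-dir wfdb/
ehgpreterm extract --data-dir wfdb/ --out features.csv
ehgpreterm run --features features.csv --out-dir results/
```

Or in Python, a full experiment on a synthetic cohort shaped like the
early-gestation (PE-TE) group — 143 term + 19 preterm recordings:

```python
import ehgpreterm as e

records = e.generate_cohort(143, 19, "early", seed=2024)
table = e.extract_table(records)                     # 162 x 72 features
cfg = e.RunConfig(classifiers=("adaboost",), n_repeats=5,
                  tuner_budget=10, seed=1)
report = e.run_experiment(table, cfg)
print(report.summary.round(2))
```

prints (values from this exact invocation):

```
              sen         spe         acc       auc      sen_real_only
             mean  std   mean  std   mean  std mean  std          mean  std
classifier
adaboost    100.0  0.0  100.0  0.0  100.0  0.0  1.0  0.0         100.0  0.0
```

Each repeat re-balances (124 synthetic preterm rows added to reach
143+143), re-screens (71 of 72 features survive on this strongly separated
synthetic cohort), re-splits (all 19 real preterm rows plus 30% of term
rows to test), and re-tunes. `sen_real_only` is the sensitivity over the
19 held-out real preterm recordings only. The ceiling metrics reflect the
generator's deliberately large class gap (see `docs/methods.md`), not
expected real-data performance.

## Layout

| module | role |
|---|---|
| `io_ehg` | WFDB record + gestational metadata IO, feature-table CSV |
| `synthetic_ehg` | labeled synthetic EHG cohort generator |
| `preprocess` | 0.08-4 Hz band-pass + 5-min trimming |
| `emd` | sifting, IMF extraction |
| `features` | the six descriptors, 72-element vector |
| `balance` | self-adaptive over-sampling to class balance |
| `select` | Mann-Whitney feature screen |
| `classify_evaluate` | split protocol, tuning, metrics, comparisons |
| `cli` | `ehgpreterm` command with one subcommand per stage |

See `docs/methods.md` for modelling assumptions, parameter defaults, and
numerical choices.
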