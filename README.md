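# ramanpheno

Label-free discrimination of regulatory (Treg) and conventional (Tconv)
T cells from single-cell Raman spectra, as a tested, reusable pipeline:

- **spectra_io** — flat CSV spectra tables (metadata columns + one column per
  wavenumber channel), band-assignment tables, JSON reports.
- **synthetic_data** — a generative cohort simulator: Lorentzian/Gaussian band
  templates with small planted class effects far below cell-to-cell
  variability, fluorescence-like baselines, cosmic-ray spikes, donor/batch
  intensity and axis-shift effects, class imbalance, and sort-purity label
  corruption — with full ground truth returned for testing.
- **preprocessing** — despiking (running median), iterative cubic-spline
  baseline subtraction, reference-peak axis calibration, silent-region
  (1800–2700 cm⁻¹) excision, PCA/MAD outlier filtering.
- **classifier** — L1-regularized logistic regression (mean negative
  log-likelihood + λ‖w‖₁, unpenalized intercept, standardized channels),
  separation-vector band annotation, ROC/AUC (trapezoid == pairwise
  concordance, exactly), confusion matrices, stratified splitting, and
  cross-validated λ selection with a one-standard-error sparsity rule.
- **confident_learning** — label-noise pruning: out-of-fold probabilities,
  per-class self-confidence thresholds, confident joint, estimated noise
  rates, and ranked removal of likely-mislabeled cells.
- **workflows** — five end-to-end studies with leakage audits and
  reproducible manifests: random-split, pruned, FrIII mixture scoring,
  donor holdout, and naive-vs-full subpopulation comparison.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end property criteria (oracle
equivalences, planted-artifact recovery, noise-rate recovery, pruning
benefit, band recovery, mixture scoring, donor-holdout behaviour, null
control); the rest are fast unit/property tests.

## CLI

```bash
ramanpheno simulate   --config cohort.yaml --seed 1 --out spectra.csv
ramanpheno preprocess --in spectra.csv --out processed.csv --qc-report qc.json
ramanpheno train      --in processed.csv --lambda auto --seed 1 \
                      --model-out model.json --report-out report.json
ramanpheno prune      --in processed.csv --out pruned.csv --report-out cl.json
ramanpheno study      --kind donor_holdout --in processed.csv \
                      --config study.yaml --out-dir results/
ramanpheno demo       --out-dir demo/        # 3-donor cohort, all 5 studies
```

Study kinds: `random_split`, `pruned`, `mixture_scoring`, `donor_holdout`,
`subpopulation`. YAML config keys mirror the `CohortConfig`,
`PreprocessConfig` and `StudyConfig` dataclasses.

## Library example

```python
import ramanpheno as rp

template = rp.default_template()
config = rp.CohortConfig(n_donors=3, cells_per_donor=500,
                         purity_tconv=0.92, purity_treg=0.82, seed=0)
cohort, truth = rp.simulate_cohort(template, config)
processed, qc = rp.run_preprocessing(cohort)

study = rp.StudyConfig(study_kind="pruned", lambda_=0.003, seed=0)
report = rp.run_pruned_study(processed, study)
print(report.results["pruned"]["test"]["auc"])
```
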