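# Grid configuration schema

`ptsim grid --config <file>` accepts a YAML (or JSON) mapping with the
following keys.  Scalars are accepted wherever a list is expected.

| key            | type                | required | default | meaning |
|----------------|---------------------|----------|---------|---------|
| `designs`      | list of strings     | yes      | —       | design labels, e.g. `PT(1:1:1:1:k)`, `MAT(1:1:1:1:2)`, `stand-alone` |
| `n_drugs`      | int (3, 4 or 5)     | yes      | —       | number of drug arms; cross-checked against each label |
| `per_drug_cap` | int                 | no       | 435     | planned enrollment per drug arm |
| `scenarios`    | list of ints        | no       | all     | 1-based effectiveness scenarios (1 = global null, `n_drugs + 1` = all effective) |
| `rp`           | list of floats      | yes      | —       | placebo true mortality rates; the effective-drug rate is `rp − 0.05` |
| `accrual_mean` | list of floats      | yes      | —       | mean patients/month of the Poisson accrual |
| `n_reps`       | int                 | no       | 10000   | Monte Carlo replicates per cell (`--reps` overrides) |
| `alpha`        | float               | no       | 0.05    | two-sided test level |
| `seed`         | int                 | no       | 0       | master seed; cell *i* of the design × scenario × rp × accrual enumeration uses the stream `SeedSequence(seed, spawn_key=(i,))` |

Unknown keys are rejected.  Example:

```yaml
designs: [PT(1:1:1:1:k), PT(1:1:1:1:1)]
n_drugs: 4
scenarios: [2, 3, 4, 5]
rp: [0.075, 0.10, 0.125, 0.15]
accrual_mean: [100, 200, 300, 400]
n_reps: 2000
seed: 1
```

Outputs: `<out>/oc.csv` — tidy long table with columns `design, n_drugs,
scenario, rp, rd, accrual_mean, n_reps, metric, drug, estimate, mc_se` —
and `<out>/manifest.json` recording the configuration, seed, package
version and wall time.  Identical manifests reproduce identical CSV bytes.
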