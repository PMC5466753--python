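# ftirlip

FTIR chemometrics for monitoring microbial lipogenesis.

## The problem

Screening oleaginous fungi (or other single-cell-oil producers) means asking,
for hundreds of strain x condition x time combinations: *how much lipid has
the biomass accumulated, and what is its fatty-acid profile?* The reference
answer — extraction, transesterification and GC-FID of the fatty acid methyl
esters (FAMEs) — is slow and expensive. High-throughput FTIR spectroscopy of
intact biomass offers an at-line alternative: lipid accumulation shows up as
growing ester-carbonyl (~1745 cm⁻¹) and acyl-chain C–H bands, unsaturation
shifts the olefinic =C–H band (~3006–3012 cm⁻¹) upward, and a multivariate
calibration against GC reference data turns spectra into quantitative
fatty-acid predictions.

`ftirlip` implements that workflow end to end for people building or
validating such screening platforms:

- **spectra** — read/write tabular FTIR data on a shared wavenumber grid
  (4000–500 cm⁻¹ by default), region selection by wavenumber, technical
  replicate averaging, a minimal JCAMP-DX importer;
- **preprocess** — Savitzky–Golay second derivative (window 9, 2nd-order
  polynomial) and extended multiplicative signal correction (EMSC) with
  linear + quadratic baseline terms on the combined 3100–2800 + 1800–500 cm⁻¹
  range;
- **bands** — ester-carbonyl peak height, sub-gridpoint olefinic peak
  position, per-condition trend curves, replicate Pearson correlations;
- **fatty_acids** — internal-standard FAME quantification
  (mass·RRF·area-ratio arithmetic), SAT/MUFA/PUFA sums, the unsaturation
  index UI = [Σ(% monoene) + 2·Σ(% diene) + 3·Σ(% triene)]/100, autoscaling,
  pooled SD;
- **chemometrics** — PCA, NIPALS PLS1/PLS2, leave-one-day-out
  cross-validation with leak-free per-fold EMSC references,
  one-standard-error component selection, and calibration reports
  (range / mean / SD / R²_CV / RMSECV / RPD_CV / factors);
- **simulate** — a synthetic-experiment generator (Gaussian-band
  Beer–Lambert mixtures with planted lipid kinetics, composition shifts,
  scatter artifacts and glucose curves) with full ground truth, so the whole
  pipeline is testable without any instrument data.

The quality index reported per response is the residual predictive deviation
RPD_CV = SD(reference)/RMSECV: ≥ 2 is usable for screening, ≥ 3 good for
quantification.

## Worked example

```python
import ftirlip as fl
from ftirlip.simulate import SyntheticConfig

exp = fl.generate_experiment(SyntheticConfig(drop_conditions=fl.STUDY_210_DROP), seed=42)
report = fl.build_calibration(
    exp.spectra, exp.fatty_acids,
    responses=["SAT", "MUFA", "PUFA", "unsaturation_index", "total_lipid"],
    exclusions=fl.EARLY_GROWTH_EXCLUSIONS,
)
print(report.formatted())
```

prints

```
Response                     Range    Mean     SD    R2  RMSECV  RPD_CV Factors
SAT                      24.1-34.3    29.8    2.8  0.69     1.6     1.8       4
MUFA                     24.0-49.0    40.0    6.6  0.91     1.9     3.4       4
PUFA                     20.3-51.6    30.2    8.0  0.94     2.0     4.0       1
unsaturation_index       0.88-1.43    1.07   0.14  0.91    0.04     3.4       1
total_lipid               6.3-37.0    25.2    9.3  1.00     0.3    34.5       4
```

Each row is one PLS1 calibration validated day-by-day: e.g. the
unsaturation-index model predicts held-out cultivation days with RMSECV 0.04
double bonds per chain against a reference SD of 0.14 (RPD 3.4) — spectra
alone recover ≥ 90 % of the reference variance for the summed fatty-acid
parameters, while total lipid is read almost perfectly from the
ester-carbonyl region. The `examples/` directory holds short narrative
scripts for each capability (simulation, preprocessing + band trends,
calibration, FAME quantification); each prints the numbers it computes and
a line on what they mean.

A thin CLI wraps the same functions
(`ftirlip simulate|preprocess|bands|calibrate|report`, each with
`--config/--seed/--outdir`), writing CSV artifacts plus a JSON manifest with
the config hash and seed for reproducibility.

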