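# odoratlas

Curation and pattern-discovery analyses for insect odorant-response
databases.

Published odor-response measurements — receptor electrophysiology in
heterologous systems, native single-sensillum recordings (SSR),
electroantennograms (EAG), and two-choice behavioral assays — are
reported in incompatible conventions: preference as an index, percent
attraction/repellency, or raw choice counts; concentrations as V/V or
W/V fractions, molarity, ppm, mass per substrate area, or dry amounts;
firing rates with or without the solvent background removed; EAG
deflections raw or normalized to a reference odorant.  `odoratlas`
standardizes all of these into one flat record schema and implements
the analyses such a compilation supports, for researchers in insect
chemical ecology and vector biology:

- **Gaussian tuning** of odorant-receptor (OR) responses to molecular
  properties.  For a property *x* (molecular volume, weight, logP,
  ...), responses are fitted with
  *r*(x) = *a*·exp(−(*x*−*b*)²/(2σ²)); σ, the standard deviation of the
  fitted Gaussian, measures tuning sharpness.  Reliability comes from a
  shuffle null: responses are permuted against the property values and
  *p* = #{σ_shuffle ≤ σ_actual}/N over N shuffles.
- **Descriptor-based response prediction**: a filtering cascade over a
  molecular-descriptor matrix (missing values, variance < 0.005, mutual
  |r| > 0.95), a 70/15/15 odorant split, one (50, 50, 50) feedforward
  network per OR with validation-driven early stopping, and a
  shuffled-response control, compared per OR by Pearson *R* and mean
  absolute error with a paired sign-rank test.
- **Cross-dataset comparisons**: empty-neuron vs oocyte sensitivity
  cross-tabulation, assay-category pairing (landing vs choice assays),
  preference vs oviposition correlation, cross-species preference
  correlation, preference change per 10-fold concentration step, and
  OR-activation-count (≥ 10 spikes/s) vs preference correlation.  All
  matching is on concentrations rounded to the nearest power of ten;
  dry amounts never match solution records.
- **A synthetic database generator** with planted, recoverable effects
  (tuning center/width, an oocyte sensitivity threshold θ, assay
  offsets δ, a concentration slope β, an activation-count loading γ)
  that closes the loop for testing every stage.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
synthetic database (200 odorants, 30 ORs, 2 species; planted tuning
b\* = 130, σ\* = 30, a\* = 100 spikes/s on a molecular-weight-like
property):

```bash
python analysis/01_simulate.py      # generate database + messy raw export
python analysis/02_standardize.py   # curation rules + round-trip check
python analysis/03_tuning.py        # Gaussian tuning + permutation test
python analysis/04_descriptor_model.py
python analysis/05_comparisons.py
```

`03_tuning.py` prints, for the planted property and three null
properties:

```
fitted 4 properties at decade 1e-2 (p from 1000 shuffles each):
  molecular_weight       n= 8685 b=       130 sigma=      27.4 p=0.000  [tuned]
  log_p                  n= 8550 b= -6.02e+11 sigma= 2.088e+13 p=0.954  [not reliable]
  polar_surface_area     n= 8595 b=  2.31e+03 sigma=      1642 p=0.680  [not reliable]
  complexity             n= 8460 b= -1.59e+04 sigma=      6880 p=0.691  [not reliable]
```

Only the planted property is detected (center 130 recovered exactly;
width slightly shrunk by the planted inhibitory responses); untuned
properties give huge, unreliable widths with null p-values.
`05_comparisons.py` reports the remaining planted effects back:

```
techniques: 3000 shared OR-odor pairs; 712 (23.7%) respond in the
  empty-neuron system but read 0 in oocytes; reverse: 0
assays (landing vs choice, mosquito): n=301 pairs, mean delta = -0.279
  (planted -0.3), p = 4.2e-51
oviposition vs PI (Aedes_aegypti): n=301, R = -0.070 (planted
  independent), p = 0.23
concentration: n=710 adjacent-decade pairs, mean delta = -0.196 per
  10-fold (planted -0.2), p = 1.8e-116
OR activation count vs PI: n=87, R = -0.242 (planted negative)
```

A command-line interface wraps the same functions
(`odoratlas simulate|standardize|tuning|predict|compare --help`).

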