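# physioconn

Directed brain–heart–lung connectivity from multichannel physiological
recordings (EEG, ECG, whole-body plethysmography), using windowed
multivariate autoregressive (MVAR) modeling and generalized partial
directed coherence (GPDC) with per-value significance testing.

The intended use case is effective-connectivity analysis in small-animal
electrophysiology — for example contrasting a control genotype against a
SUDEP-prone mutant, or tracking how brain-to-lung flow changes around
seizures — but the machinery is generic: any set of simultaneously
recorded channels grouped into "organs" can be analyzed.

## What it computes

1. **Windowed MVAR fit.** Each recording is cut into non-overlapping
   10-s windows. In each window an order-7 MVAR model is fitted by
   ordinary least squares. At the reference setting (6 channels, 500 Hz)
   each window provides 30,000 data points for 252 coefficients — a
   \>100× data-to-parameter ratio.
2. **Squared GPDC.** From the fitted coefficients and residual
   variances, squared GPDC is evaluated on a 1–200 Hz grid. GPDC is
   column-normalized (the squared outflows of each source channel sum to
   1 at every frequency), invariant to channel rescaling, and exactly
   zero for structurally absent couplings.
3. **Per-value significance (ssGPDC).** Every (source, target,
   frequency) value in every window gets a p-value — either from 99
   circular-shift surrogates (reference method) or from a closed-form
   asymptotic null (fast alternative). Only values with P < 0.05 are
   pooled downstream.
4. **Organ-pair band profiles.** Significant values are pooled over the
   channel pairs of each ordered organ pair (e.g., all four EEG→ECG
   pairs for Brain ⇒ Heart) and summarized per 10-Hz band; bands
   containing 60-Hz mains harmonics are excluded. Empty bands are
   reported as zero and flagged.
5. **Group comparison.** Pooled ssGPDC samples are compared with
   two-sided Mann–Whitney–Wilcoxon rank-sum tests (exact for small
   samples without ties), full-spectrum and per-band; `*` marks
   p < 0.05, `**` p < 0.001.
6. **Peri-event dynamics.** For the most discriminative band (minimum
   rank-sum p), a per-window time series is extracted and smoothed with
   a centered 9-point moving average (90 s of raw data per point), read
   against group-level mean ± SEM reference bands.
7. **Synthetic testbed.** A seeded generator builds recordings from an
   explicit ground truth (AR(2) resonators + directed couplings), so
   every estimate can be validated against a known topology.

## Worked example

Compare a control-like and a mutant-like synthetic group (10 min each),
then locate the most discriminative band per interaction
(`examples/03_group_comparison.py`):

```python
from physioconn import (
    analyze_recording, compare_groups_full_spectrum,
    compare_groups_per_band, define_bands, make_testbed,
    select_discriminative_band,
)

groups = {}
for name, scenario, seed in [("WT", "WT_LIKE", 11), ("KO", "KO_LIKE", 12)]:
    rec = make_testbed(scenario, duration_s=600.0, seed=seed).recording
    groups[name] = analyze_recording(rec, order=7, method="asymptotic")

bands = define_bands()
table = compare_groups_full_spectrum(groups["WT"], groups["KO"], bands,
                                     labels=("WT", "KO"))
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

Output (real run):

```
from_organ to_organ   n_a   n_b  u_statistic  p_value stars  testable
     BRAIN    HEART 11486  9292     7.34e+07        0    **      True
     BRAIN    LUNGS  8979 11989      3.2e+07        0    **      True
     HEART    BRAIN 11246  9367     8.06e+07        0    **      True
     HEART    LUNGS   543 10148     5.85e+04        0    **      True
     LUNGS    BRAIN 10820  6469     4.04e+07 7.16e-65    **      True
     LUNGS    HEART   478   529     1.04e+05 1.87e-06    **      True
```

The designed contrast is recovered: Heart ⇄ Brain flow is reduced and
Brain ⇒ Lungs flow elevated in the KO-like group. Band selection:

```
  HEART => BRAIN    10- 20 Hz   p = 3.27e-186 **
  BRAIN => HEART    40- 50 Hz   p = 5.2e-184 **
  BRAIN => LUNGS    80- 90 Hz   p = 1.44e-164 **
```

Peri-event dynamics (`examples/04_seizure_dynamics.py`) on a scenario
with 80-s epochs of elevated brain-to-lung coupling show the smoothed
series rising through the seizure and relaxing after it:

```
  t =   110 s   0.0518
  t =   150 s   0.0719 <- ictal
  t =   180 s   0.0858 <- ictal
  t =   220 s   0.0709 <- ictal
  t =   260 s   0.0528
```

More narrative walk-throughs live in `examples/`:

| script | shows |
| --- | --- |
| `01_simulate_and_inspect.py` | the generator's ground truth and spectra |
| `02_single_recording_connectivity.py` | windowed analysis + band profile of one recording |
| `03_group_comparison.py` | two-group rank-sum comparison and band selection |
| `04_seizure_dynamics.py` | time-resolved flow around seizure epochs |

## Command-line interface

The CLI is a thin wrapper over the library; all settings travel in a
YAML config.

```sh
physioconn simulate --scenario KO_SEIZING --duration 3600 --seed 1 \
    --out ko.tsv --events-out ko_events.tsv
physioconn all config.yaml        # connectivity -> profiles -> comparison -> dynamics
```

A config lists inputs (delimited text or EDF) with their group and
channel-to-organ map; every analysis default (window length, model
order, grid, significance method, band width, smoothing) is
overridable. Runs write tab-separated tables plus a `run_log.json`
capturing the package version, seeds, and per-input window bookkeeping;
reruns with the same config are byte-identical.

## Reproduction

```sh
pip install --no-build-isolation -e ".[test]"
pytest -q                                           # full suite, ~1 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the headline guarantees (GPDC
normalization and scale invariance, exact structural zeros, type-I error
calibration, directionality recovery, parameter recovery, exact
rank-sum p-values, end-to-end group contrast);
`scripts/acceptance.py` recomputes the same quantities from scratch and
writes them to JSON, fully determined by `--seed`.

## Methods note

`docs/methods.md` documents the model and estimators, the two
significance backends and their calibration, the band and pooling rules,
the synthetic generator design, and the package's limitations (linearity,
no multiple-comparison correction by default, zero-assignment for empty
bands).
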