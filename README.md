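# dmnpdc

Directed resting-state connectivity of the default mode network (DMN) from
multichannel time series: multivariate autoregressive (MVAR) modelling,
partial directed coherence (PDC), and the group-level statistics used in
clinical severity studies — driven end to end by a calibrated
synthetic-cohort generator with known ground-truth coupling.

## The problem

Frequency-domain Granger causality asks, for a pair of brain regions,
whether region j's past helps predict region i beyond i's own past — and
at which rhythm. For an MVAR(p) model

    x_t = Σ_{r=1..p} A_r x_{t−r} + e_t,

the partial directed coherence from source j to sink i at frequency f is

    π_ij(f) = |Ā_ij(f)| / sqrt(Σ_k |Ā_kj(f)|²),
    Ā(f)    = I − Σ_r A_r e^{−i2πfr/fs},

normalised so every source's squared outflows sum to one at each
frequency. Severity studies of social anxiety report group differences in
band-averaged PDC over eight DMN regions (mPFC: FZ/F3/F4;
precuneus/PCC: PZ; lateral parietal: P3/P4; supramarginal: CP5/CP6) and
correlations between mean connectivity and the Social Interaction Anxiety
Scale (SIAS). Such recordings are rarely deposited, so this package pairs
the full analysis pipeline with a generator that emulates the typical severity-study design
(4 severity groups × 22 subjects) from stable ground-truth MVAR processes
— making estimator correctness and the designed group effects testable.

Who this is for: anyone validating directed-connectivity pipelines
(PDC/Granger over EEG-like band structure), teaching frequency-domain
causality, or needing a seeded ground-truth cohort with realistic group
contrasts and symptom coupling.

## Worked example

```python
from dmnpdc import make_cohort, preprocess, subject_connectivity, pearson_corr

cohort = make_cohort(n_per_group=22, duration_s=116.0, seed=1)
tensors = {}
for s in cohort.subjects:
    epochs = preprocess(s.recording, apply_bandpass=False)  # 29 x 4-s epochs
    tensors[s.id] = subject_connectivity(epochs, order_policy="aic")

severe = cohort.group_subjects("severe")
c = pearson_corr(
    [tensors[s.id].mean_offdiag("alpha") for s in severe],
    [s.sias for s in severe],
)
print(f"severe group: r({c.n}) = {c.r:+.3f}, p = {c.p:.4f}")
```

prints

```
severe group: r(22) = +0.758, p = 0.0000
```

i.e. within the severe group, a subject's mean alpha-band PDC over the 56
directed DMN pairs rises with their SIAS score — the designed (and
study-typical) positive coupling; the control group shows the mirrored
negative correlation.

The same analysis as a narrative sequence lives under `analysis/`
(`01_simulate_cohort.py` … `05_group_stats.py`); running them in order
writes recordings, epochs, connectivity tensors, band power and the
statistics report under `results/`. The final stage prints, for one seeded
88-subject cohort:

```
delta     F(3,252) = 3.838, p = 0.0103, eta2 = 0.044
alpha PDC ~ SIAS [control ]: r = -0.658, p = 0.0009
alpha PDC ~ SIAS [severe  ]: r = +0.758, p = 0.0000
alpha PDC ~ SIAS [pooled  ]: r = -0.249, p = 0.0194
```

— a significant delta-band group effect with mild/moderate connectivity
above control/severe, and opposite-signed severity correlations in the
extreme groups.

There is also a CLI over the same pipeline:

```bash
dmnpdc all --seed 1 --out results/run        # generate -> connect -> stats
dmnpdc generate --config cfg.yaml            # cohort + manifest only
```

## What's inside

| module | contents |
| --- | --- |
| `dmnpdc.synthetic` | cohort generator: group templates (precuneus hub for severe/moderate, frontal outflow for control), calibration of coupling strengths to reported alpha-band group means, SIAS coupling |
| `dmnpdc.preprocessing` | common-average reference, zero-phase FIR band-pass, robust artifact marking, anti-aliased decimation, 4-s epoching |
| `dmnpdc.mvar` | stacked-OLS MVAR fits (pooled across epochs), AIC order selection, companion-matrix stability |
| `dmnpdc.pdc` | PDC spectra, five-band averaging, the per-subject 8×8×5 tensor |
| `dmnpdc.band_power` | Welch PSD and absolute band power |
| `dmnpdc.group_stats` | one-way ANOVA + η², Tukey HSD, Bonferroni, KS normality screen, Pearson correlations |
| `dmnpdc.pipeline` / `dmnpdc.cli` | seeded end-to-end orchestration, CSV/JSON/heat-map export |

Design rationale, calibration details and known limitations are in
[docs/methods.md](docs/methods.md).

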