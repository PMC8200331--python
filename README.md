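# optoconn

Group-level resting-state functional connectivity analysis for multichannel
fNIRS (functional near-infrared spectroscopy), built for infant-cohort studies
where spontaneous hemodynamic activity is recorded during natural sleep and
compared across experimental groups.

fNIRS measures cortical oxy- and deoxyhemoglobin concentration changes
(HbO, HbR) from light attenuation at two wavelengths through source–detector
optode pairs ("channels"). `optoconn` implements the full analysis chain from
raw photon counts to group statistics:

* **Preprocessing** — optical density relative to the mean baseline,
  wavelet-domain despiking of sparse motion artifacts, the modified
  Beer–Lambert law (default DPF 5.3 at 760 nm / 4.2 at 850 nm), truncation to
  a fixed ~560 s segment, and one *joint* nuisance OLS per chromophore:
  Fourier terms for every grid frequency ≥ 0.09 Hz (temporal filtering),
  Legendre polynomials of order 0–4 (drifts), and the channel-mean global
  signal, fitted simultaneously.
* **Quality assessment** — HbO/HbR coupling (valid recordings show negative
  correlation and antiphase instantaneous dynamics), Welch spectra, and
  hierarchical channel clustering on correlation distance.
* **Temporal group ICA with dual regression** — subjects are z-normalised and
  temporally concatenated into a `[channels × 2 chromophores] × [time ×
  subjects]` matrix; FastICA yields group functional networks (FNs), with
  ICASSO-style consistency indices (Iq) across random restarts; dual
  regression

      stage 1:  data (2C × T) ~ group maps  →  subject time courses
      stage 2:  data ~ normalised time courses  →  subject spatial maps

  takes each FN back to single subjects, where channelwise one-way ANOVAs
  (BH-FDR within each FN's channels, q < 0.05) and JZS Bayes factors compare
  groups.
* **Connectome ICA (connICA)** — per subject, a *robust* channel-pair
  correlation matrix per chromophore: z-scored pairs are weighted once by a
  Tukey biweight window `S(u) = (1 − (u/k)²)²`, `u = ρ/σ`, on the whitened
  joint radius ρ with `σ = 1.4826·MAD(ρ)` and `k = 4.685` (the constant giving
  the biweight location estimator 95% Gaussian efficiency), then Pearson on
  the weighted pair. Fisher-z upper triangles of both chromophores form a
  `[subjects] × [1035 pairs × 2]` edge matrix (46 channels); FastICA across
  subjects yields functional connectome components (FCCs) with one weight per
  subject, a multi-run recurrence filter for stability, and per-component
  ANOVA/FDR/Bayes-factor group tests.
* **Synthetic cohort generator** — cohorts with known ground truth (planted
  bilateral networks, homotopic coupling, antiphase HbO/HbR, cardiac /
  respiratory / Mayer physiology, slow global vasomotion, polynomial drifts,
  motion spikes, optional group effects), emitted as raw intensities so the
  whole chain is exercised from the modified Beer–Lambert forward model
  onward. Defaults mirror a 99-infant, 3-group, 46-channel, 8.93 Hz study.

## Worked example

```python
import numpy as np
import optoconn as oc

# a small two-group cohort with a planted effect: group 1 expresses
# network 0 with 1.8x the amplitude of group 0
spec = oc.CohortSpec(
    n_groups=2, n_per_group=(12, 12), n_channels=16, n_samples=1800,
    effect=(0, 1, 1.8), seed=1,
)
recordings, truth = oc.generate_cohort(spec)

subjects = [oc.preprocess_recording(rec, n_samples=1500) for rec in recordings]
qa = oc.hb_coupling(subjects[0])
print(f"subject 0 QA: median corr(HbO,HbR) = "
      f"{np.median(qa.correlation[qa.valid]):.2f}, passed = {qa.passed}")

edges = oc.RobustConnectivity().fit(subjects).transform(subjects)
print(f"edge matrix: {edges.shape[0]} subjects x {edges.shape[1]} edges")

ica = oc.ConnICA(n_components=4, n_runs=10, seed=0).fit(edges)
table = oc.fcc_group_stats(ica.fccs_, truth.group_labels, q=0.05)
cols = ["fcc", "retained", "iq", "F", "p", "fdr_significant", "bf10", "evidence"]
print(table[cols].round(3).to_string(index=False))
```

Output:

```
subject 0 QA: median corr(HbO,HbR) = -0.99, passed = True
edge matrix: 24 subjects x 240 edges
 fcc  retained    iq      F     p  fdr_significant   bf10                    evidence
   0      True 1.000  1.389 0.251            False  0.506   anecdotal evidence for H0
   1      True 1.000 11.426 0.003             True 15.038      strong evidence for H1
   2      True 0.999  2.154 0.156            False  0.683   anecdotal evidence for H0
   3      True 0.999  0.211 0.650            False  0.314 substantial evidence for H0
```

The preprocessed subject shows the physiologically expected antiphase HbO/HbR
coupling. Of the four extracted connectome components, exactly one carries the
planted group difference: it survives FDR correction across components and its
Bayes factor (BF10 ≈ 15) indicates strong evidence for a group effect, while
the remaining components correctly lean toward the null. `GroupICA`
(temporal group ICA + dual regression) follows the same estimator pattern:
`fit` on a list of preprocessed subjects, `transform` to get subject-specific
network maps, then `fn_group_stats` for channelwise comparisons.

A `optoconn` command-line interface chains the same stages on files:
`simulate`, `preprocess`, `qa`, `connectome`, `tgica`, `connica`.

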