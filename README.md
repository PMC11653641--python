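# ictalesi

Noninvasive imaging of seizure-onset activity from scalp EEG.  For
drug-resistant focal epilepsy, localizing the cortex that generates ictal
(seizure) rhythms guides surgical planning, but scalp recordings blur
sources through the head's volume conduction.  `ictalesi` implements a
complete, self-contained workflow for studying this inverse problem:

* **Ictal source model** — a modified Jansen–Rit (Wendling-type) neural
  mass model with fast somatic inhibition.  Each synapse applies the
  impulse response `h(t) = Qqt·e^(−qt)` and the sigmoid
  `S(v) = 2e₀/(1+e^(r(v₀−v)))`; varying the gains (A, B, G) and rate
  constants (a, b, g) produces the six waveform families of seizure onset,
  from sporadic spikes to low-voltage fast activity.  Grid exploration,
  regime classification and balanced train/test parameter banks are
  included.
* **Forward model** — a parcellated spherical cortex with radial dipoles
  and the analytic three-concentric-shells (brain/skull/scalp) solution
  for a 76-channel 10-10 montage; loaders accept externally computed
  boundary-element lead fields.
* **Synthetic data** — contiguous cortical patches carrying one or two
  neural-mass waveforms, projected to the sensors with SNR-controlled
  noise and max-abs normalization.
* **Inverse network** — a per-time-step residual spatial stack plus
  residual LSTM temporal stack mapping sensor matrices to region
  waveforms, trained with MSE/Adam (pure NumPy, hand-derived gradients;
  exposed as a scikit-learn style regressor).
* **Classical baselines** — sLORETA, frequency-domain imaging (FDI) and
  the LCMV beamformer, with ictal peak-averaging.
* **Evaluation** — Otsu-thresholded energy maps scored by sensitivity,
  specificity, precision/F1, localization error, spatial dispersion,
  seizure-onset-zone distance and temporal correlation.

See `docs/methods.md` for the model equations, parameter defaults and
numerical choices.

## Worked example

The one-command demo builds a 60-region spherical head model, explores a
thinned parameter grid, balances a small ictal bank, renders 1,600
training samples (400 patches x 2 variants x 2 SNR levels, 0.5 s at
100 Hz), trains the network for 20 epochs and evaluates held-out
regime-switching patches:

```bash
ictalesi demo --seed 0 --out runs/demo
```

```
n_train: 1600
n_test: 16
final_train_loss: 0.01175874083613356
mean_sensitivity: 0.734375
mean_specificity: 0.9578117266127701
mean_correlation: 0.8776792269514944
mean_localization_error_mm: 14.246652757760799
```

Reading: on 16 unseen patches whose oscillation regime switches mid-sample,
the thresholded energy maps recover ~73 % of the true patch regions while
marking ~96 % of the uninvolved cortex as inactive; reconstructed waveforms
correlate at r ≈ 0.88 with the simulated sources, and the symmetric
centroid distance between estimate and truth is ~14 mm on this coarse
60-region sphere.  Larger models and training sets (see the benchmark
below) push specificity and correlation above 0.97.

The same stages are scriptable individually (`simulate-nmm`, `build-bank`,
`make-headmodel`, `gen-data`, `train`, `infer`, `baseline`, `evaluate`) or
callable as library functions.

```python
from ictalesi import head_model, nmm

trace = nmm.simulate_nmm(nmm.NMMParams(A=5.5, B=14, G=4, g=0.5), seed=1)
label = nmm.classify_regime(nmm.waveform_features(trace))
print(label.label, label.name)   # e.g. "6 quasi-sinusoidal activity"
```

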