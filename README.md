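# eegdenoiser

Removal of ocular (EOG) and muscular (EMG) artifacts from single-channel EEG
segments with a one-dimensional, full-scale-connected multi-residual
encoder–decoder network ("MultiResUNet3+"), plus everything needed to study
it end to end: surrogate signal banks, SNR-controlled semi-synthetic
contamination, a training pipeline, and a temporal/spectral evaluation suite.

The package is pure Python on top of NumPy/SciPy/pandas/h5py — the network,
backpropagation and the Adam optimizer are implemented in NumPy, so there is
no deep-learning-framework dependency.

## Quick start

```python
import eegdenoiser as ed

# 1. Surrogate banks (or load real banks from HDF5/NPZ files)
from dataclasses import replace
eeg = ed.generate_surrogate_bank(replace(ed.DEFAULT_SPECS["EEG"], count=72, seed=1))
eog = ed.generate_surrogate_bank(replace(ed.DEFAULT_SPECS["EOG"], count=72, seed=2))

# 2. Contaminate: y = x + λ·n at each SNR level, normalized by σ_y
ds = ed.build_scenario_dataset(eeg, eog, [], "EOG",
                               snr_levels=range(-7, 3), seed=0)
split = ed.split_dataset(ds.manifest, "B").splits["B"]
x_tr, y_tr = ds.pooled_arrays(split.train)
x_va, y_va = ds.pooled_arrays(split.val)

# 3. Model / Results (statsmodels-style): fit() returns a results object
from eegdenoiser import ArchitectureSpec, EEGDenoiser, TrainConfig
model = EEGDenoiser(y_tr, x_tr,
                    arch=ArchitectureSpec(d=3, n_base=8, input_length=512),
                    config=TrainConfig(epochs=30, batch_size=8, seed=0))
results = model.fit(val_data=(y_va, x_va))
print(results.summary())

# 4. Evaluate: CC, η, γ, RRMSE (temporal/spectral), band-power ratios
x_te, y_te = ds.pooled_arrays(split.test)
report = results.evaluate(y_te, x_te, fs=ds.fs)
print(report.summary())
```

### Command line

```bash
eegdenoiser synth --kind EEG --count 100 --out eeg.h5
eegdenoiser synth --kind EOG --count 100 --out eog.h5
eegdenoiser mix --scenario EOG --eeg eeg.h5 --eog eog.h5 --out manifest.json
eegdenoiser describe -d 5 -n 64
eegdenoiser train --scenario EOG --eeg eeg.h5 --eog eog.h5 \
    -d 3 -n 8 --epochs 30 --checkpoint weights.npz
eegdenoiser evaluate --scenario EOG --eeg eeg.h5 --eog eog.h5 \
    -d 3 -n 8 --checkpoint weights.npz --report-json report.json
```

## Package layout

| Module | Contents |
| --- | --- |
| `eegdenoiser.segments` | `Segment`, surrogate bank generation, HDF5/NPZ I/O, Fourier resampling |
| `eegdenoiser.contamination` | `mix`, `normalize_pair`, scenario assembly, manifests, splits |
| `eegdenoiser.network` | architecture arithmetic, `MultiResUNet3Plus` and its building blocks |
| `eegdenoiser.denoiser` | `EEGDenoiser` (model) / `DenoiserResults` (fit results) |
| `eegdenoiser.metrics` | CC, η, γ, RRMSE, periodogram PSD, band-power ratios, `MetricReport` |
| `eegdenoiser.experiments` | per-SNR (A) and pooled (B) protocols, k-fold cross-validation |
| `eegdenoiser.cli` | `eegdenoiser` command-line entry point |
| `eegdenoiser._autodiff` | minimal NumPy reverse-mode autodiff + Adam |

See `docs/methods.md` for the model description, parameter tables, numerical
choices, and known limitations (including a quantitative analysis of what
denoising quality is attainable at desk scale on surrogate data).

## Testing

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

`tests/test_acceptance.py` holds the desk-scale acceptance suite; the
reduced-scale learning tests there train a small network for several minutes
on one CPU. One of its assertions (held-out η > 50 %) is knowingly failing:
the required value is not attainable with the fixed small architecture on the
fixed surrogate family — `docs/methods.md` § "Limitations" gives the
receptive-field / linear-filter ceiling analysis. Reference targets:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
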