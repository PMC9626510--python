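# arp300

Fast single-trial P300 decoding for a nine-target oddball speller, built
around a lightweight **separable 1D CNN** (depthwise + pointwise
convolution), with four classical baselines (LDA, BLDA, SWLDA, linear SVM),
nine-way target decoding, and Wolpaw information-transfer-rate evaluation.
Because no public recordings exist for this paradigm, the package ships a
**synthetic oddball-EEG simulator** that reproduces the session protocol
(10 runs x 9 blocks x 5 trials x 9 flashes at 175 ms SOA, 30 data channels
at 1 kHz) with environment-specific ERP latency (~482 ms AR / ~435 ms CS),
reduced AR amplitude, a parieto-occipital topography, and 1/f + alpha +
white background noise. Everything downstream of the simulator treats the
data exactly as a recorded session would be treated.

The CNN is implemented in pure NumPy (analytic gradients + Adam) so the
package has no deep-learning framework dependency.

## Layout

| module                | contents |
|-----------------------|----------|
| `arp300.simulate`     | stimulus schedules, synthetic sessions, grand-average ERPs |
| `arp300.preprocess`   | channel drop, 0.1–12 Hz zero-phase band-pass, 600 ms epoching, decimation to 200 samples, repetition averaging |
| `arp300.nn`           | minimal NumPy layer/optimizer engine (BatchNorm, grouped Conv1d, Linear, Adam) |
| `arp300.sepcnn`       | SepCNN + standard-CNN architectures, training, scoring, separable-convolution cost formulas |
| `arp300.baselines`    | shrinkage LDA (Gram/Woodbury), evidence-maximised BLDA, stepwise SWLDA, linear SVM |
| `arp300.evaluate`     | 9-way decoding, accuracy tables, AUC, Wolpaw ITR, paired t-test, one-way ANOVA, cross-validation |
| `arp300.io`           | HDF5 session/epoch containers, CSV schedules, minimal EDF import/export, checkpoints |
| `arp300.cli`          | `arp300 simulate / preprocess / train / evaluate / pipeline / report` |
| `arp300.datasets`     | bundled reference accuracy/latency tables used as arithmetic fixtures |

## CLI

```sh
arp300 simulate --environment ar --runs 10 --seed 1 --out session.h5
arp300 preprocess session.h5 --lo 0.1 --hi 12 --window-ms 600 --downsample 3 --out epochs.h5
arp300 train epochs.h5 --model sepcnn --seed 1 --out model.npz
arp300 evaluate epochs.h5 --model sepcnn --folds 5 --itr-t 2.0 --seed 1 --out report.json
arp300 pipeline --config run.toml --out-dir out/     # end to end, one master seed
arp300 report report.json --csv table.csv
```

`pipeline` reads one TOML/YAML config (unknown keys rejected); every
subcommand honours `--seed`, and all stage seeds derive deterministically
from the master seed, so identical configs give bit-identical reports.

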