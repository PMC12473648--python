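# fallflow

Fall detection from video by direct reconstruction of global motion
parameters. Instead of computing a dense optical-flow field, the motion
between each pair of consecutive frames is projected onto the six
generators of the 2-D linear non-homogeneous transformation group
(translation x/y, dilation, rotation, two shears) and recovered with a
single 6×6 least-squares solve. The resulting per-pair 6-vectors are
assembled into 6×150 windows and classified as fall / no-fall by a compact
time-axis CNN, optionally extended with a bidirectional LSTM.

The whole pipeline is testable offline: a synthetic-scene module renders
seeded textures warped by known motion schedules, and a feature-space
generator produces labeled motion windows where falls appear as abrupt
simultaneous bursts on all six channels.

## Modules

| module | contents |
| --- | --- |
| `fallflow.gloria_core` | gradients, generator basis, structural tensor / driving vector, 6-parameter solve, per-sequence extraction |
| `fallflow.synthetic_scenes` | seeded textures, sub-pixel affine warping, ground-truth sequences, labeled motion-window simulation |
| `fallflow.windowing` | 6×N window assembly, fall-interval labeling, leak-free normalization |
| `fallflow.fall_classifier` | CNN and CNN+BiLSTM window classifiers (pure NumPy, hand-written backprop, Adam, seeded and deterministic) |
| `fallflow.evaluation` | confusion-matrix metrics, ROC curves, AUC |
| `fallflow.cli_pipeline` | video/PNG I/O, configs, and the `extract` / `train` / `detect` / `evaluate` / `simulate` commands |
| `fallflow.nn` | the minimal layer/optimizer toolkit used by the classifiers |

The classifiers are implemented directly in NumPy (no deep-learning
framework dependency); every layer's backward pass is validated against
finite-difference gradients in the test suite.

## Command line

```bash
# generate a labeled synthetic window dataset
fallflow simulate --out windows.csv --n-windows 400 --seed 1

# train (stratified seeded 90/10 split; report scores the held-out 10%)
fallflow train --data windows.csv --arch cnn --seed 1 \
    --model-out model.npz --report-out report.json

# extract per-frame-pair motion vectors from a video
fallflow extract --video frames_dir/ --out motion.csv

# detect fall events (PNG frame directory or AVI/MP4 container)
fallflow detect --video frames_dir/ --model model.npz --threshold 0.5 --out events.json

# score aligned per-window predictions
fallflow evaluate --pred pred.csv --truth truth.csv --report-out metrics.json
```

Videos can be AVI/MP4 containers (when an ffmpeg-capable imageio plugin is
available) or directories of image frames sorted by filename. Annotations
are 0-based half-open frame intervals. A YAML config (`--config`) can set
window length, stride, solver settings and the full classifier
configuration; see `fallflow.cli_pipeline.PipelineConfig`.

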