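# Methods

## Sensor model and synchronization

Each insole sensor emits one 6-channel IMU packet every 20 ms
(accelerometer in g, gyroscope in deg/s — the file header declares these
units) carrying a sequence number and a reception timestamp. The sequence
number fixes the sample's position on the sensor's own uniform grid;
missing numbers identify lost packets. The two sensors' clocks differ by a
roughly constant offset, estimated as the mean difference of the
reception instants of the first *N* rank-matched packets (*N* = 50, one
second of data, CLI-configurable). Sign convention: a positive offset
means the first stream received later.

Inside `synchronize` the averaged quantity is the per-packet clock anchor
`recv_time − (seq − seq₀)·T` rather than the raw reception time; on
gapless streams this is identical to the rank-matched mean, and it stays
unbiased when a packet is lost inside the averaging window. The later
stream's time base is shifted by the estimate, both streams are assigned
to the common grid by nearest sample, sequence gaps are filled by
previous-sample hold (leading gaps by back-fill) and flagged in a
per-sample `gap_mask`. Sample-hold was chosen over interpolation because
it preserves grid regularity without inventing dynamics; downstream
detectors treat flagged samples like any other. All event intervals are
half-open `[start, end)` on 0-based sample indices.

Offset recovery accuracy: with reception jitter of sd 5 ms and N = 50 the
estimator's error is ~1 ms (sd of a 50-sample mean of 7 ms differences),
comfortably inside the half-sample (10 ms) alignment requirement; the
test suite verifies this over 100 seeded trials per offset.

## Significant-motion detection (kicks and activity segmentation)

Motion intensity is the product of a sample with its first difference,
`M_i = (x_i − x_{i−1})·x_i`, with `M_0 = 0` (no predecessor). `M` is
signed; the absolute value is taken before smoothing so that downward
peaks register and negative lobes cannot cancel the average — the
quantity thresholded is a magnitude of motion. A centered moving average
of odd length `size` smooths `|M|`; at the boundaries the window is
truncated and the divisor shrinks to the number of valid samples. The
adaptive threshold is `mean(M̄)·ratio`, so sensitivity scales with the
session's overall motion level and is invariant to rescaling the signal
(scaling `x` by `c` scales both `M̄` and the threshold by `c²`). Samples
with `M̄` strictly above the threshold are significant; ties count as
non-significant. Maximal significant runs become events; events shorter
than `min_duration` are dropped.

Defaults for strike detection: `size = 11` samples (0.22 s, matching the
strike-pulse scale), `ratio = 3.0`, `min_duration = 0.2 s`. These are a
compromise — a larger `ratio` suppresses running-stride oscillation, the
duration floor removes smoothing-widened blips — and all three are
exposed on the CLI. The striking foot's Y-acceleration channel is the
detection channel.

The same segmenter, applied to the sum of smoothed rectified motion
intensity across all 12 channels, separates active spans from stationary
pauses in CoD sessions (`size = 31`, `ratio = 0.01`, `min_duration =
1 s`). The low ratio keeps the quiet walk-back registering as activity
while true pauses fall below threshold. Consecutive activity segments are
paired in order as (part A, part B) of each round; an odd trailing
segment is dropped with a warning. Only part A is modeled.

## CoD dataset construction

Windows are 0.7 s (35 samples at 50 Hz) of six channels — gyroscope Y and
Z plus accelerometer Z, both feet — slid with a 3-sample stride. A 90%
overlap of a 35-sample window implies a non-integral 3.5-sample stride;
stride 3 realizes 32/35 ≈ 91.4% overlap, keeping the nominal figure as a
floor (configurable). A window is labeled positive when it covers at
least 30% of some annotated CoD interval, boundary inclusive.

Class imbalance (~10% positive windows at generator defaults) is
countered by replicating positive windows with fresh zero-mean Gaussian
noise per channel, sd estimated from stationary spans of the session
(sample sd, ddof 1), until the positive fraction reaches 50%. The number
of copies is `ceil((r·N − E)/(1 − r))`, which lands the fraction exactly
at the target when attainable; originals are never modified.

Subsets are normalized per channel by z-score, each subset with its own
statistics — including the test subset. Normalizing test data with its
own statistics (rather than the training statistics) is deliberate: no
statistic crosses subset boundaries, so the test subset cannot leak into
training and vice versa. A zero-variance channel is centered only and
flagged. The test subset is one whole player; remaining rounds are
shuffled by seed and assigned 80/20 to train/validation at round
granularity so that overlapping windows of one round never straddle
subsets.

## Network and ensemble

One member is the fixed stack

    BN → Conv1D(32, k3) → ReLU → BN → Conv1D(64, k3) → ReLU → Flatten
       → BN → Dense(24) → ReLU → BN → Dropout(0.5) → Dense(12) → ReLU
       → BN → Dense(2) → softmax

The convolution runs along the 6-channel axis with the 35 time samples as
input features. Convolving along time would be the conventional choice,
but this orientation is what produces the published shape chain
(6,35)→(4,32)→(2,64)→128→24→12→2 and parameter budget — total 13,946,
trainable 13,484, non-trainable 462 (two running statistics per
batch-norm feature: 35+32+128+24+12 features) — and is honored exactly.
The network, batch-norm (ε = 1e-5, running-stat momentum 0.9), dropout,
Adam and the training loop are implemented in numpy; single-threaded
numpy makes training bit-reproducible under a seed.

Training defaults: cross-entropy, Adam 1e-3, batch 64, up to 100 epochs,
early stopping on validation loss with patience 10, best weights
restored. He-normal initialization. Hidden activations are ReLU, output
softmax; dropout rate 0.5. All are configurable; none of these
hyperparameters is architectural.

The ensemble holds out the designated test player entirely, then trains
eight members, each excluding one further player (leave-one-player-out
over the eight non-test players). Member probabilities are averaged with
divisor 8 — a true mean, keeping AP within [0, 1].

## Post-processing

AP is smoothed by a centered moving average (default 5 prediction steps)
into WAP, compared against the dynamic threshold `1.75·mean(WAP)`
computed per round when round identities are known (whole series
otherwise; ties are non-events). Maximal supra-threshold runs become
detections; a detection's span is measured between its first and last
window centers, `(run_length − 1)/f_pred` with `f_pred = fs/stride =
16.7 Hz` — measuring by window extent would make every span ≥ 0.7 s and
the 0.1 s rule vacuous. Detections spanning under 0.1 s are removed; this
single reusable filter is what eliminates isolated one-window false
positives. A constant WAP can never trigger (c < 1.75c for c > 0).

## Synthetic sessions

The generator emulates the study conditions as they present to the
sensors, not biomechanics: sinusoidal stride oscillation (3 Hz cadence;
100 deg/s gyro, 0.5 g accel, antiphase feet), half-sine ball strikes
(8 g × 0.15 s for shots, 60% of that for passes) on the striking foot's Y
accelerometer, CoDs as 0.4 s of support-foot stillness with a 250 deg/s
swing-foot gyro transient, idle noise (0.02 g / 1.0 deg/s), and a
transport layer adding a 37 ms inter-foot clock offset, 2 ms reception
jitter and 0.2% packet loss. Shot/pass sessions are 30 repetitions of
run-up / strike / still / walk-back. A CoD round is run–CoD–run–CoD–run
(part A, ≈ 16.8 s — sized so positive windows are ≈ 10% of part-A
windows), a pause, a walk-back (part B) and a pause; 30 rounds per
session by default. Ground truth records strike intervals (padded 80 ms
toward the plant/contact gesture), CoD intervals, part A/B spans and idle
spans.

What the generator does not emulate — and what passing tests therefore do
not show about real data: inter-player technique variability, gait
irregularity, sensor drift and saturation, rebounds and mis-hits,
non-stationary noise. The synthetic signatures are cleaner than reality;
detector F1 ≈ 1.0 and ensemble recall/specificity well above 0.7 on
synthetic sessions demonstrate correctness of the pipeline, not field
accuracy.

## Scaling of the shipped experiments

The test suite and `scripts/acceptance.py` run the full ensemble
experiment at 9 players × 10 rounds with training capped at 12 epochs
(patience 3) — the task converges within a few epochs at these signal
levels, and this size keeps a complete CPU run in minutes. The library
defaults remain 30 repetitions and 100 epochs.

## Known limitations

- Rank-matched offset estimation cannot distinguish a clock offset from a
  genuine start-time difference between recordings; both are absorbed
  into alignment.
- The round segmenter assumes pauses separate part A and part B; sessions
  without pauses yield merged segments.
- `augment_minority` replicates positive windows cyclically; with very few
  distinct positives the augmented set is many noisy copies of the same
  windows.
- Deployment-time CoD detection without round annotations falls back to a
  whole-series dynamic threshold, which is more sensitive to the
  activity/idle mix than the per-round form.
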