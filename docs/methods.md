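# Methods

## The problem and the procedure

During blocked experiments, the latent state induced by context — here the
social context of gentle grooming by a trusted partner vs. non-social
computer-controlled airflow — can persist across trials and be visible in
the *baseline* activity between stimuli. The package asks whether that
state can be decoded from baseline LFP, using classifier accuracy as the
measure of decodable context information, with a shuffled-label null as
the chance calibration.

The chain is: stimulus schedule → baseline window extraction → wavelet
spectrogram → per-(session, nucleus) dataset → classifier accuracy
distribution vs. its null. A spike-triggered-average (STA) branch
characterizes which frequency bands differ between contexts, and a
physiology branch (heart rate, respiratory sinus arrhythmia) verifies the
autonomic contrast that plausibly drives the brain-state difference.

## Synthetic sessions

No recordings ship with the package; `bcd.synthgen` generates sessions
with the statistical structure the analysis assumes. What is emulated,
and what is not, determines what passing tests mean.

**Stimulus schedule.** Airflow blocks: 11 presentations × 10 repeats
(110); touch blocks: 20 × 5 (100); 1 s stimuli, 4 s gaps. Blocks
alternate; defaults are 3 + 3 blocks per session with 120 s between
blocks (block count, gap and session length are package choices — the
paradigm fixes only the within-block timing). The desk-scale analyses in
the tests use 1 + 1 blocks.

**LFP.** Per channel, independent Gaussian noise with a 1/f^α spectrum
(α = 1), std 50 µV, truncated below 0.5 Hz. The truncation emulates the
AC coupling of extracellular recording hardware and is load-bearing:
without it, 1/f components with periods comparable to a block carry block
identity, and a classifier can "decode" context from noise alone in a
world with no injected effect. Context enters as band-limited Gaussian
noise added over the whole block (a persistent state, not an evoked
response): during touch blocks the 10–17 Hz power is multiplied by
`touch_gain` (default 2.0), during airflow blocks 17–25 Hz by
`airflow_gain` (2.0); arbitrary extra (lo, hi, gain, block) effects can
be injected for ablation experiments. Context-independent nuisance
structure: Poisson-timed Gabor bursts (0.2 /s, 150 ms, random 5–45 Hz
center) and broadband transients during every stimulus, identical for
both stimulus types. Setting both gains to 1 yields a null world in which
block type is statistically invisible in the LFP.

Not emulated: volume conduction, electrode drift, line noise, shared
across-channel covariance, cross-frequency coupling, non-Gaussian
amplitude statistics. Passing tests therefore show the *pipeline*
recovers injected effects at realistic SNR and stays calibrated without
them — not that real amygdala LFP contains such effects.

**Spikes.** Bernoulli approximation of an inhomogeneous Poisson process
on the sample grid; with `lfp_coupling > 0` the rate is modulated by the
channel's band-passed LFP so STAs are oscillatory in the coupling band.

**Heartbeats.** Integrate-and-fire: a beat fires at each integer crossing
of the integrated instantaneous rate. The rate is the block's base HR
(airflow 130, touch 110 BPM) modulated (i) sinusoidally at the
respiratory frequency (0.3 Hz) with the block's RSA depth (airflow 0.05,
touch 0.15) and (ii) by broadband < 1 Hz noise of fractional SD
`hrv_noise` (0.02). The HRV noise floor matters because the RSA statistic
normalizes each window's spectrum to unit area in the respiratory band:
it measures the *sharpness* of the respiratory peak against background
variability, and with a noiseless sinusoid both conditions saturate.
With `hrv_noise = 0`, `rsa_depth = 0` the generator degenerates to exact
constant inter-beat intervals (used in tests).

One master seed fans out via `numpy` seed sequences to independent
per-channel and per-component substreams; identical (parameters, seed)
gives bit-identical sessions.

## Baseline selection

Candidates are the intervals between two consecutive same-type stimuli in
one block (never before a block's first stimulus), trimmed by 200 ms
after offset and before onset; with the default timing each candidate
spans 3.6 s. One window offset per session is chosen by aligning all
candidates at interval start, computing the across-trial SD per timepoint
(per channel, then averaged over channels), and taking the 0.5 s stretch
with the lowest mean SD, earliest offset on ties. A per-session (rather
than per-channel) offset keeps all spectrograms on one time base.

## Spectrograms

Continuous wavelet transform with a complex Morlet wavelet, ω₀ = 5,
evaluated at 1–50 Hz in 1 Hz steps via the scale relation
a = (ω₀/2π)·fs/f. Power is |CWT|²/a — the extra 1/a makes the response
amplitude-true, so equal-amplitude tones at different frequencies give
equal power. No cone-of-influence masking is applied; on 0.5 s windows
the rows below ~5 Hz are edge-dominated and are treated as features like
any other. For classification the power image is block-averaged along
time by a decimation factor (default 50 → 10 bins per 0.5 s window);
this trades temporal detail for a ~25× smaller classifier input and
leaves band-power contrasts intact. Min–max scaling to [0, 1] is
per-pixel with extrema estimated from the training set only; test values
outside the training range are clipped (per-image scaling is available
as an option).

## Decoding protocol

Per (session, nucleus) dataset: labels from block type, at least 20 and
at most `max_per_class` (default 300) windows per class. Each repeat
draws a fresh 80/10/10 split of the *unique* trials per class, then
equalizes classes within folds: the training fold bootstraps the minority
class up to parity (on ties the touch class is resampled, keeping the
resampling step in the protocol), while validation and test folds
subsample the majority down. Two properties are deliberate: no physical
trial appears in more than one fold (balancing before splitting would
leak duplicated minority trials into the test set — measured on the null
world this inflates a memorizing classifier to ~59%), and evaluation
folds contain no duplicates (a duplicate re-weights the fold for the
whole run and biases its accuracy estimate).

**CNN.** 3×3 conv ×24 + ReLU, batch norm, 3×3 conv ×48 + ReLU, 2×2 max
pool with stride 1 (a stride-2 variant is available), batch norm,
flatten, fc 64 + ReLU, dropout 0.5, fc 2; Adam (lr 1e-3), cross-entropy,
mini-batches of 20, 40 epochs in the full protocol. After each epoch the
validation accuracy is evaluated; the parameters with the best validation
accuracy are used at test time (earliest epoch on ties; final parameters
when no validation set is given). Implemented in NumPy with im2col
convolutions; exact architecture conformance is asserted by a
parameter-shape test.

**SVM.** scikit-learn `SVC`, RBF kernel, C = 1; kernel width by the
median heuristic (γ = 1/median ‖xᵢ−xⱼ‖² over a subsample) on flattened
spectrograms.

**Null protocol.** Identical in every respect except that training (and
validation) labels are permuted; the test set keeps true labels. Note a
structural property of label-shuffle nulls: a permutation that happens to
agree with the truth on more than half the training items leaves a
learnable residue, so the null accuracy distribution has a fat right
tail. Percentile-based separation claims therefore need adequate repeat
counts; the full protocol uses 50.

**Reports.** 5th/50th/95th accuracy percentiles per distribution;
separation is declared when the real 5th percentile exceeds the null
95th. Band ablation retrains on row-restricted spectrograms (10–17,
17–25, 10–25 Hz, inclusive bounds). Across nuclei, accuracy samples are
compared with the Kruskal–Wallis H-test, plus the Spearman rank
correlation between median accuracy and per-nucleus contact count.

## STA and physiology

STA: ±80 ms LFP snippets around spikes that fall inside extracted
baseline windows on the unit's channel, averaged per block label; the STA
spectrum is the mean of per-snippet Welch periodograms (Hann window; the
segment defaults to the full snippet, the only length that resolves
1–50 Hz on 160 ms snippets). Per-nucleus mean STAs are pointwise means
over units.

Physiology: beats terminating an inter-beat interval < 250 ms are dropped
(iteratively, so cascades are handled); intervals > 1500 ms are treated
as gaps whose HR samples are excluded; bounds are inclusive (250 ms =
240 BPM and 1500 ms = 40 BPM are retained). The surviving instantaneous
HR is interpolated to a 1 ms grid with a modified-Akima cubic Hermite
interpolant. RSA strength per 60 s window (hop 3 s — read as the window
*step*, so consecutive windows share 57 s; the alternative reading is a
config option): multitaper PSD with 7 Slepian tapers (NW = 4, the
smallest time-bandwidth supporting 7 tapers), restricted to
0.25–0.5 Hz, normalized to unit area; the statistic is the mean power
within ± half of the half-prominence width around the dominant interior
peak, or the whole-band mean when no peak exists. Across windows the
values are normalized as (P − μ)/μ with μ the median window power (a
sum-based μ is available behind `mu_mode="sum"`; a sum is not on a power
scale, so the median is the default). Block contrasts use one-sided
paired t-tests across sessions; exactly-zero differences report t = 0,
p = 0.5.

## Problem sizes in the shipped tests

The suite runs the full chain at desk scale: sessions with one airflow
and one touch block on 8 channels, up to 300 baseline windows per class
(test sets of 60), SVM distributions at 20–50 repeats, CNN at 2 epochs ×
20 repeats for the null-calibration check, 16 epochs × 10 repeats for
the signal-detection check (validation accuracy plateaus by ~epoch 10 on
these datasets), and 8 epochs × 10 repeats per band for the ablation
check. Physiology recovery uses 8 simulated sessions with per-session
parameter draws around the defaults (HR ± 4 BPM, depth ± 0.01–0.02,
respiratory rate 0.27–0.45 Hz), since a paired test across sessions
requires between-session variability.

## Known limitations

- The generator's context effect is stationary band-limited Gaussian
  power; the transient, burst-like context dynamics that broadband
  decoders could exploit in real data are not modeled, so band ablation
  results on synthetic data only demonstrate the machinery.
- The CNN is small-scale and CPU-bound by design; it is not a tuned
  architecture, and no hyperparameter search is performed.
- Classifiers are session- and nucleus-specific; no cross-session
  generalization is attempted.
- Baseline windows on the same channel are treated as exchangeable;
  residual short-range temporal correlation between neighboring windows
  is ignored.
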