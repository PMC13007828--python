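# Methods

## Scope and model

`neohfa` analyzes ripple-band (80-250 Hz) high-frequency activity (HFA)
on neonatal scalp EEG. The unit of analysis is a bipolar-referenced
sleep segment; the subject-level statistic is the HFA rate in
events/min/channel; the cohort-level analysis compares rates between
clinical groups (neonates with seizures vs healthy neonates, seizure
etiologies, EEG-background grades, therapeutic-hypothermia status, and
1-year outcome including postneonatal epilepsy). The term HFA is used
deliberately: detections are high-frequency events that satisfy the
operational criteria below, not necessarily discrete physiological
high-frequency oscillations.

## Segment selection

Only sleep-annotated time is analyzed (sleep is the low-EMG state).
Ictal intervals are excluded together with 60 s of padding on each side
(closed intervals: a sample exactly at the 60 s boundary is excluded).
Channels annotated as continuously bad are dropped entirely; transient
annotated artifact spans are subtracted from the usable time. What
remains is tiled greedily into 2-min windows; a trailing remainder is
kept if it is at least 30 s. A subject is analyzable when the union of
selected windows covers at least 5 min. The greedy-maximal tiling is one
of many tilings consistent with a 30 s-2 min window range; the detector
is insensitive to the choice (a dedicated test splits a window in half
and checks the event count moves by at most one event).

## Bipolar montage

The default montage derives 24 bipolar channels from 12 scalp
electrodes (Fp1/2, F3/4, C3/4, P3/4, O1/2, T3/4). Twenty-three pairs
follow from the planar neighbor graph (parasagittal chains, temporal
chains, fronto/parieto-temporal links, transverse links); the
transverse temporal pair T3-T4 completes the 24. Any 12-electrode
arrangement yields 23 planar neighbor pairs, so some such convention is
required; the pair list is a YAML-configurable input, not a constant.

## Three-stage detector

**Stage I (baseline detection).** The signal is band-passed with a
linear-phase equiripple FIR: passband 80-240 Hz (ripple <= 0.25 dB
single-pass), stopbands below 70 Hz and above 250 Hz at >= 60 dB. The
order is grown from a Bellanger estimate until the measured frequency
response meets the spec (243 taps at 1024 Hz). Filtering is
forward-backward (zero phase) so event timing is identical in broadband
and band-limited views. The amplitude threshold is the 95th percentile
of the band envelope (Hilbert magnitude) over *baseline* time, where
baseline means 1-s windows whose normalized ripple-band Stockwell
entropy is at least 0.9; if less than 5 s of baseline is found the
whole segment is used and the segment flagged. Events of interest
(EoIs) are envelope excursions above threshold lasting strictly more
than 20 ms that contain at least 4 local maxima of the rectified band
signal above threshold; excursions separated by less than 10 ms are
merged first so one oscillation with a single sub-threshold sample is
not counted twice.

**Stage II (time-frequency validation).** The Stockwell transform of
the EoI plus 100 ms of context on each side is computed over
40-250 Hz. The discrete S-transform uses the standard frequency-domain
formulation with the frequency-scaled Gaussian window
`exp(-2 pi^2 m^2 / k^2)`; its time-marginal equals the Fourier spectrum
exactly, which anchors the implementation against an FFT oracle. An EoI
is retained when its event-averaged power spectrum has a local maximum
at >= 80 Hz whose power is at least 10x the minimum power (trough)
between the low-frequency range and that peak — the quantitative
reading of a high-frequency peak that stands isolated from surrounding
low-frequency activity. The 10x ratio is configurable.

A note on entropy magnitudes: because the S-transform window broadens
with frequency (sigma_f = f/2 pi), a pure tone's ripple-band power
distribution has normalized entropy around 0.67-0.85 depending on
frequency, not near zero. White noise sits at 0.99. The 0.9 baseline
cutoff separates the two regimes; implementations that expect tone
entropies near zero are assuming a constant-bandwidth transform.

**Stage III (artifact rejection).** EoIs are discarded when (a) the
ripple-band peak-to-peak amplitude is >= 40 uV, (b) SNR < 4, where SNR
is the linear ratio of the event envelope peak to the median baseline
envelope of the same segment (SNR exactly 4 is kept — the criterion is
strict), or (c) the event overlaps a z-score artifact mask by any
sample. Two mask detectors run per recording, each padded by 100 ms:

* *Jump artifacts* are broadband, so they carry energy below the ripple
  band where true ripples carry none. Each channel is low-passed below
  70 Hz and the rectified first difference is z-scored. A channel
  sample with |z| >= 15 is flagged on that channel (focal electrode
  jump); samples where the cross-channel median z exceeds its median by
  5 IQRs are flagged everywhere.
* *Muscle artifacts* are detected from the z-scored 110-140 Hz band
  envelope, aggregated across channels by the median and thresholded at
  median + 5 IQR. Myogenic bursts are spatially widespread, so they
  raise the cross-channel median; a focal ripple on one channel —
  including ripples whose frequency falls inside 110-140 Hz — leaves it
  untouched. Per-channel thresholding of this band is not able to
  distinguish a 125 Hz ripple from a muscle burst even in principle;
  the spatial median is the discriminating statistic.

The 5 x IQR and |z| = 15 thresholds are the published operating points;
the signal each z-score is computed on (low-passed difference, band
envelope) and the median aggregation are implementation choices
documented here because the reference implementation is not public.

**Rate.** The subject HFA rate is total accepted events divided by the
summed analyzed channel-minutes. When every channel contributes the
same duration this equals events-per-minute divided by the channel
count; with unequal usable time per channel it remains a per
channel-minute rate.

## Synthetic data

The signal simulator generates what the detector assumes: colored
Gaussian background with PSD proportional to 1/f^beta (default beta = 2,
shaped from 0.5 Hz, scaled to 20 uV RMS) plus a 1 uV RMS white floor
standing in for amplifier noise and tonic EMG — without the floor, real
scalp EEG's ripple-band noise level is badly underestimated and any
high-frequency transient produces unbounded z-scores. Ripples are
Tukey-windowed (25% taper) sinusoids at 100-200 Hz lasting 40-80 ms
(always >= 4 cycles), placed by a homogeneous Poisson process per
channel (default 0.2 events/min/channel) with overlap rejection.
Injected amplitude is calibrated per channel from a target SNR drawn in
8-12, using the same SNR definition as the detector, so ground-truth
SNR is directly interpretable; the resulting peak-to-peak amplitudes
(25-40 uV) sit below the artifact ceiling. Artifacts: focal rectangular
jumps (100-300 uV), spatially coherent 110-140 Hz noise bursts on all
channels (muscle), and ripple-like transients at >= 40 uV peak-to-peak.
Event amplitudes are peak-to-peak throughout.

The simulator does **not** model neonatal sleep microstructure (tracé
alternant), volume conduction, electrode-specific noise spectra,
regional (hemifacial) EMG, or non-stationary background. Detector
recovery results on this background therefore demonstrate correctness
of the detection logic, not clinical operating characteristics.

The cohort simulator draws per-subject rates from gamma distributions
(default; lognormal available) moment-matched to the published group
means/SDs. The joint study cohort assembles the published
cross-tabulation: rates are drawn per etiology (HIE n=16 at .15/.14,
SVL n=14 at .07/.05, genetic n=14 at .24/.19, other n=3 at the overall
seizure moments .16/.15 since no moments are published for it) and
outcome/background/hypothermia/term labels are assigned within etiology
per the published table. Because outcome groups are etiology mixtures,
their marginal moments land close to the published per-outcome
summaries without being imposed.

## Statistics

* Permutation test: two-sided, statistic |mean(x) - mean(y)|, labels
  permuted uniformly (vectorized argsort-of-uniforms), default 10 000
  resamples, p = (1 + count) / (B + 1) (add-one estimator: valid and
  never zero).
* Hedges g with the classic small-sample correction
  J = 1 - 3/(4N - 9); the exact gamma-function correction is available.
  Recomputing g from published rounded group moments gives 0.92 (vs
  published .87) and 1.17 (vs .99); rounding of the summary statistics
  and the correction variant account for differences of this size, so
  g is not an acceptance quantity.
* Youden threshold: candidate cutoffs are midpoints between consecutive
  sorted unique rates plus sentinels; positive call is rate >=
  threshold (higher HFA = disease); ties in J break toward the lowest
  threshold (maximal sensitivity). AUC is the Mann-Whitney statistic
  over n_pos x n_neg.
* Wilson score intervals with z = 1.96. The published bounds for 8/8,
  34/47 and 10/11 reproduce exactly at printed precision; the 12/16
  lower bound computes to 50.50%, consistent with the published 50
  under truncation. The AUC interval applies the Wilson formula with
  the total sample size — the AUC is not a binomial proportion, so this
  is a labeled heuristic.
* Welch ANOVA (Satterthwaite-type denominator df) and Games-Howell post
  hoc p-values from the studentized-range distribution with q = t
  sqrt(2); Kruskal-Wallis with tie correction via scipy. No
  multiple-testing correction is applied across comparison families
  (only Games-Howell adjusts within its own family).
* All stochastic routines take explicit seeds; the pipeline fans a
  single global seed out by hashing stage and subject names, so adding
  a stage never perturbs another stage's stream.

## Problem sizes and measured behavior

Detector recovery is scored on 8-channel, 10-min recordings (the
per-channel detection path is identical at any channel count; the
cross-channel artifact aggregation only gets stronger with more
channels). Measured on seeded runs: sensitivity 1.0 for injected
ripples at SNR 8-12, and 0.03-0.06 false detections/min/channel on
event-free background — the false calls are background fluctuations
that clear the SNR >= 4 gate by a small margin, which is the expected
behavior of the published operating point rather than a defect. The
detected rate therefore overestimates the injected rate by roughly the
false-call rate.

Cohort power, measured over 1000 replicates of the published designs:
the seizure-vs-healthy permutation test (n = 47 vs 8) rejects at
alpha = .05 in ~93% of replicates, and the PNE arm (n = 11 vs 16) in
~88%. The recovered Youden cutoff for the PNE arm falls below the
PNE-group mean in nearly all replicates but *between* the two group
means in only ~77% — for right-skewed rate distributions the optimal
cutoff sits in the bulk of the lower group, frequently below both
means. Type-I error of the permutation test calibrates to 0.05 within
Monte-Carlo error.

## Known limitations

* The baseline-entropy parameterization (1-s windows, 0.9 cutoff, 95th
  percentile, 5 s minimum baseline) is a reconstruction; the upstream
  detector it emulates is not publicly specified at this level of
  detail. All five numbers are config fields.
* Whether the SNR gate shares its baseline with the amplitude threshold
  is unspecified upstream; here they share it.
* EDF export uses 16-bit quantization over the per-channel data range;
  round-trip error is bounded by range/2^16 (~0.004 uV at typical
  amplitudes) and is invisible to the detector.
* Fast-ripple (> 250 Hz) detection, ictal HFA, automated sleep staging
  and real-time operation are out of scope.
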