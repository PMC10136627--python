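# Methods

`msconn` implements a microstate-gated dynamic functional connectivity
analysis for event-related potentials (ERPs): the multichannel evoked
response is segmented into a small number of quasi-stable scalp
topographies (microstates), phase-locking networks are estimated
separately within each state, and per-participant summary metrics are
compared across conditions and groups with a mixed-design
repeated-measures ANOVA. This note documents the models, the choices
made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## The microstate model

At each sample the average-referenced scalp potential vector
`v(t) ∈ R^C` (C channels) is modelled as one of k fixed unit-strength
topographies `u_1 … u_k` scaled by a time-varying amplitude, plus
noise. Field strength is measured by the global field power

    GFP(t) = sqrt( (1/C) Σ_i (v_i(t) − v̄(t))² ),

the spatial standard deviation across electrodes; it is
reference-invariant and zero only for a flat map. Topographic
similarity is the Pearson correlation across channels of
average-referenced maps, **with sign preserved**: ERP components carry
meaningful polarity, so a map and its negation are different states.
(This differs from spontaneous-EEG microstate analysis, where polarity
is conventionally folded.)

### Segmentation (topographic K-means)

The clustering is a modified K-means on topographies: assignment by
maximum signed spatial correlation, centroid update as the
GFP²-weighted mean of member maps, renormalized to unit GFP and zero
channel-mean each iteration. The objective is the global explained
variance

    GEV = Σ_t (GFP(t) · corr(v(t), u_{L(t)}))² / Σ_t GFP(t)²,

the GFP-weighted fraction of topographic variance explained by the
labelling L. Iterations stop when assignments stabilise or GEV
improves by less than `tol` (default 1e-6, max 500 iterations); the
best of `n_restarts` (default 20) random initialisations is kept. An
empty cluster is reseeded at the currently worst-fit map. Because a
map that correlates negatively with every centroid is still assigned
to the (least negative) maximum, a single iteration could in principle
lower the corr²-based GEV; the implementation ratchets — the
best-scoring state seen is retained — so the reported GEV trace is
non-decreasing.

Back-fitting labels every sample of an ERP with the template of
maximum signed correlation. Exact ties keep the previous sample's
label when it is among the winners (temporal smoothness), otherwise
the lowest class index; both rules are deterministic. No temporal
smoothing or minimum-duration rejection is applied by default; a
minimum-duration merge is available (`min_duration_ms`). Durations per
class are label counts × the sample period. Class names A, B, C, … are
assigned by descending total labelled time in the pooled back-fit.

By default every sample of each ERP enters the clustering;
`gfp_peaks_only` restricts it to local GFP maxima, the common
alternative reading of fitting "at each GFP point".

### Choosing the number of classes

`cross_validate_k` repeats (default 50×) a random split of the
participants into halves, clusters the pooled training-half
topographies at each k in 3…10, and back-fits the resulting templates
to the held-out half. Three held-out scores are recorded per
(repeat, k):

* **test GEV.** Recorded for inspection, but deliberately *not* the
  default selection rule: because back-fitting takes the maximum
  correlation over templates, adding a template can essentially never
  reduce held-out GEV, and empirically the mean test-GEV curve is
  monotone increasing in k on every cohort we generated. An argmax
  over it therefore always returns the top of the range — it is
  non-identifying.
* **penalized CV criterion.** The residual test variance inflated by
  ((C−1)/(C−1−k))², the classic microstate cross-validation penalty;
  selected by minimum. Identifies the truth only marginally on
  realistic cohorts (the residual keeps shrinking through transition
  blends and individual variability).
* **silhouette (default).** The silhouette of the back-fit labels on
  a GFP²-weighted subsample (default 1500 maps) of held-out
  topographies under the signed-correlation distance d = 1 − r.
  Splitting a true class yields two nearly collinear templates and a
  sharp silhouette drop, so the score peaks at the true k; on default
  synthetic cohorts it selects the generated k = 4 in essentially
  every repeat, with a wide margin.

Ties go to the smallest k. The cross-validation uses fewer K-means
restarts (default 3) than the final clustering; selection was
insensitive to this in our runs.

### Global mean templates

Individual template sets are averaged into a global set with unknown
class correspondence resolved by optimal assignment (Hungarian
algorithm) on the k×k signed correlation matrix against a provisional
mean, iterated until the permutations stabilise. Signed matching means
a polarity-flipped map is never identified with its upright
counterpart. Statistics are always computed from per-participant
back-fits of the global templates; grand averages are used for
nothing but the templates themselves.

## Phase-locking networks

Instantaneous phases come from the analytic (Hilbert) signal of the
band-limited epochs, per trial and channel. The phase-locking value
between channels a, b at sample t is the modulus of the trial-mean
unit phasor of the phase difference; it is 1 for perfect locking and
has a finite-sample floor of about sqrt(π)/(2·sqrt(N)) for N unrelated
trials. PLV is computed on the 0.1–30 Hz broadband signal (no band
decomposition), matching the preprocessing band. The first and last 5%
of epoch samples (configurable) are excluded from all gated averages
because the analytic signal is unreliable near the epoch edges.

The per-state network averages PLV(t) over the (valid) samples
carrying one microstate label; a state with no labelled samples is
marked as an empty network and skipped downstream. Graph metrics on
the symmetric, nonnegative, zero-diagonal adjacency:

* **Cp** — mean clustering coefficient. Default mode is *weighted* on
  the full PLV matrix (no threshold, since PLV is strictly positive
  and a threshold adds a free parameter), using the geometric-mean
  triangle formula with weights normalized by the maximum weight.
  A *binary* mode with proportional-sparsity thresholding is available
  for toolbox-style comparability.
* **Lp** — characteristic path length with distances 1/weight
  (weighted) or 1 (binary), averaged over ordered pairs with finite
  distance; the finite-pair count is reported (disconnection can only
  arise after thresholding).

## Statistics

Every metric (rating, per-class duration, Cp, Lp) is analysed from the
same long table — one value per participant × condition — as a
two-way mixed ANOVA: Condition (Neg / Neu / Rea) within subjects,
Group (music / control) between. Sphericity is tested with Mauchly's
W; when it fails at α = 0.05 the within-effect degrees of freedom are
multiplied by the Greenhouse–Geisser ε (policy configurable:
`mauchly` / `always` / `never`), giving fractional dfs in the report
strings. The decomposition, W and ε come from pingouin; the
conditional policy, the interaction's corrected p-value and the
formatting are this package's. Post-hoc comparisons are
Bonferroni-adjusted t-tests with per-comparison error terms: paired
between conditions, independent between groups, and independent
group contrasts within each condition for the interaction. Degenerate
(zero-variance) tables are flagged rather than fitted. Missing cells
are an error; no imputation.

## Preprocessing

Fixed order: band-pass filter → epoch & baseline-correct → amplitude
rejection → average reference → resample → per-condition averaging,
with per-stage counts in the run report. Choices:

* zero-phase 4th-order Butterworth band-pass (0.1–30 Hz default).
  When the data span fewer than two cycles of the low edge (always
  true for a 0.1 Hz edge on a 5.2 s epoch), an IIR high-pass is
  numerically meaningless — its transient exceeds the signal — so the
  high-pass is replaced by linear detrending and only the low-pass is
  applied. On continuous recordings the genuine band-pass is used.
* half-open epoch window [−200, 5000) ms, baseline [−200, 0) ms,
  0 ms = stimulus onset; 250 Hz target rate gives 1300 samples.
* amplitude-threshold rejection (±100 µV default) is a deterministic
  stand-in for manual ICA/visual cleaning of real recordings, not an
  equivalent; synthetic cohorts contain no artifacts by construction.
* polyphase resampling; no notch filter (the band-pass already
  excludes mains frequencies); no bad-channel interpolation (real-data
  users must supply clean channels).

## The synthetic cohort generator

No public recording accompanies the design this package targets, so
the generator is first-class, tested code that emulates it: two groups
(music n = 28, control n = 24), 90 trials per participant in three
conditions (Neg / Rea / Neu, 30 each; 60 negative and 30 neutral
pictures), 64 channels, epochs −200…5000 ms at 250 Hz.

Each epoch is `u_{L(t)} · env(t) + noise`:

* **Templates** are random smooth spatial polynomials over a
  deterministic disk layout, average-referenced, unit-GFP, redrawn
  until pairwise |r| ≤ 0.5. Each participant uses an individually
  perturbed variant of the group set (`template_variability`, default
  0.3, i.e. individual-to-group correlations around 0.95) — the
  spread that makes averaging individual sets into a global template
  meaningful, and what gives a participant split-half something to
  cross-validate.
* **State sequence** L(t): piecewise-constant labels with segment
  durations uniform in 300–900 ms by default (consecutive segments
  differ), shared by all trials of a participant. The range matches
  the several-hundred-ms dynamic windows characteristic of
  slow-paradigm ERP microstate analyses; much shorter segments would
  leave a large fraction of samples inside the band-pass filter's
  transition blends.
* **Envelope** env(t): a 0.05 µV floor (keeping every sample
  identifiable in the noiseless limit) plus a sigmoid onset ramp and
  three Gaussian bumps (4, 3, 2.5 µV at 300, 1000, 2800 ms) — an
  ERP-like profile with a signal-free pre-stimulus baseline, as
  baseline correction assumes.
* **Noise**: spatially and temporally white Gaussian, scaled so the
  ratio of mean signal GFP to expected noise GFP equals `snr`
  (default 5); `snr=inf` is exactly noiseless. The GFP-based ratio
  matches the analysis's own amplitude measure.
* **Phase-coupled pairs** for PLV validation: both channels follow a
  common 10 Hz oscillator with a random phase per trial; each adds an
  independent trial-constant von Mises jitter. With jitters of
  concentration κ the population PLV is (I₁(κ)/I₀(κ))², so κ is
  solved by 1-D root finding to hit a requested target exactly.
* **Ratings**: per-participant condition means drawn
  Normal(cell mean, SD), clipped to the 1–9 scale.

What the generator does **not** emulate: volume-conducted (spatially
correlated) noise, ocular/muscle artifacts, forward-modelled head
geometry, trial-to-trial latency jitter, or condition-dependent state
sequences. Passing tests therefore establish that the analysis chain
recovers known structure under its own model assumptions — template
identifiability, k-selection, PLV targets, ANOVA calibration — not
that it is robust to every property of real recordings.

## Problem sizes used in validation

Validation runs use cohorts scaled to the information each check
needs: model-selection recovery uses 12+12 participants with 10 trials
per condition (epoch geometry, channel count, snr = 5 and the full
k = 3…10 range with 50 split-half repeats retained); template-recovery
and end-to-end checks use 16-channel, 8-participant cohorts; the
ANOVA null calibration simulates 2000 cohorts at the full 28/24 group
sizes; PLV estimator bias is measured at 5000 trials.

## Known limitations

* The silhouette selection criterion, like any cluster-validity
  index, presumes the states are topographically well separated; with
  strongly overlapping true templates (|r| near 1) no split-half
  criterion will separate them.
* The weighted Lp depends on the 1/weight distance convention; other
  monotone transforms would reorder nothing but change magnitudes.
* The amplitude-threshold rejection cannot remove structured
  artifacts (blinks, drifts) that real ICA-based cleaning targets.
* With few trials the PLV floor (~sqrt(π)/(2·sqrt(N))) biases all
  connections upward; comparisons across conditions with equal trial
  counts are unaffected, absolute values are not.
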