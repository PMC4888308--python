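# Methods

`preshot` quantifies event-related desynchronization/synchronization
(ERD/ERS) of theta and alpha rhythms in the seconds before a self-paced
pistol shot, separately for the four performance states of the MAP
(multi-action plan) model, and tests state differences with a
within-subject ANOVA battery. Because raw EEG for this paradigm is not
publicly deposited, the package ships a synthetic-session generator with
known injected effects; every stage of the analysis is validated against
that ground truth.

## The ERD/ERS index

For a band-limited signal, instantaneous power is the squared magnitude
of the analytic signal (Hilbert envelope). The convention here is
|analytic|², so a sine of amplitude A has envelope power A² (not ½A²);
all internal oracles use the same convention. For each epoch, channel and
1-s interval of interest the index is

    ERD/ERS% = −100 · (P_int − P_base) / P_base

with P_base the band power in the −5…−4 s pre-shot baseline averaged over
all epochs of the same (subject × performance type) group — the finest
grouping consistent with group-wise baseline averaging — and P_int the
mean envelope power in the interval. The leading −1 makes a power
*decrease* positive (ERD) and an increase negative (ERS), matching
classical reporting; `sign_convention="raw_percent_change"` switches to
the plain percent change. Per-epoch indices are averaged into the
(subject × type) map, then across subjects with equal subject weight;
averaging power before forming the index is available
(`average="power_first"`) for sensitivity checks and agrees closely on
synthetic data.

Analysis setup (fixed defaults): bands theta 4–8 Hz, low alpha 8–10 Hz,
high alpha 10–12 Hz; epochs −6…+4 s around shot release; intervals
[−3,−2], [−2,−1], [−1,0] s; baseline −5…−4 s (baselines earlier than −5 s
are rejected, as pre-−5 s spans are contaminated by postural
adjustment). Band filtering for the Hilbert step is a zero-phase
4th-order Butterworth; a 0.5-s guard at each epoch edge is excluded from
every window statistic. Baseline power of zero produces a missing value
with a warning, never a division blow-up. The index is scale-invariant:
rescaling a channel leaves it unchanged.

## Preprocessing

The continuous recording is filtered 0.3–40 Hz (zero-phase 4th-order
Butterworth — a standard, stable choice at a 0.3 Hz high-pass) *before*
epoching, because the high-pass transient spans several seconds. Epochs
are `round(10·fs)` samples on the half-open window [−6, +4); the
sample-index rule is `round(onset·fs)` everywhere. Artifact handling is
deliberately rejection-only with transparent thresholds (no correction):
an epoch is discarded when, within the analysis-relevant span [−6, 0] s,
any channel exceeds 100 µV peak-to-peak, jumps more than 50 µV between
samples, or is flat below 0.5 µV. Post-shot transients (recoil,
movement) never discard a trial. Raw and retained counts are reported
per subject. No re-referencing is applied; data stay in the recording
reference, and the index's scale invariance makes it insensitive to a
common gain.

## Performance categorization

Each trial is crossed on two margins: optimal iff shooting score ≥ the
score threshold, automatic iff perceived control ≤ the control threshold
(closure chosen as ≥/≤ and exposed as configuration). Thresholds are
either fixed (10.2 score, 4 Borg units) or pooled medians
(`median_split`, the default, with a per-subject option). A quirk worth
knowing: the reported mean control of the optimal-automatic state (4.59)
and of the suboptimal-automatic state (4.39) both exceed the fixed
cut-off 4, so the fixed rule classifies the average "automatic" trial as
controlled; the pooled median (≈5.5 under the default behavior
distributions) separates the automatic and controlled clusters cleanly.
This is why `median_split` is the default. The median split also forces
each margin to ~50/50, so when the true mixture is 51/49 the per-type
counts are systematically redistributed by a few percent relative to the
generative mixture — visible in `examples/categorize_quadrants.py`.

## Synthetic sessions

Defaults are the study conditions: 10 subjects × 120 shots, 32-channel
10–20 cap (with M1/M2), 1024 Hz, inter-shot interval 60 ± 5 s, so one
recording lasts ≈2 h. Tests and the acceptance script use a documented
down-scaled variant (256 Hz, 4–8 channels, 12 ± 1 s spacing) that keeps
≥6 s of history and ≥4 s of future signal around every shot.

Per channel the signal is a 1/f^α Gaussian background (α = 1 by default,
flattened below 0.5 Hz) plus one narrowband oscillator per analysis band
(centers 6, 9, 11 Hz; amplitude 10 µV), each a constant-amplitude sine
with a random-walk phase giving ≈0.05 Hz linewidth. The narrow linewidth
is deliberate: wider Lorentzian tails leak across the shared 8 Hz and
10 Hz band edges and bias neighboring-band indices. The background std
is 2.5 µV, i.e. ≈20 dB in-band SNR for the rhythms. This is the level at
which the generator satisfies its own calibration contract — Welch band
power in a modulated window over baseline within g² ± 10%, and index
recovery within ±5 points of 100·(1−g²) at ≥50 epochs/cell — because the
measured ratio is (g²·P_osc + P_noise)/(P_osc + P_noise): in-band noise
dilutes every injected effect toward zero by the noise fraction.

Amplitude gains g are configured per (performance type, band, channel,
window) with wildcards; ground truth is expressed in power,
100·(1−g²), to avoid the amplitude-vs-power factor confusion.
Transitions are raised-cosine ramps of 100 ms; transitions from baseline
into a modulated block are centred 0.1 s *before* the window start (and
symmetrically after the end) so that the band filters' ±0.2 s envelope
smearing settles outside the measured window — the transient lives in
the unanalysed −4…−3 s gap and post-shot span. Gain changes between two
adjacent modulated windows are centred on the boundary; such
per-window-differing configurations therefore carry a residual smear of
up to ~10% of the gain difference into each neighbour, a known
limitation of 1-s windows at 2-Hz bandwidths.

Per-subject channel×band amplitude heterogeneity (±10%) exercises
grand-averaging nontrivially without affecting indices (scale
invariance). Ocular artifacts are slow 150–300 µV deflections weighted
toward the frontopolar sites; muscular artifacts are 20–40 Hz bursts;
both arrive as a Poisson process (default 0.5/min, chosen to yield a
moderate rejection fraction comparable to a real session) and every
event is logged so detector recall can be scored. Behavior per trial is
Gaussian per type with the reported means/SDs (scores clipped to
0–10.9, control to 0–11); the true type labels are drawn from the
reported mixture (238, 350, 212, 348)/1148.

What the generator does *not* emulate: volume conduction and realistic
inter-channel correlation, real blink/EMG morphology, slow
non-stationarity over the 2-h session, reference-electrode effects, and
any coupling between behavior and EEG beyond the type label. Passing
tests therefore demonstrate correctness of the measurement chain, not
performance on real recordings.

## Statistics

Per (band, electrode), per-subject mean indices form the n × 4 × 3 cell
table (subjects × performance types × intervals, both factors within
subject). Sums of squares follow the balanced partition — subjects, A,
A×S, B, B×S, A×B, A×B×S — with F_A = MS_A/MS_{A×S}, F_B = MS_B/MS_{B×S},
F_{A×B} = MS_{A×B}/MS_{A×B×S}; the partition is verified against a
brute-force projection-matrix oracle and statsmodels' AnovaRM. For
n = 10 the printed df pairs are (3,27), (2,18), (6,54). A numerically
null effect SS (≤1e−12 of SS_total) reports F = 0; a zero error MS
reports F = NaN.

Sphericity per effect uses the covariance of orthonormal contrasts
(Kronecker products for the interaction): Mauchly's W with the standard
chi-square approximation, ε_GG = (tr S)²/(d·tr S²), and
ε_HF = min(1, (n·d·ε_GG − 2)/(d·(n − 1 − d·ε_GG))). Two-level effects
are trivially spherical. When n − 1 ≤ d the covariance is singular:
epsilons still come from the trace formulas, Mauchly's p is NaN, and a
warning names the fallback. The default policy rescales dfs by ε_HF only
when Mauchly's p < .05 ('always' and 'never' are provided); printed dfs
stay uncorrected integers with ε reported separately, matching the
published table layout. Effect size is partial eta squared,
η²p = F·df1/(F·df1 + df2) ≡ SS_effect/(SS_effect + SS_error).

Fisher LSD post-hocs run on the marginal means of significant main
effects only (classical LSD protection), using that effect's error term:
t_ij = (m_i − m_j)/√(2·MS_error/n_eff) with n_eff the observations per
marginal mean; for a two-level factor t² equals the omnibus F. No
multiplicity correction is applied across the 96 electrode×band ANOVAs
(matching the original analysis); a Benjamini–Hochberg column is
available via `fdr=True`. Electrodes with incomplete designs are skipped
and listed. Under null cell tables the battery's per-test rejection rate
at α = .05 is calibrated within [0.03, 0.07] (500-replicate simulation
in the acceptance suite).

## Topographic maps

Electrode positions are standard 10–20/10–10 unit-sphere coordinates,
symmetrized so homologous left/right sites mirror exactly. The scalp is
projected azimuthal-equidistant from the vertex; values are interpolated
by inverse-distance weighting (power 2) on great-circle distances —
dependency-light, exact at electrode sites, sufficient for qualitative
maps (spherical splines are a possible extension). Points outside the
electrode convex hull are masked. Color limits are symmetric about zero
at the per-band grand max |index|, maximum ERD red and maximum ERS blue.
Each band yields a 12-panel figure (4 types × 3 windows).

## Problem sizes used by tests and the acceptance script

Gain recovery: 10 subjects × 120 trials at 256 Hz, 8 channels, 12-s
spacing, gains {1.0, 0.8, 0.6, 1.25} coupled to quadrant (~300 epochs
per grand cell). Single-subject recovery: 320 trials (~80 epochs/cell).
Type-I calibration: 500 null cell tables at n = 10, one electrode, one
band. Categorization: n = 1148 trials. These sizes were chosen so each
property is measured with sampling error well inside its tolerance.

## Known limitations

- The measurement chain's ±0.2 s envelope smearing biases 1-s window
  estimates of step modulations whose transitions fall inside a window;
  the generator's lead/lag placement removes this at block edges but not
  between adjacent windows with different gains.
- Median-split categorization redistributes per-type counts toward 50/50
  margins and mislabels trials in the overlap of the control
  distributions (~5–10% under default behavior parameters); downstream
  group contrasts are correspondingly diluted.
- The EDF writer targets the plain 16-bit EDF profile (one 1-s record
  per second, whole-second recordings); EDF+ annotations are not
  written.
- Fisher LSD is provided for main effects; interaction post-hocs would
  require simple-effects machinery that is out of scope.
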